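"""Position-specific scoring profiles with Gumbel-calibrated E-values.

Each cluster's alignment is turned into a match-state log-odds profile
(PSSM) over its well-occupied columns, scored against database sequences by
local dynamic programming with affine gaps, and calibrated against i.i.d.
background decoys so that scores translate into E-values.  The per-family
share of hits below an E-value threshold summarizes how similar a cluster
is to each family in a labeled database.

This is deliberately *not* a full profile-HMM: there is no insert-state
emission model and no Forward algorithm.  A Viterbi-style best local
alignment against a PSSM with affine gap penalties captures what the
pipeline needs — a calibrated family-similarity ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sequence_io import AMINO_ACIDS, GAP, UNKNOWN, Alignment, SequenceRecord

EULER_GAMMA = 0.5772156649015329

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class GumbelCalibration:
    mu: float
    lam: float  # > 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel lambda must be positive")


@dataclass(frozen=True)
class ProfileModel:
    match_columns: tuple[int, ...]  # original alignment column indices
    log_odds: np.ndarray  # (n_match, 20), base-2
    background: np.ndarray  # (20,), sums to 1
    gap_open: float = -11.0
    gap_extend: float = -1.0
    calibration: GumbelCalibration | None = None

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "log_odds", np.asarray(self.log_odds, dtype=float))
        if abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValueError("background must be positive and sum to 1")
        mc = tuple(self.match_columns)
        object.__setattr__(self, "match_columns", mc)
        if any(b <= a for a, b in zip(mc, mc[1:])):
            raise ValueError("match_columns must be strictly increasing")
        if self.log_odds.shape != (len(mc), 20):
            raise ValueError("log_odds shape must be (n_match, 20)")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")

    @property
    def length(self) -> int:
        return len(self.match_columns)


@dataclass(frozen=True)
class FamilyDatabase:
    records: tuple[SequenceRecord, ...]
    family_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [r.id for r in self.records if r.id not in self.family_of]
        if missing:
            raise ValueError(f"records without family label: {missing[:5]}")


@dataclass(frozen=True)
class HitTable:
    e_threshold: float
    hits: tuple[tuple[str, str, float, float], ...]  # (seq_id, family, score, evalue)
    distribution: dict[str, float]  # family -> percentage of kept hits


def database_background(records) -> np.ndarray:
    """Residue frequencies of a sequence collection (uniform fallback)."""
    counts = np.zeros(20)
    for r in records:
        for c in r.residues:
            i = _AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(20, 1 / 20)
    return counts / counts.sum()


def sequence_weights(aln: Alignment) -> dict[str, float]:
    """Henikoff & Henikoff position-based weights, summing to the row count.

    In each column a residue type shared by s rows in a column with r
    distinct types contributes 1/(r*s) to each of those rows; gaps count as
    a type of their own.  Over-represented (near-duplicate) rows end up
    down-weighted.
    """
    chars = aln.to_array()
    n, _ = chars.shape
    raw = np.zeros(n)
    for col in chars.T:
        types, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        raw += 1.0 / (len(types) * counts[inverse])
    if raw.sum() == 0:
        raw[:] = 1.0
    weights = raw * n / raw.sum()
    return {r.id: float(w) for r, w in zip(aln.rows, weights)}


def build_profile(
    aln: Alignment,
    background: np.ndarray | None = None,
    match_gap_frac: float = 0.5,
    pseudocount_alpha: float = 0.5,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> ProfileModel:
    """Weighted log-odds profile over well-occupied alignment columns.

    Match columns are those with gap fraction <= `match_gap_frac`.  Observed
    weighted counts ``c_a`` are smoothed with background-proportional
    pseudocounts, ``p_a = (c_a + alpha*q_a*n_eff) / (n_eff + alpha*n_eff)``,
    and converted to base-2 log-odds against the background ``q``.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    weights = sequence_weights(aln)
    w = np.array([weights[r.id] for r in aln.rows])
    chars = aln.to_array()
    n_rows = chars.shape[0]
    match_cols: list[int] = []
    rows_logodds: list[np.ndarray] = []
    alpha = pseudocount_alpha
    for col_idx, col in enumerate(chars.T):
        if np.sum(col == GAP) / n_rows > match_gap_frac:
            continue
        counts = np.zeros(20)
        n_eff = 0.0
        for c, wt in zip(col, w):
            i = _AA_INDEX.get(c)
            if i is not None:  # gaps and 'X' carry no count
                counts[i] += wt
                n_eff += wt
        if n_eff <= 0:
            continue
        p_hat = (counts + alpha * background * n_eff) / (n_eff + alpha * n_eff)
        rows_logodds.append(np.log2(p_hat / background))
        match_cols.append(col_idx)
    if not match_cols:
        raise ValueError("no match columns at the given gap-fraction threshold")
    return ProfileModel(
        tuple(match_cols),
        np.array(rows_logodds),
        background,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def _encode_seq(seq: str) -> np.ndarray:
    """Residues as 0..19 indices; unknown 'X' -> 20 (scores 0 everywhere)."""
    return np.array([_AA_INDEX.get(c, 20) for c in seq], dtype=np.int64)


def _match_score_table(profile: ProfileModel) -> np.ndarray:
    """(n_match, 21) score table: 20 residues + neutral unknown column."""
    return np.hstack([profile.log_odds, np.zeros((profile.length, 1))])


def batch_scores(profile: ProfileModel, encoded: np.ndarray) -> np.ndarray:
    """Best local alignment scores for a batch of equal-length sequences.

    `encoded` is (n_seqs, L) of residue indices (pad with 20, the neutral
    unknown, for shorter sequences — a zero-scoring column can never raise
    a local score).  Vectorized over sequences and sequence positions; the
    dynamic programme iterates over profile positions only.
    """
    table = _match_score_table(profile)
    go, ge = profile.gap_open, profile.gap_extend
    n_seqs, slen = encoded.shape
    neg = -np.inf
    m_prev = np.full((n_seqs, slen), neg)  # M[i-1, :]
    ix_prev = np.full((n_seqs, slen), neg)  # gap in sequence (consume profile)
    iy_prev = np.full((n_seqs, slen), neg)  # gap in profile (consume sequence)
    offsets = ge * np.arange(slen)
    best = np.zeros(n_seqs)
    for i in range(profile.length):
        s = table[i][encoded]  # (n_seqs, slen)
        prev = np.maximum(np.maximum(m_prev, ix_prev), iy_prev)
        m = s.copy()
        m[:, 1:] += np.maximum(0.0, prev[:, :-1])
        # Ix: gap in the sequence — extend down the profile, same column
        ix = np.maximum(m_prev + go, ix_prev + ge)
        # Iy: gap in the profile — affine along the sequence axis, from M of
        # this row; linear extension allows a running-max formulation
        run = np.maximum.accumulate(m - offsets, axis=1)
        iy = np.full((n_seqs, slen), neg)
        iy[:, 1:] = run[:, :-1] + offsets[:-1] + go
        best = np.maximum(best, m.max(axis=1))
        m_prev, ix_prev, iy_prev = m, ix, iy
    return best


def profile_align(
    profile: ProfileModel, seq: SequenceRecord
) -> tuple[float, tuple[int, int]]:
    """Best local alignment of an ungapped query against the profile.

    Returns ``(score, (start, end))`` with a half-open span in the query;
    a query scoring nowhere positive gets ``(0.0, (0, 0))``.
    """
    residues = seq.residues
    if GAP in residues:
        raise ValueError("query must be ungapped")
    enc = _encode_seq(residues)
    table = _match_score_table(profile)
    go, ge = profile.gap_open, profile.gap_extend
    plen, slen = profile.length, len(enc)
    neg = -np.inf
    m = np.full((plen + 1, slen + 1), neg)
    ix = np.full((plen + 1, slen + 1), neg)
    iy = np.full((plen + 1, slen + 1), neg)
    start = np.zeros((plen + 1, slen + 1, 3), dtype=np.int64)  # origin column per state
    best, best_pos = 0.0, None
    for i in range(1, plen + 1):
        srow = table[i - 1]
        for j in range(1, slen + 1):
            prev_states = (m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1])
            k = int(np.argmax(prev_states))
            cont = prev_states[k]
            if cont > 0:
                m[i, j] = srow[enc[j - 1]] + cont
                start[i, j, 0] = start[i - 1, j - 1, k]
            else:
                m[i, j] = srow[enc[j - 1]]
                start[i, j, 0] = j - 1
            if m[i - 1, j] + go >= ix[i - 1, j] + ge:
                ix[i, j] = m[i - 1, j] + go
                start[i, j, 1] = start[i - 1, j, 0]
            else:
                ix[i, j] = ix[i - 1, j] + ge
                start[i, j, 1] = start[i - 1, j, 1]
            if m[i, j - 1] + go >= iy[i, j - 1] + ge:
                iy[i, j] = m[i, j - 1] + go
                start[i, j, 2] = start[i, j - 1, 0]
            else:
                iy[i, j] = iy[i, j - 1] + ge
                start[i, j, 2] = start[i, j - 1, 2]
            if m[i, j] > best:
                best = m[i, j]
                best_pos = (i, j)
    if best_pos is None:
        return 0.0, (0, 0)
    i, j = best_pos
    return float(best), (int(start[i, j, 0]), j)


def write_profile_tsv(profile: ProfileModel, path) -> None:
    """Serialize a profile: metadata header lines, then one row per match
    column with its original column index and 20 log-odds scores."""
    with open(path, "w") as fh:
        fh.write(f"# gap_open\t{profile.gap_open}\n")
        fh.write(f"# gap_extend\t{profile.gap_extend}\n")
        fh.write("# background\t" + "\t".join(f"{q:.10g}" for q in profile.background) + "\n")
        if profile.calibration is not None:
            fh.write(
                f"# calibration\t{profile.calibration.mu:.10g}"
                f"\t{profile.calibration.lam:.10g}\n"
            )
        fh.write("column\t" + "\t".join(AMINO_ACIDS) + "\n")
        for col, row in zip(profile.match_columns, profile.log_odds):
            fh.write(f"{col}\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_profile_tsv(path) -> ProfileModel:
    gap_open, gap_extend = -11.0, -1.0
    background = np.full(20, 1 / 20)
    calibration = None
    cols: list[int] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "gap_open":
                    gap_open = float(parts[1])
                elif parts[0] == "gap_extend":
                    gap_extend = float(parts[1])
                elif parts[0] == "background":
                    background = np.array([float(x) for x in parts[1:21]])
                elif parts[0] == "calibration":
                    calibration = GumbelCalibration(float(parts[1]), float(parts[2]))
                continue
            parts = line.split("\t")
            if not line or parts[0] == "column":
                continue
            cols.append(int(parts[0]))
            rows.append([float(x) for x in parts[1:21]])
    return ProfileModel(
        tuple(cols),
        np.array(rows),
        background,
        gap_open=gap_open,
        gap_extend=gap_extend,
        calibration=calibration,
    )


def fit_gumbel(scores: np.ndarray) -> GumbelCalibration:
    """Method-of-moments Gumbel fit: ``lambda = pi / (sd * sqrt(6))``,
    ``mu = mean - gamma / lambda`` (Euler–Mascheroni gamma)."""
    scores = np.asarray(scores, dtype=float)
    sd = float(np.std(scores, ddof=1))
    if sd == 0:
        raise ValueError("scores have zero variance; cannot fit a Gumbel")
    lam = float(np.pi / (sd * np.sqrt(6.0)))
    mu = float(np.mean(scores)) - EULER_GAMMA / lam
    return GumbelCalibration(mu=mu, lam=lam)


def calibrate(
    profile: ProfileModel, length: int, n_decoys: int = 200, seed: int = 0
) -> ProfileModel:
    """Fit a Gumbel null to scores of i.i.d. background decoys."""
    if n_decoys < 50:
        raise ValueError("need at least 50 decoys")
    rng = np.random.default_rng(seed)
    decoys = rng.choice(20, size=(n_decoys, length), p=profile.background)
    scores = batch_scores(profile, decoys)
    return replace(profile, calibration=fit_gumbel(scores))


def evalue(profile: ProfileModel, score: float, db_size: int) -> float:
    """Expected hits at or above `score` in a size-`db_size` database."""
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    cal = profile.calibration
    p = -np.expm1(-np.exp(-cal.lam * (score - cal.mu)))
    return float(db_size * p)


def search(
    profile: ProfileModel, db: FamilyDatabase, e_threshold: float = 0.1
) -> HitTable:
    """Score every database record; keep hits with E-value below threshold.

    The distribution is each family's percentage of the kept hits (summing
    to 100 when any hit survives).
    """
    if not db.records:
        raise ValueError("empty database")
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    maxlen = max(len(r.residues) for r in db.records)
    encoded = np.full((len(db.records), maxlen), 20, dtype=np.int64)
    for i, r in enumerate(db.records):
        enc = _encode_seq(r.residues)
        encoded[i, : len(enc)] = enc
    scores = batch_scores(profile, encoded)
    db_size = len(db.records)
    hits = []
    for r, s in zip(db.records, scores):
        e = evalue(profile, float(s), db_size)
        if e < e_threshold:
            hits.append((r.id, db.family_of[r.id], float(s), e))
    hits.sort(key=lambda h: h[3])
    dist: dict[str, float] = {}
    if hits:
        for _, fam, _, _ in hits:
            dist[fam] = dist.get(fam, 0.0) + 1.0
        dist = {f: 100.0 * c / len(hits) for f, c in sorted(dist.items())}
    return HitTable(e_threshold, tuple(hits), dist)
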