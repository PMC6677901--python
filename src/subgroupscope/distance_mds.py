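"""Substitution-matrix distances between aligned sequences, and their
classical (Torgerson) metric MDS embedding.

The dissimilarity between two aligned rows is a normalized score
difference::

    d_ij = 1 - 2 * s_ij / (s_ii|C + s_jj|C)

where ``s_ij`` is the summed substitution-matrix score over the pair's
co-ungapped columns ``C`` and the self-scores are restricted to the same
column set (so shared gap architecture never inflates the distance between
identical subsequences).  The result is clamped to [0, 2]: 0 for identical
rows, 1 when the cross-score is zero, up to 2 for strongly anti-correlated
residue pairs.  Pairs with no shared columns get the maximal distance 2.

Classical MDS (principal coordinates analysis) double-centers the squared
distance matrix, eigendecomposes it, and keeps the components with positive
eigenvalue, so Euclidean-realizable distances are reconstructed exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sequence_io import GAP, Alignment, SubstitutionMatrix


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(d)) or d.min() < -1e-12 or d.max() > 2 + 1e-12:
            raise ValueError("distances must be finite and within [0, 2]")


@dataclass(frozen=True)
class MdsProjection:
    """Principal-coordinate embedding: rows of `coords` are sequences."""

    labels: tuple[str, ...]
    coords: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,), positive, non-increasing


def pairwise_score(row_a: str, row_b: str, matrix: SubstitutionMatrix) -> float:
    """Summed matrix score over co-ungapped columns (0 if there are none)."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    total = 0.0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        total += matrix.score(a, b)
    return total


def _encode(aln: Alignment, matrix: SubstitutionMatrix) -> np.ndarray:
    """Alignment as matrix-alphabet indices; gaps and absent residues -> -1.

    Residues absent from the matrix other than 'X' are an error.
    """
    chars = aln.to_array()
    codes = matrix.encoder()[chars.view(np.uint32).reshape(chars.shape)]
    unknown = (codes < 0) & (chars != GAP) & (chars != "X")
    if np.any(unknown):
        bad = sorted(set(chars[unknown].tolist()))
        raise ValueError(f"residues absent from the substitution matrix: {bad}")
    codes[(chars == GAP) | ((chars == "X") & (codes < 0))] = -1
    return codes


def score_distance_matrix(aln: Alignment, matrix: SubstitutionMatrix) -> DistanceMatrix:
    """Pairwise normalized score distances for all rows of an alignment."""
    if len(aln.rows) < 2:
        raise ValueError("need at least two rows")
    codes = _encode(aln, matrix)
    n, _ = codes.shape
    nongap = codes >= 0
    safe = np.where(nongap, codes, 0)
    # per-row, per-column self score (0 where the row is gapped/unknown)
    table = matrix.scores
    self_scores = np.where(nongap, table[safe, safe], 0.0)
    d = np.zeros((n, n))
    pathological = False
    for i in range(n - 1):
        js = slice(i + 1, n)
        mask = nongap[i] & nongap[js]  # (n-i-1, L)
        cross = np.where(mask, table[safe[i], safe[js]], 0.0).sum(axis=1)
        s_ii = np.where(mask, self_scores[i], 0.0).sum(axis=1)
        s_jj = np.where(mask, self_scores[js], 0.0).sum(axis=1)
        denom = s_ii + s_jj
        shared = mask.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dij = 1.0 - 2.0 * cross / denom
        bad = ~shared | (denom <= 0)
        if np.any(shared & (denom <= 0)):
            pathological = True
        dij[bad] = 2.0
        d[i, i + 1 :] = np.clip(dij, 0.0, 2.0)
    if pathological:
        warnings.warn(
            "non-positive self-scores over shared columns; affected pairs "
            "set to maximal distance 2",
            stacklevel=2,
        )
    d = d + d.T
    return DistanceMatrix(tuple(aln.ids), d)


def classical_mds(dist: DistanceMatrix, m: int | None = None) -> MdsProjection:
    """Torgerson scaling of a distance matrix.

    Keeps the top-``m`` components with positive eigenvalue (default: all
    positive ones, capped at 10).  Sign convention: within each component the
    entry of largest magnitude is positive, making the embedding
    deterministic.
    """
    d = dist.d
    n = d.shape[0]
    if m is not None and not (1 <= m < n):
        raise ValueError(f"m must be in [1, {n - 1})")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval[0])) if eigval.size else 0.0
    n_pos = int(np.sum(eigval > tol))
    if m is None:
        keep = min(n_pos, 10)
    else:
        keep = m
        if n_pos < m:
            warnings.warn(
                f"only {n_pos} positive eigenvalues available (requested {m})",
                stacklevel=2,
            )
            keep = n_pos
    if n_pos == 0:  # all rows effectively coincident
        warnings.warn("no positive eigenvalues; returning a zero embedding", stacklevel=2)
        return MdsProjection(dist.labels, np.zeros((n, 1)), np.zeros(1))
    vals = eigval[:keep]
    coords = eigvec[:, :keep] * np.sqrt(vals)
    flip = coords[np.abs(coords).argmax(axis=0), np.arange(keep)] < 0
    coords[:, flip] *= -1.0
    return MdsProjection(dist.labels, coords, vals)


def write_distance_tsv(dist: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(dist.d, index=list(dist.labels), columns=list(dist.labels)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def write_coords_tsv(proj: MdsProjection, path) -> None:
    import pandas as pd

    cols = [f"PC{i + 1}" for i in range(proj.coords.shape[1])]
    pd.DataFrame(proj.coords, index=list(proj.labels), columns=cols).to_csv(
        path, sep="\t", float_format="%.10g"
    )
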