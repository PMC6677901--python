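"""Conserved alignment blocks, per-cluster logo matrices, discriminating
sites between clusters, and mapping of columns to a reference numbering.

A *block* is a maximal run of at least `min_len` consecutive alignment
columns each containing no more than `max_gap_frac` gaps (boundary
inclusive).  Within blocks, per-cluster residue distributions are compared
column by column; a column whose distributions diverge strongly between at
least one cluster pair (normalized Jensen–Shannon divergence, base 2) is a
candidate subgroup-discriminating site.  Columns are reported in the
numbering of a designated reference sequence so they can be located on a
known structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .sequence_io import AMINO_ACIDS, GAP, Alignment

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class Block:
    start: int  # inclusive column
    end: int  # exclusive column

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("empty block")

    def __contains__(self, col: int) -> bool:
        return self.start <= col < self.end


@dataclass(frozen=True)
class LogoColumn:
    column: int
    frequencies: np.ndarray  # (20,)
    heights: np.ndarray  # (20,), bits
    total_height: float  # bits


@dataclass(frozen=True)
class SiteReport:
    column: int
    ref_number: int | None
    per_cluster_consensus: dict[str, tuple[str, ...]]  # residues at >= 20% freq
    divergence: float  # max pairwise normalized JSD, in [0, 1]
    annotation: str = ""


def column_gap_fraction(aln: Alignment, col: int) -> float:
    """Fraction of rows gapped at a column."""
    if not (0 <= col < aln.n_cols):
        raise IndexError(f"column {col} out of range [0, {aln.n_cols})")
    return sum(r.residues[col] == GAP for r in aln.rows) / len(aln.rows)


def extract_blocks(
    aln: Alignment, max_gap_frac: float = 0.9, min_len: int = 3
) -> list[Block]:
    """Maximal runs of qualifying columns, left to right.

    A column qualifies when its gap fraction is <= `max_gap_frac`
    (inclusive at the boundary); runs shorter than `min_len` are dropped.
    """
    qualifies = [
        column_gap_fraction(aln, c) <= max_gap_frac for c in range(aln.n_cols)
    ]
    blocks: list[Block] = []
    start: int | None = None
    for c, ok in enumerate(qualifies + [False]):
        if ok and start is None:
            start = c
        elif not ok and start is not None:
            if c - start >= min_len:
                blocks.append(Block(start, c))
            start = None
    return blocks


def cluster_column_frequencies(
    aln: Alignment,
    member_ids,
    col: int,
    pseudocount: float = 0.0,
) -> tuple[np.ndarray, bool]:
    """Gap-excluded residue frequencies of a column over a row subset.

    Returns ``(frequencies, all_gap)``; an all-gap column yields the uniform
    distribution with ``all_gap=True`` and a warning.
    """
    member_ids = list(member_ids)
    if not member_ids:
        raise ValueError("empty member set")
    counts = np.full(20, float(pseudocount))
    observed = 0
    for sid in member_ids:
        c = aln.row(sid).residues[col]
        i = _AA_INDEX.get(c)
        if i is not None:
            counts[i] += 1.0
            observed += 1
    if observed == 0 and pseudocount == 0.0:
        warnings.warn(f"column {col} is all-gap in this cluster", stacklevel=2)
        return np.full(20, 1 / 20), True
    return counts / counts.sum(), observed == 0


def kl_logo(
    freqs: np.ndarray, background: np.ndarray
) -> tuple[float, np.ndarray]:
    """Kullback–Leibler logo height of a column, in bits.

    Total height is the relative entropy of the column distribution against
    the background (clamped at 0); each letter's height is its frequency
    share of the total.
    """
    p = np.asarray(freqs, dtype=float)
    q = np.asarray(background, dtype=float)
    nz = p > 0
    total = float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))
    total = max(total, 0.0)
    return total, p * total


def logo_matrix(
    aln: Alignment, member_ids, background: np.ndarray, columns=None
) -> list[LogoColumn]:
    """KL logo columns for a cluster (all columns by default)."""
    if columns is None:
        columns = range(aln.n_cols)
    out = []
    for col in columns:
        freqs, _ = cluster_column_frequencies(aln, member_ids, col)
        total, heights = kl_logo(freqs, background)
        out.append(LogoColumn(col, freqs, heights, total))
    return out


def write_logo_tsv(columns: list[LogoColumn], path) -> None:
    """One row per column: index, 20 frequencies, 20 letter heights, total."""
    with open(path, "w") as fh:
        freq_cols = "\t".join(f"freq_{a}" for a in AMINO_ACIDS)
        height_cols = "\t".join(f"bits_{a}" for a in AMINO_ACIDS)
        fh.write(f"column\t{freq_cols}\t{height_cols}\ttotal_bits\n")
        for lc in columns:
            freqs = "\t".join(f"{x:.6g}" for x in lc.frequencies)
            heights = "\t".join(f"{x:.6g}" for x in lc.heights)
            fh.write(f"{lc.column}\t{freqs}\t{heights}\t{lc.total_height:.6g}\n")


def normalized_jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence, base 2, in [0, 1]."""
    return float(jensenshannon(p, q, base=2) ** 2)


def discriminating_sites(
    cluster_members: dict[str, list[str]],
    aln: Alignment,
    blocks: list[Block],
    jsd_threshold: float = 0.5,
    consensus_min_freq: float = 0.2,
    ref_numbering: dict[int, int] | None = None,
) -> list[SiteReport]:
    """Columns within blocks whose per-cluster residue distributions diverge.

    For every block column, each cluster's gap-excluded distribution is
    computed; the site's divergence is the maximum pairwise normalized JSD
    over cluster pairs (clusters that are all-gap at the column are left out
    of the comparison and flagged in the annotation).  Sites at or above
    `jsd_threshold` are reported in column order, with each cluster's
    consensus residues (frequency >= `consensus_min_freq`).
    """
    if len(cluster_members) < 2:
        raise ValueError("need at least two clusters")
    reports: list[SiteReport] = []
    for block in blocks:
        for col in range(block.start, block.end):
            dists: dict[str, np.ndarray] = {}
            omitted: list[str] = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for name, members in cluster_members.items():
                    freqs, all_gap = cluster_column_frequencies(aln, members, col)
                    if all_gap:
                        omitted.append(name)
                    else:
                        dists[name] = freqs
            if len(dists) < 2:
                continue
            names = sorted(dists)
            div = max(
                normalized_jsd(dists[a], dists[b])
                for i, a in enumerate(names)
                for b in names[i + 1 :]
            )
            if div < jsd_threshold:
                continue
            consensus = {
                name: tuple(
                    AMINO_ACIDS[i]
                    for i in np.argsort(dists[name])[::-1]
                    if dists[name][i] >= consensus_min_freq
                )
                for name in names
            }
            annotation = (
                f"all-gap in: {', '.join(sorted(omitted))}" if omitted else ""
            )
            reports.append(
                SiteReport(
                    column=col,
                    ref_number=(ref_numbering or {}).get(col),
                    per_cluster_consensus=consensus,
                    divergence=div,
                    annotation=annotation,
                )
            )
    reports.sort(key=lambda r: r.column)
    return reports


def map_to_reference(
    aln: Alignment, ref_id: str, offset: int = 1
) -> dict[int, int]:
    """Map alignment columns to the reference row's residue numbering.

    Columns where the reference is non-gap get consecutive numbers starting
    at `offset`; gap columns are absent from the map.
    """
    row = aln.row(ref_id)  # KeyError if missing
    mapping: dict[int, int] = {}
    number = offset
    for col, c in enumerate(row.residues):
        if c != GAP:
            mapping[col] = number
            number += 1
    return mapping
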