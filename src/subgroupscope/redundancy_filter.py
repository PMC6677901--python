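"""Greedy identity-threshold redundancy reduction (cd-hit style).

Records are sorted by decreasing length (ties broken by id) and scanned
once: each record joins the first existing representative it shares more
than `threshold` identity with, otherwise it founds a new cluster.  Identity
is the number of identities in an optimal global alignment divided by the
shorter sequence's (ungapped) length — the convention used by cd-hit.

The identity alignment scores match +1, mismatch 0, gap 0, so the optimal
score *is* the maximum attainable identity count.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .sequence_io import GAP, SequenceRecord


@dataclass(frozen=True)
class RedundancyResult:
    representatives: tuple[str, ...]
    membership: dict[str, str]  # seq_id -> representative id
    threshold: float


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity over the shorter sequence's length."""
    a, b = seq_a.replace(GAP, ""), seq_b.replace(GAP, "")
    if not a or not b:
        return 0.0
    if aligner is None:
        aligner = _identity_aligner()
    identities = aligner.score(a, b)
    return identities / min(len(a), len(b))


def _kmers(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    records: list[SequenceRecord],
    threshold: float = 0.5,
    seed: int = 0,
    prefilter: bool = True,
) -> RedundancyResult:
    """Greedy incremental clustering at an identity threshold.

    `seed` is accepted for interface uniformity with the stochastic stages;
    the algorithm itself is deterministic (length-then-id ordering).  With
    `prefilter`, pairs whose 5-mer containment implies an identity estimate
    below ``threshold - 0.2`` skip the alignment entirely.
    """
    del seed
    if not records:
        raise ValueError("no records to cluster")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    aligner = _identity_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.ungapped()), r.id))
    reps: list[SequenceRecord] = []
    rep_kmers: list[set[str]] = []
    membership: dict[str, str] = {}
    for rec in ordered:
        seq = rec.ungapped()
        km = _kmers(seq)
        assigned = False
        for rep, rkm in zip(reps, rep_kmers):
            if prefilter and km:
                shorter = min(km, rkm, key=len)
                containment = (
                    len(km & rkm) / len(shorter) if shorter else 0.0
                )
                # Mash-style containment -> identity estimate
                if containment ** 0.2 < threshold - 0.2:
                    continue
            if pairwise_identity(seq, rep.ungapped(), aligner) > threshold:
                membership[rec.id] = rep.id
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            rep_kmers.append(km)
            membership[rec.id] = rec.id
    return RedundancyResult(
        representatives=tuple(r.id for r in reps),
        membership=membership,
        threshold=threshold,
    )
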