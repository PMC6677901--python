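"""Synthetic chimeric-regulator datasets with known subgroup structure.

The generator emulates the structure of a real chimeric-regulator family:
``k`` effector-domain subgroups radiating from a common ancestor, strongly
diverged between subgroups (defaults land near 20% between-subgroup
identity) but coherent within them; long insertions/deletions; a shared
N-terminal HTH segment; taxon ("phylum") labels assigned independently of
subgroup so that subgroup structure cuts across taxonomy by construction;
and a family-labeled database in which some families are true relatives of
designated subgroups, for profile-search validation.

Substitutions are drawn from a BLOSUM-conditional neighbor distribution,
``p(b | a) ∝ q_b · 2^{s(a,b)}`` over ``b ≠ a``, so that substitution-matrix
distances stay meaningful even at high divergence.  Because the alignment
of every leaf to the root coordinate system is known by construction, the
generator emits a *true* master alignment — no aligner is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_search import FamilyDatabase
from .sequence_io import AMINO_ACIDS, GAP, Alignment, DomainSpan, SequenceRecord, load_matrix

PHYLA = (
    "Actinobacteria",
    "Alphaproteobacteria",
    "Bacteroidetes",
    "Betaproteobacteria",
    "Gammaproteobacteria",
    "Firmicutes",
)


@dataclass(frozen=True)
class GeneratorConfig:
    k_subgroups: int = 3
    n_per_subgroup: int = 50
    domain_length: int = 300
    root_mutation_rate: float = 0.85  # root -> subgroup ancestor
    leaf_mutation_rate: float = 0.15  # ancestor -> leaf
    indel_rate: float = 0.01  # per-site event probability in leaves
    max_indel_len: int = 12
    n_phyla: int = 6
    hth_length: int = 60
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("root_mutation_rate", "leaf_mutation_rate", "indel_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.k_subgroups < 2:
            raise ValueError("k_subgroups must be >= 2")
        if min(self.domain_length, self.hth_length, self.max_indel_len, self.n_per_subgroup) < 1:
            raise ValueError("lengths and counts must be >= 1")


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple[SequenceRecord, ...]  # full chimeras, unaligned
    spans: tuple[DomainSpan, ...]
    alignment: Alignment  # true master alignment of the AAT domains
    truth_subgroup: dict[str, int]
    phylum: dict[str, str]
    reference_ids: dict[int, str]  # subgroup -> designated reference record
    subgroup_ancestors: tuple[str, ...] = field(default=())
    config: GeneratorConfig | None = None


def _substitution_kernel(matrix_name: str = "BLOSUM62") -> np.ndarray:
    """(20, 20) conditional substitution distributions, zero on the diagonal."""
    m = load_matrix(matrix_name)
    idx = [m.index(a) for a in AMINO_ACIDS]
    scores = m.scores[np.ix_(idx, idx)]
    kernel = np.exp2(scores)
    np.fill_diagonal(kernel, 0.0)
    return kernel / kernel.sum(axis=1, keepdims=True)


_KERNEL: np.ndarray | None = None


def _kernel() -> np.ndarray:
    global _KERNEL
    if _KERNEL is None:
        _KERNEL = _substitution_kernel()
    return _KERNEL


def mutate(encoded: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability `rate` using the BLOSUM kernel."""
    out = encoded.copy()
    hit = np.flatnonzero(rng.random(encoded.size) < rate)
    if hit.size:
        kern = _kernel()
        cum = kern.cumsum(axis=1)
        u = rng.random(hit.size)
        out[hit] = np.array(
            [np.searchsorted(cum[a], x) for a, x in zip(encoded[hit], u)]
        )
    return out


def _decode(encoded: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in encoded)


def _geometric_len(rng: np.random.Generator, max_len: int, p: float = 0.35) -> int:
    return int(min(rng.geometric(p), max_len))


def generate_dataset(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Sample a full dataset: chimera records, spans, true alignment, labels."""
    if cfg is None:
        cfg = GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    background = rng.dirichlet(np.full(20, 5.0))
    length = cfg.domain_length
    root = rng.choice(20, size=length, p=background)
    hth_root = rng.choice(20, size=cfg.hth_length, p=background)
    ancestors = [
        mutate(root, cfg.root_mutation_rate, rng) for _ in range(cfg.k_subgroups)
    ]
    phyla = PHYLA[: cfg.n_phyla] if cfg.n_phyla <= len(PHYLA) else tuple(
        f"Phylum{i + 1}" for i in range(cfg.n_phyla)
    )

    # leaves: residues per root position (-1 = deleted), insertions after a
    # root position; alignment is reconstructed exactly from this history
    leaves: list[tuple[str, int, np.ndarray, dict[int, np.ndarray]]] = []
    for g, anc in enumerate(ancestors):
        for i in range(cfg.n_per_subgroup):
            seq = mutate(anc, cfg.leaf_mutation_rate, rng)
            residues = seq.astype(np.int64)
            insertions: dict[int, np.ndarray] = {}
            pos = 0
            while pos < length:
                if rng.random() < cfg.indel_rate:
                    ell = _geometric_len(rng, cfg.max_indel_len)
                    if rng.random() < 0.5:  # deletion
                        residues[pos : pos + ell] = -1
                        pos += ell
                        continue
                    insertions[pos] = rng.choice(20, size=ell, p=background)
                pos += 1
            leaves.append((f"sg{g + 1}_{i:03d}", g, residues, insertions))

    ins_width = np.zeros(length, dtype=int)
    for _, _, _, ins in leaves:
        for pos, res in ins.items():
            ins_width[pos] = max(ins_width[pos], len(res))

    records: list[SequenceRecord] = []
    spans: list[DomainSpan] = []
    aligned_rows: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    phylum: dict[str, str] = {}
    for name, g, residues, ins in leaves:
        row_parts: list[str] = []
        for pos in range(length):
            row_parts.append(GAP if residues[pos] < 0 else AMINO_ACIDS[residues[pos]])
            if ins_width[pos]:
                inserted = _decode(ins.get(pos, np.empty(0, dtype=int)))
                row_parts.append(inserted.ljust(ins_width[pos], GAP))
        aligned = "".join(row_parts)
        aat = aligned.replace(GAP, "")
        hth = _decode(mutate(hth_root, cfg.leaf_mutation_rate, rng))
        records.append(SequenceRecord(name, hth + aat))
        spans.append(DomainSpan(name, "HTH", 0, cfg.hth_length))
        spans.append(DomainSpan(name, "AAT", cfg.hth_length, cfg.hth_length + len(aat)))
        aligned_rows.append(SequenceRecord(name, aligned))
        truth[name] = g
        phylum[name] = phyla[rng.integers(len(phyla))]

    reference_ids = {
        g: f"sg{g + 1}_000" for g in range(cfg.k_subgroups)
    }
    return SyntheticDataset(
        records=tuple(records),
        spans=tuple(spans),
        alignment=Alignment(tuple(aligned_rows)),
        truth_subgroup=truth,
        phylum=phylum,
        reference_ids=reference_ids,
        subgroup_ancestors=tuple(_decode(a) for a in ancestors),
        config=cfg,
    )


def generate_family_db(
    n_families: int = 4,
    n_per_family: int = 25,
    length: int = 300,
    divergence: float = 0.3,
    seed: int = 1,
    seed_ancestors: dict[str, str] | None = None,
) -> FamilyDatabase:
    """Family-labeled sequence database with known memberships.

    `seed_ancestors` maps family names to ancestor sequences (e.g. the
    subgroup ancestors of a generated dataset), creating one true-relative
    family per provided ancestor; remaining families get independent random
    ancestors named ``bgfam<N>``.
    """
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    rng = np.random.default_rng(seed)
    background = rng.dirichlet(np.full(20, 5.0))
    seed_ancestors = seed_ancestors or {}
    if len(seed_ancestors) > n_families:
        raise ValueError("more seed ancestors than families")
    families: list[tuple[str, np.ndarray]] = []
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for name, anc in seed_ancestors.items():
        families.append((name, np.array([aa_index[c] for c in anc if c in aa_index])))
    for j in range(n_families - len(seed_ancestors)):
        families.append((f"bgfam{j + 1}", rng.choice(20, size=length, p=background)))
    records: list[SequenceRecord] = []
    family_of: dict[str, str] = {}
    for name, anc in families:
        for i in range(n_per_family):
            sid = f"{name}_{i:03d}"
            records.append(SequenceRecord(sid, _decode(mutate(anc, divergence, rng))))
            family_of[sid] = name
    return FamilyDatabase(tuple(records), family_of)
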