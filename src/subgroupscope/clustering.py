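"""K-means clustering in MDS space with silhouette-based selection of the
cluster number and a residue-randomization null control.

The null control answers the question "how high a silhouette could this
procedure reach on sequences with the same composition but no subgroup
structure?": within each aligned row the non-gap residues are permuted
among that row's non-gap positions (gap architecture fixed), the whole
distance → MDS → K-sweep procedure is re-run, and the peak silhouette over
K is recorded.  A real dataset with genuine subgroups should beat that peak
by a clear margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .distance_mds import classical_mds, score_distance_matrix
from .sequence_io import GAP, Alignment, SequenceRecord, SubstitutionMatrix

DEFAULT_SEED = 1331


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray  # (n,) cluster indices
    centroids: np.ndarray  # (K, m)
    inertia: float
    seed: int
    restarts: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def label_map(self, ids) -> dict[str, int]:
        return {i: int(c) for i, c in zip(ids, self.labels)}


@dataclass(frozen=True)
class ModelSelection:
    k_range: tuple[int, int]
    silhouette_by_k: dict[int, float]
    best_k: int
    null_silhouette_by_k: dict[int, float] = field(default_factory=dict)
    null_peak: float = float("nan")


def _kmeanspp_init(coords: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = coords.shape[0]
    centers = [coords[rng.integers(n)]]
    for _ in range(1, k):
        d2 = cdist(coords, np.array(centers)).min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            centers.append(coords[rng.integers(n)])
            continue
        centers.append(coords[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _lloyd(
    coords: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, debug: bool
) -> tuple[np.ndarray, np.ndarray, float]:
    centers = _kmeanspp_init(coords, k, rng)
    labels = np.full(coords.shape[0], -1)
    prev_inertia = np.inf
    for _ in range(max_iter):
        dists = cdist(coords, centers)
        new_labels = dists.argmin(axis=1)
        # re-seed empty clusters from the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = dists[np.arange(len(new_labels)), new_labels].argmax()
                centers[c] = coords[far]
                new_labels[far] = c
        inertia = float(
            ((coords - centers[new_labels]) ** 2).sum()
        )
        if debug:
            assert inertia <= prev_inertia + 1e-8, "inertia increased"
        prev_inertia = inertia
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = coords[labels == c].mean(axis=0)
    dists = cdist(coords, centers)
    labels = dists.argmin(axis=1)
    inertia = float(((coords - centers[labels]) ** 2).sum())
    return labels, centers, inertia


def kmeans(
    coords: np.ndarray,
    k: int,
    seed: int = DEFAULT_SEED,
    restarts: int = 25,
    max_iter: int = 300,
    debug: bool = False,
) -> ClusteringResult:
    """Lloyd's algorithm with k-means++ initialization, best of `restarts`."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        labels, centers, inertia = _lloyd(coords, k, rng, max_iter, debug)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    labels, centers, inertia = best
    return ClusteringResult(labels, centers, inertia, seed, restarts)


def silhouette(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score, Euclidean metric.

    Per point: s = (b - a) / max(a, b) with a the mean distance to the
    point's own cluster (excluding itself) and b the smallest mean distance
    to another cluster.  Members of singleton clusters contribute 0.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    d = cdist(coords, coords)
    n = coords.shape[0]
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    scores = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue  # singleton convention: s = 0
        a = d[i, labels == c].sum() / (sizes[c] - 1)
        b = min(d[i, labels == o].mean() for o in uniq if o != c)
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def select_k(
    coords: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = DEFAULT_SEED,
    restarts: int = 25,
) -> ModelSelection:
    """Sweep K, score each partition by mean silhouette, pick the argmax.

    Ties go to the smallest K (parsimony).
    """
    n = np.asarray(coords).shape[0]
    if not (2 <= k_min <= k_max < n):
        raise ValueError("require 2 <= k_min <= k_max < n")
    by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        result = kmeans(coords, k, seed=seed, restarts=restarts)
        by_k[k] = silhouette(coords, result.labels)
    best_k = max(sorted(by_k), key=lambda k: by_k[k])
    return ModelSelection((k_min, k_max), by_k, best_k)


def randomize_rows(aln: Alignment, seed: int = DEFAULT_SEED) -> Alignment:
    """Permute each row's non-gap residues among its non-gap positions."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in aln.rows:
        chars = np.array(list(rec.residues))
        idx = np.flatnonzero(chars != GAP)
        chars[idx] = chars[rng.permutation(idx)]
        rows.append(SequenceRecord(rec.id, "".join(chars), rec.description))
    return Alignment(tuple(rows))


def null_control(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = DEFAULT_SEED,
    n_replicates: int = 3,
    mds_components: int = 3,
    restarts: int = 25,
) -> tuple[dict[int, float], float]:
    """Silhouette-by-K averaged over residue-randomized replicates.

    Returns ``(null_silhouette_by_k, null_peak)``.  If randomization leaves
    the distances degenerate (e.g. an alignment of identical rows), the
    replicate is skipped with a warning; with no usable replicate the result
    is empty with NaN peak.
    """
    acc: dict[int, list[float]] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        shuffled = randomize_rows(aln, seed=rep_seed)
        dist = score_distance_matrix(shuffled, matrix)
        if dist.d.max() < 1e-12:
            warnings.warn(
                "randomized distances are degenerate (identical rows?); "
                "replicate skipped",
                stacklevel=2,
            )
            continue
        proj = classical_mds(dist)
        coords = proj.coords[:, : min(mds_components, proj.coords.shape[1])]
        sel = select_k(coords, k_min, k_max, seed=rep_seed, restarts=restarts)
        for k, s in sel.silhouette_by_k.items():
            acc.setdefault(k, []).append(s)
    by_k = {k: float(np.mean(v)) for k, v in sorted(acc.items())}
    peak = max(by_k.values()) if by_k else float("nan")
    return by_k, peak


def name_clusters(
    label_map: dict[str, int],
    references: dict[str, str],
    priority: list[str],
) -> dict[int, str]:
    """Name each cluster after the highest-priority reference it contains.

    Clusters without a reference (or whose best reference name is already
    taken) fall back to ``cluster<N>``.
    """
    rank = {name: i for i, name in enumerate(priority)}
    clusters = sorted(set(label_map.values()))
    names: dict[int, str] = {}
    taken: set[str] = set()
    for c in clusters:
        members = [i for i, lab in label_map.items() if lab == c]
        refs = sorted(
            (references[i] for i in members if i in references),
            key=lambda nm: rank.get(nm, len(rank)),
        )
        name = f"cluster{c}"
        if refs:
            if refs[0] in taken:
                warnings.warn(
                    f"reference name {refs[0]!r} already used; cluster {c} "
                    f"falls back to {name!r}",
                    stacklevel=2,
                )
            else:
                name = refs[0]
        names[c] = name
        taken.add(name)
    return names
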