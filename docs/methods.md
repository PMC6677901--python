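# Methods

This note documents the models, parameter choices and numerical
conventions behind `subgroupscope`, and what the synthetic benchmarks do
and do not demonstrate.

## Problem setting

MocR-type regulators are chimeras: an N-terminal winged helix-turn-helix
(wHTH) DNA-binding domain fused to a C-terminal aminotransferase-like
(AAT, fold type-I PLP-dependent) effector domain. The analysis asks
whether the effector domains of a large, redundancy-filtered collection
fall into subgroups, whether those subgroups cut across taxonomy, which
enzyme families each subgroup resembles, and which alignment positions
discriminate the subgroups. The package operates downstream of domain
annotation and alignment: domain coordinates and the master alignment are
inputs (producing them with rps-blast/CDD and clustal omega is out of
scope), and a `--realign` hook exists but deliberately errors.

## Sequence handling

Residues are upper-cased; `.` is normalized to `-`; the rare codes
B/Z/J/U/O and `*` collapse to the unknown residue `X`, which scores 0
against everything when a matrix lacks it. All coordinates are 0-based and
half-open, including the domain-span TSV interface. Domain splitting
enforces the chimeric architecture: exactly one HTH span strictly before
one AAT span, anything else being a rejection (a distinct error type from
I/O failures, so pipelines can count rejected sequences).

## Redundancy filtering

A cd-hit-style greedy scan: records sorted by decreasing length (ties by
id) join the first representative with identity above the threshold
(default 0.5), where identity is the number of identities in an optimal
global alignment divided by the shorter sequence's length. The identity
alignment uses match +1, mismatch 0, gap 0, so the alignment score *is*
the maximal identity count — identity, not similarity. An optional 5-mer
containment prefilter (Mash-style estimate `containment^(1/5)`) skips
alignments when the estimate falls below `threshold − 0.2`; its
correctness is guarded by a brute-force all-pairs oracle test rather than
by a bound. Exact replication of cd-hit's banded heuristics is a non-goal.

## Distances and embedding

The dissimilarity between aligned rows is
`d_ij = 1 − 2 s_ij / (s_ii|C + s_jj|C)`, clamped to [0, 2], with all
scores summed over the pair's co-ungapped columns `C`. Restricting the
self-scores to `C` makes the distance 0 exactly when two rows agree on
every shared column, regardless of gap architecture; pairs with no shared
column get the maximal distance 2, as do pairs whose shared-column
self-scores are non-positive (pathological matrices; warned). The formula
is this package's construction: a bounded, symmetric, matrix-driven
dissimilarity that vanishes for identical sequences.

Classical MDS follows Torgerson: `B = −½ J D² J`, eigendecomposition,
coordinates `v_k √λ_k` for positive eigenvalues (default: all positive
ones, capped at 10). Sign convention: the largest-magnitude entry of each
component is positive, making embeddings deterministic. On
Euclidean-realizable distances the embedding reproduces all pairwise
distances to < 1e-8 (tested at n = 50 in 3-D). Downstream clustering uses
the first three components, matching how such sequence-space projections
are usually read; this is configurable.

## Clustering and model selection

K-means is Lloyd's algorithm with k-means++ seeding, 25 restarts by
default, empty clusters re-seeded from the point farthest from its
centroid, convergence on stable assignments or 300 iterations, and an
in-loop assertion (debug flag) that inertia never increases. Silhouette
uses Euclidean distances in the embedding; members of singleton clusters
contribute exactly 0. The K sweep (default 2–10) picks the silhouette
argmax, ties to the smaller K (parsimony).

The null control permutes each row's non-gap residues among that row's
non-gap positions — composition and gap architecture preserved — and
re-runs distances → MDS → K sweep, averaging silhouettes over 3
replicates. Shuffling within rows (rather than columns, or permuting
labels) was chosen as the most conservative null that does not require
re-alignment: it destroys positional signal while keeping everything a
composition-only explanation could use. An alignment that randomization
leaves degenerate (e.g. identical rows) is flagged and skipped with a
warning rather than an error.

Default seed 1331 throughout; every stochastic function takes an explicit
seed.

## Profile model and E-values

Profiles are match-state PSSMs, not full Plan7 HMMs: no insert-state
emissions, no Forward algorithm. Match columns are those with gap
fraction ≤ 0.5 (hmmbuild-like column assignment; configurable). Henikoff
position-based weights (gaps counted as a type) feed weighted counts,
smoothed with background-proportional pseudocounts
`p̂_a = (c_a + α q_a n_eff)/(n_eff(1 + α))`, α = 0.5, and converted to
base-2 log-odds. Searching uses best local alignment by dynamic
programming with affine gaps (open −11, extend −1, the classic protein
defaults); the batch scorer is vectorized over sequences with a
running-maximum formulation of the in-row gap state and is verified
against an exhaustive path-enumeration oracle on small problems.

Score statistics: decoys drawn i.i.d. from the background (default: the
search database's residue frequencies) at a fixed length, Gumbel fitted
by method of moments (`λ = π/(σ√6)`, `μ = mean − γ/λ`), and
`E = N·(1 − exp(−exp(−λ(score − μ))))`. Method of moments was preferred
to ML for determinism and closed form; at the default 200 decoys it is
accurate enough that among 1000 fresh background decoys the number of
E < 1 hits stays within a Poisson(1)-like band (observed 0–2). The hit
table keeps E < 0.1 and reports each family's percentage of kept hits
(per-profile hit share, summing to 100).

## Blocks, logos, discriminating sites

A conserved block is a maximal run of ≥3 consecutive columns with gap
fraction ≤ 0.9 — the boundary is inclusive, so a column with exactly 90%
gaps qualifies. Logo heights are Kullback–Leibler: total column height
`Σ p log2(p/q)` (clamped at 0), letter heights proportional to frequency;
gaps are excluded from column distributions. Rendering fidelity to any
particular logo server is a non-goal; logos are emitted as TSV matrices.

Site discrimination uses the maximum pairwise normalized Jensen–Shannon
divergence (base 2, range [0, 1]) between per-cluster column
distributions, reported at ≥0.5 by default, with per-cluster consensus
residues at ≥20% frequency. JSD was chosen over visual logo comparison to
make the call thresholdable and testable; it is symmetric and bounded.
Clusters that are all-gap at a column are omitted from that column's
comparison and flagged. Reference numbering maps columns to consecutive
residue numbers of a designated reference row, with a user-supplied
offset (e.g. to match a crystal structure's construct numbering); PDB
parsing is out of scope.

## Synthetic data generator

The generator emulates the *post-filtering* state of a real chimeric
regulator dataset: `k = 3` subgroups × 50 leaves, effector-domain length
300, a shared HTH segment of 60 residues, six taxon labels assigned
independently of subgroup. A root sequence drawn from a
Dirichlet-perturbed background yields subgroup ancestors at substitution
rate 0.85 per site, and leaves at 0.15, with per-site indel events at
0.01 (geometric lengths, capped at 12; insertions and deletions equally
likely). Substitutions are drawn from a BLOSUM62-conditional neighbor
distribution `p(b|a) ∝ 2^{s(a,b)}` over `b ≠ a`, so high divergence still
leaves matrix-visible similarity. Under these defaults the mean
between-subgroup identity of the generated domains is ≈10–15%,
within the intended "around 20%" twilight-zone regime, and
within-subgroup identity ≈70%. Because every leaf's history relative to
the root is known, the generator emits the *true* master alignment;
passing tests therefore demonstrate recovery under a correct alignment,
not robustness to alignment error — the main respect in which the
synthetic benchmark is easier than real data. Real datasets also bring
alignment uncertainty, non-uniform taxon sampling, and families whose
divergence is not clocklike; none of these are modeled.

The family database generator plants one true-relative family per
subgroup (members mutated from the subgroup ancestor at rate 0.3) plus
independent background families, giving profile search a known correct
ranking.

One consequence of "the generator models post-filter data": running the
pipeline's 50% redundancy filter on synthetic data would filter twice and
collapse each subgroup to about one representative. Pipeline runs on
synthetic data therefore set `identity_threshold: 0.9` (trimming only
near-duplicates), while the default for real, unfiltered input remains
0.5.

## Problem sizes and determinism

Test and acceptance runs use the generator defaults (150 sequences,
domain length 300, ~870 alignment columns), ten generator seeds for the
recovery sweep, 200 calibration decoys per profile, a 100-sequence
4-family search database, and 1000 decoys for the E-value check — sizes
at which every stage completes in seconds while all structural claims
(K recovery, null separation, family ranking) remain non-trivial. All
randomness flows from explicit seeds; a pipeline run with a fixed seed
reproduces its summary byte for byte.

## Known limitations

- The profile model scores Viterbi-style best alignments; families whose
  similarity is spread over many suboptimal alignments (where Forward
  sums matter) will be under-scored relative to HMMER.
- Gumbel calibration assumes approximately Gumbel-distributed local
  scores; strongly biased-composition queries may mis-calibrate.
- The distance formula is declared, not derived from any published
  package's internals; other bounded dissimilarities would order pairs
  slightly differently.
- The greedy redundancy filter reproduces cd-hit's semantics, not its
  exact cluster boundaries.
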