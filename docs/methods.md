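# Methods

This note documents the models, numerical choices, and defaults behind
`nmfem`, and what the synthetic-data tests do and do not establish about
real data.

## Preprocessing

**FPKM.** For read-count input, `FPKMᵢⱼ = countsᵢⱼ · 10⁹ / (lengthᵢ ·
totalⱼ)` with `totalⱼ` the sample's column sum. Gene length is the number of
bases covered by the union of the gene's exon intervals (1-based inclusive;
overlapping and adjacent exons merged so shared bases count once — a raw sum
would inflate lengths of genes with many overlapping isoform exons). UMI
molecule-count matrices skip FPKM conversion entirely: the counts are
already amplification-free and all downstream stages only require
non-negativity.

**Size factors.** Median-of-ratios normalization: reference genes are those
positive in every sample; sample j's factor is the median over reference
genes of `valueᵢⱼ / geomeanᵢ` (an even count of reference genes takes the
arithmetic mean of the two central ratios), and factors are rescaled to
geometric mean 1 so normalization never changes the overall scale. If no
gene is positive in all samples the step fails with advice to add a
pseudocount or skip it.

**Filters.** Samples first, then genes, so gene zero-fractions are computed
on retained samples only; the combination is a fixed point (re-applying it
changes nothing). A sample is kept iff the geometric mean of its expression
over the housekeeping genes present in the matrix is ≥ 4 (FPKM units by
default; configurable). The geometric mean of a set containing a zero is
defined as 0 — no pseudocount — which deliberately makes the filter strict:
a cell failing to express *any* housekeeping gene is degraded. A gene is
kept iff it is expressed (non-zero) in at least 30% of cells (zero fraction
≤ 0.7; the boundary value is kept). A default mouse housekeeping list ships
with the package; analyses in other namespaces should supply their own.

## KL-NMF and consensus clustering

Multiplicative updates preserve non-negativity and never increase the
generalized KL divergence. A floor of 1e-16 is added inside the `(WH)`
denominators and at initialization, the standard guard against division by
zero and absorbing zeros in multiplicative updates. `W` and `H` are
initialized uniformly on `[ε, max(A)]` from a seeded generator, so every
fit is bitwise reproducible.

**Stopping rule.** The default is connectivity stationarity: stop once the
argmax-of-H cluster assignment has not changed for 40 consecutive
iterations (checked every 10), capped at 2,000 iterations. This is the
convention of the original consensus-NMF implementations, and it is the
right criterion for a *clustering* use of NMF: the assignment typically
freezes long before the divergence flattens (an order of magnitude fewer
iterations), and further updates only polish `W`/`H` entries without moving
any sample. A divergence-based rule (relative KL decrease over 10 iterations
below 1e-6) is available as `stop="divergence"` for factorization-accuracy
work. The divergence trace is recorded at every check in either mode and is
non-increasing.

**Consensus.** Each of `n_runs = 30` restarts (seeds `base_seed + r`) votes
1 for every co-clustered cell pair; the consensus matrix of voting
frequencies is symmetric with unit diagonal. Final labels cut an
average-linkage tree on `1 − consensus` into k groups. The cophenetic
correlation between those distances and the tree's cophenetic distances
measures how block-like the consensus is; the rank scan (default 2..5, the
practical range — larger k multiplies runtime and rarely adds stable
structure) picks the k with the best coefficient, ties to the smaller k.
Each rank uses a disjoint seed block so restarts are independent across
ranks. If all pairwise consensus distances are equal the correlation is
undefined and reported as 1 (any tree fits perfectly). NMF runs on the
linear-scale normalized matrix, not log-transformed: the factorization
itself requires non-negativity and the multiplicative model is scale-aware.
`W`/`H` columns are not rescaled after fitting; the D-score consumes them
as produced, which keeps rankings reproducible.

## D-score

`Dᵢ = |λ·Wᵢ₁ − (1−λ)·Wᵢ₂|` for a rank-2 factorization. The defining
requirement is that a uniformly expressed gene scores 0; the minimal
construction realizing it is to project the all-ones sample profile onto
the rows of `H` by non-negative least squares, obtaining loadings
`(u₁, u₂)`, and set `λ = u₂/(u₁+u₂)`, which zeroes `λu₁ − (1−λ)u₂`
identically. Swapping the two factors maps λ → 1−λ and leaves every Dᵢ
unchanged. At a boundary (`u₁ = 0`) λ = 1, which is the unique value
zeroing the score of a gene loading only on factor 2. The score is defined
for k = 2 only; for multi-group data the pipeline first isolates the
closest pair of groups (smallest centroid distance on the 2-D correlation
t-SNE embedding) and refits at rank 2. Ranking ties break by gene id for
determinism.

Because the score is a difference of absolute loadings, it scales with
expression: very low-expressed genes cannot achieve large loadings, and
very high uniformly expressed genes have balanced loadings — the ranking
therefore favors genes of intermediate, group-specific expression.

## Clustering benchmark

Methods: NMF (per-run seeded fit + argmax labels), K-means (2 clusters,
random initialization seeded per run, single start so run-to-run variance
is visible), and three deterministic hierarchical variants cut at 2 groups
(Euclidean+complete, Euclidean+Ward, correlation-distance+complete). The
Rand measure counts unordered sample pairs: positive = co-clustered by the
tested method, true = agreement with the reference; `R = (TP+TN)/(m(m−1)/2)`.
Each method's 30 per-run Rand values are compared with the NMF reference by
a two-sided Welch unequal-variance t-test; "significantly worse" means
p < 0.05 with a lower mean. When both arrays are constant (ceiling case)
the p-value is reported as 1 — no evidence of a difference. The optional
t-SNE arm embeds samples on pairwise correlation distances (perplexity
min(30, ⌊(m−1)/3⌋), seeded per run) and feeds the 2-D coordinates to every
method; for NMF the coordinates are shifted by their global minimum (plus
1e-9) to restore non-negativity, since t-SNE output is signed and the
handling is otherwise unconstrained.

## Module detection

Vertices carry Welch t-statistics of the log2(x+1) expression difference
(second group minus first; log2(x+1) stabilizes count variance and keeps
zeros finite; zero-variance genes get t = 0). From each seed gene a module
grows greedily by adding the boundary vertex that most increases
`s(M) = Σ_{i∈M}|tᵢ| / √|M|`, stopping when no addition strictly increases
the score or at 50 members. The √|M| normalization is the standard
subnetwork-scoring compromise between total weight (which favors sprawling
modules) and mean weight (which refuses all growth); it is configurable in
spirit — the scorer is one function. Significance: permute the t-values
across all vertices, regrow from the same seed, and report the add-one
estimator `p = (1 + #{null ≥ observed})/(n_perm + 1)`, which is never below
`1/(n_perm+1)` and is uniform under an exchangeable null (verified by
Kolmogorov–Smirnov distance in the tests). Modules from the top-500 seed
list sharing > 50% of the smaller module's members are deduplicated keeping
the lower p-value; the top 5 by p-value (ties: higher score) are reported
with their hubs (highest within-module degree, ties by gene id).

## Synthetic data generator

`simulate_populations` emulates the structure of droplet/plate scRNA-Seq
experiments with known truth. Per-gene log2 base means are Normal(3, 2)
clipped to [0.25, 9]; each group up-shifts its own marker subset (default
5% of genes at 2 log2-fold) drawn from the intermediate-expression band
(log2 mean 3–5) — deliberately, because that is the regime the D-score
favors and where the interesting selection behavior lives. Counts are
negative-binomial with size `r = 1 + μ/2`, so `CV² = 1/μ + 1/r` falls with
the mean (low-expression genes are noisiest), scaled by a per-cell
log-normal library factor (sd 0.2 log2 units). Dropout is logistic in
log2(μ+1) with midpoint 1.5 and scale 0.7: essentially certain loss below
~1 count, negligible above ~16. Twenty housekeeping genes sit at log2 mean
8 with no dropout so the housekeeping sample filter retains every intended
cell. Defaults (2,000 genes, 50 cells per group) give a dataset in which
the planted split is recoverable but K-means is measurably worse — the
regime of interest.

What the generator does *not* model: batch effects, library-size
confounding beyond the scalar per-cell factor, UMI collision statistics,
gene–gene correlation beyond the group structure, and doublets. Passing
tests therefore demonstrate correctness of the algorithms under a clean
noise model, not performance on any particular real dataset; real-data
Rand measures depend on the upstream alignment/counting pipeline and on
biological confounders outside this package's scope.

`simulate_ppi` plants a densified connected subgraph (edge probability 0.6,
regenerated until connected) in an Erdős–Rényi background (default 300
nodes, edge probability 0.02), matching the sparse-with-dense-communities
shape of curated PPI networks at test scale.

## Problem sizes in the test suite

The end-to-end clustering check runs the full stated protocol — 20
generator seeds × (30-run consensus at k = 2 plus a 30-run scan over
k = 2..5) on 2,000 × 100 matrices, about 3,000 NMF fits — which the
buffer-reusing update loop completes in under ten minutes on one CPU.
Other checks use smaller instances (50 random matrices up to 200 × 50 for
monotonicity; 150-node graphs with 999 permutations for module recovery;
200 × 100-permutation null runs for p-value calibration) chosen to exercise
the contracts rather than to stress hardware. `scripts/acceptance.py` runs
one full-size replicate of each analysis (~half a minute).

## Known limitations

- Cophenetic rank selection can tie at 1.0 for nested structure (a
  perfectly stable coarse split of a finer partition); ties resolve to the
  smaller k, which is conservative.
- The D-score is defined only for rank 2; multi-group data are reduced to
  their closest pair first, and genes distinguishing the *other* groups are
  invisible to that ranking.
- The greedy module search is seed-anchored and myopic; it can miss a
  high-scoring module reachable only through a low-weight bridge vertex.
- Monte Carlo p-values are permutation-based and ignore the network's
  degree structure under the null (weights are exchanged freely across
  vertices of different degree).
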