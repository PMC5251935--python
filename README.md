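# nmfem

Detecting heterogeneity in single-cell RNA-Seq data by non-negative matrix
factorization: unsupervised subpopulation discovery via consensus KL-NMF,
feature-gene ranking by the D-score, clustering benchmarking with the
pair-counting Rand measure, and seeded module detection on protein–protein
interaction (PPI) networks.

## Who this is for

Analysts with a gene × cell expression matrix (raw counts, FPKM, or UMI
molecule counts) who want to (1) find subpopulations among superficially
similar cells without pre-assigned labels, (2) extract the genes that drive
the separation, and (3) place those genes in their interactome context.
Distance-based methods (K-means, hierarchical clustering) struggle when
groups are close and data are noisy; a parts-based factorization is less
sensitive to initial gene selection and captures broad expression-pattern
shifts rather than single-gene differences.

## The model

The expression matrix `A` (n genes × m cells, non-negative) is approximated
by `A ≈ WH` with `W` (n × k) and `H` (k × m) non-negative. Columns of `W`
are *meta-genes*; row i of `W` holds gene i's *loadings*; cell u is assigned
to the meta-gene maximizing `H[:, u]`. Fitting minimizes the generalized
Kullback–Leibler divergence

```
D(A‖WH) = Σᵢⱼ [ Aᵢⱼ log(Aᵢⱼ/(WH)ᵢⱼ) − Aᵢⱼ + (WH)ᵢⱼ ]
```

with the classical multiplicative updates

```
H_au ← H_au · [Σᵢ W_ia A_iu / (WH)_iu] / Σ_k W_ka
W_ia ← W_ia · [Σ_u H_au A_iu / (WH)_iu] / Σ_v H_av
```

Because restarts are random, clustering is *consensus-based*: 30 seeded
restarts vote on co-clustering of every cell pair, the consensus matrix is
cut with an average-linkage tree, and the rank k (scanned over 2..5) is
chosen by the best cophenetic correlation coefficient.

For a rank-2 factorization, gene importance is the **D-score**

```
Dᵢ = | λ·W_i1 − (1−λ)·W_i2 |
```

with λ calibrated so a uniformly expressed gene scores exactly 0 (the
constant profile is projected onto the rows of H by non-negative least
squares, giving loadings u₁, u₂, and λ = u₂/(u₁+u₂)). The top 500 D-score
genes seed a greedy module search on a PPI network in which each vertex is
weighted by the Welch t-statistic of its log2 expression change between the
two groups; module significance is a Monte Carlo permutation p-value.

## Worked example

Simulate a two-population dataset with 100 planted marker genes, then run
the full workflow (preprocess → consensus clustering with rank scan →
D-score ranking):

```
nmfem simulate --genes 2000 --cells 100 --seed 1 -o sim
nmfem run --counts sim/counts.tsv --seed 1 -o out
```

which prints

```
wrote sim/counts.tsv (2000 genes x 100 cells)
done; chosen k = 2; manifest at out/manifest.json
```

`out/manifest.json` records 1,769 genes surviving the zero-fraction filter,
cophenetic coefficients `{2: 1.000, 3: 0.999, 4: 0.997, 5: 0.990}` (hence
k = 2: the two-group split is perfectly reproducible across restarts while
finer splits are not), and λ = 0.504. The head of `out/genes.tsv`:

```
gene_id   loading_1   loading_2    d_score  rank
 G00349 1951.212129    1.029820 982.865126     1
 G01730    1.805327 1971.572527 977.025464     2
 G00701 1932.918484   16.993043 965.727412     3
 G01630    1.193384 1920.879803 952.189373     4
 G01763    5.998417 1924.339059 951.483575     5
```

Top-ranked genes load almost entirely on one meta-gene — they are expressed
in one subpopulation and silent in the other. All 100 planted markers land
in the top-500 feature list. With a PPI edge list (`--graph ppi.tsv`) the
pipeline additionally writes the top modules with per-gene t-statistics,
hub genes, and permutation p-values.

The same stages are available as a library (`nmfem.KLNMF`,
`nmfem.consensus_cluster`, `nmfem.select_rank`, `nmfem.dscore.rank_genes`,
`nmfem.evaluation.benchmark_clustering`, `nmfem.modules.detect_modules`,
`nmfem.simulate.simulate_populations`); `KLNMF` follows the scikit-learn
estimator convention (`fit`, `fit_transform`, `get_params`, fitted
attributes `W_`, `H_`, `labels_`, `divergence_trace_`).

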