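"""Clustering benchmarks: pair-counting Rand measure, correlation t-SNE,
closest-pair identification, and the multi-method comparison harness.

The Rand measure counts unordered sample pairs.  A *positive* pair is one
the tested method places in the same cluster; *true* means the decision
agrees with the reference partition:

    R = (TP + TN) / (TP + FP + FN + TN),   TP+FP+FN+TN = m(m-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, ttest_ind
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics.cluster import pair_confusion_matrix

from nmfem.nmf import fit_nmf

__all__ = [
    "PairConfusion",
    "rand_index",
    "correlation_distance",
    "embed_2d",
    "closest_pair",
    "BenchmarkReport",
    "benchmark_clustering",
    "BENCHMARK_METHODS",
]


@dataclass
class PairConfusion:
    """Unordered-pair confusion counts between a test and a reference clustering."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def R(self) -> float:
        """The Rand measure (TP + TN) / all pairs."""
        return (self.TP + self.TN) / self.total


def rand_index(test_labels, ref_labels) -> PairConfusion:
    """Pair-counting Rand confusion of a test clustering against a reference.

    Positive = pair co-clustered by the test; true = the test's same/different
    call matches the reference.  Label names are irrelevant.
    """
    test = np.asarray(test_labels)
    ref = np.asarray(ref_labels)
    if test.shape != ref.shape or test.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if test.size < 2:
        raise ValueError("need at least 2 samples")
    # pair_confusion_matrix counts ordered pairs: C[same_in_ref, same_in_test]
    C = pair_confusion_matrix(ref, test)
    return PairConfusion(TP=int(C[1, 1] // 2), FP=int(C[0, 1] // 2),
                         FN=int(C[1, 0] // 2), TN=int(C[0, 0] // 2))


def correlation_distance(x, y) -> float:
    """d_c(x, y) = 1 - Pearson correlation, in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("profiles must be 1-D vectors of equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation distance undefined for a constant profile")
    return float(1.0 - pearsonr(x, y).statistic)


def _correlation_distance_matrix(m: pd.DataFrame) -> np.ndarray:
    values = m.to_numpy(dtype=float)
    if (values.std(axis=0) == 0).any():
        bad = m.columns[values.std(axis=0) == 0].tolist()[:5]
        raise ValueError(f"constant sample profile(s): {bad}")
    d = 1.0 - np.corrcoef(values.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def embed_2d(m: pd.DataFrame, seed: int = 0, perplexity: float | None = None) -> pd.DataFrame:
    """2-D t-SNE of the samples on their pairwise correlation distances.

    ``perplexity`` defaults to min(30, floor((m-1)/3)); an explicit value must
    satisfy perplexity < (m-1)/3.  Deterministic given ``seed``.
    """
    n = m.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for a 2-D embedding")
    cap = (n - 1) / 3
    if perplexity is None:
        perplexity = min(30.0, np.floor(cap))
    elif perplexity >= cap:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples; use < {cap:.1f} "
            f"(suggested {int(np.floor(cap))})")
    dist = _correlation_distance_matrix(m)
    coords = TSNE(n_components=2, metric="precomputed", init="random",
                  perplexity=perplexity, random_state=seed).fit_transform(dist)
    return pd.DataFrame(coords, index=m.columns, columns=["tsne_1", "tsne_2"])


def closest_pair(coords, group_labels) -> tuple:
    """The unordered pair of groups with the smallest centroid distance.

    ``coords`` is (m, 2); centroids are per-group coordinate means and the
    distance is Euclidean.  Ties go to the lexicographically smallest pair.
    """
    xy = np.asarray(getattr(coords, "values", coords), dtype=float)
    labels = np.asarray(group_labels)
    if xy.shape[0] != labels.shape[0]:
        raise ValueError("coords and group_labels length mismatch")
    groups = sorted(pd.unique(labels).tolist(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    centroids = {g: xy[labels == g].mean(axis=0) for g in groups}
    best = None
    best_d = np.inf
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            d = float(np.linalg.norm(centroids[a] - centroids[b]))
            if d < best_d:
                best, best_d = (a, b), d
    return best


@dataclass
class BenchmarkReport:
    """Per-method Rand performance over repeated seeded runs."""

    method: str
    with_tsne: bool
    rand_values: np.ndarray
    welch_p: float = np.nan
    significantly_worse: bool = False
    run_seeds: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.rand_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.rand_values, ddof=1))


BENCHMARK_METHODS = (
    "NMF",
    "K-means",
    "Hclust Euclidean+Complete",
    "Hclust Euclidean+Ward",
    "Hclust Correlation+Complete",
)


def _cluster_once(method: str, X: np.ndarray, seed: int) -> np.ndarray:
    """Cluster samples (rows of X) into two groups with one benchmark method."""
    if method == "K-means":
        km = KMeans(n_clusters=2, init="random", n_init=1, random_state=seed)
        return km.fit_predict(X) + 1
    if method == "Hclust Euclidean+Complete":
        Z = linkage(X, method="complete", metric="euclidean")
    elif method == "Hclust Euclidean+Ward":
        Z = linkage(X, method="ward", metric="euclidean")
    elif method == "Hclust Correlation+Complete":
        Z = linkage(pdist(X, metric="correlation"), method="complete")
    else:
        raise ValueError(f"unknown method {method!r}")
    return fcluster(Z, t=2, criterion="maxclust")


def _welch(values: np.ndarray, reference: np.ndarray) -> float:
    if np.ptp(values) == 0 and np.ptp(reference) == 0:
        # both methods perfectly stable: no evidence of a difference
        return 1.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = ttest_ind(values, reference, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def benchmark_clustering(m: pd.DataFrame, ref_labels, n_runs: int = 30,
                         base_seed: int = 0, with_tsne: bool = False,
                         perplexity: float | None = None) -> list[BenchmarkReport]:
    """Compare NMF against K-means and three hierarchical variants by Rand measure.

    Every method is run ``n_runs`` times into 2 clusters and scored against
    ``ref_labels`` (which must contain exactly two groups).  Run r uses seed
    ``base_seed + r`` for each stochastic component.  With ``with_tsne``,
    each run first embeds the samples by correlation t-SNE and all methods
    cluster the 2-D coordinates (shifted by their global minimum for NMF,
    which needs non-negative input).  Welch's unequal-variance two-sided
    t-test compares every method with the NMF-without-t-SNE reference;
    ``significantly_worse`` flags p < 0.05 together with a lower mean.
    """
    ref = np.asarray(ref_labels)
    if ref.shape[0] != m.shape[1]:
        raise ValueError("ref_labels length must equal the number of samples")
    if len(np.unique(ref)) != 2:
        raise ValueError("benchmarking expects exactly 2 reference groups "
                         "(pick a closest pair first)")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")

    seeds = [int(base_seed) + r for r in range(n_runs)]
    X_full = m.to_numpy(dtype=float).T  # samples x genes

    def run_arm(tsne: bool) -> dict[str, np.ndarray]:
        rand = {meth: np.empty(n_runs) for meth in BENCHMARK_METHODS}
        for r, seed in enumerate(seeds):
            if tsne:
                coords = embed_2d(m, seed=seed, perplexity=perplexity).to_numpy()
                X = coords
                # 2 x m, shifted to be strictly positive for NMF
                A_nmf = (coords - coords.min() + 1e-9).T
            else:
                X = X_full
                A_nmf = m
            for meth in BENCHMARK_METHODS:
                if meth == "NMF":
                    labels = fit_nmf(A_nmf, 2, seed=seed).labels_
                else:
                    labels = _cluster_once(meth, X, seed)
                rand[meth][r] = rand_index(labels, ref).R
        return rand

    reference_rand = run_arm(tsne=False)
    reports = []
    arms = [(False, reference_rand)]
    if with_tsne:
        arms.append((True, run_arm(tsne=True)))
    ref_values = reference_rand["NMF"]
    for tsne, rand in arms:
        for meth in BENCHMARK_METHODS:
            p = 1.0 if (not tsne and meth == "NMF") else _welch(rand[meth], ref_values)
            rep = BenchmarkReport(method=meth, with_tsne=tsne, rand_values=rand[meth],
                                  welch_p=p, run_seeds=seeds)
            rep.significantly_worse = p < 0.05 and rep.mean < float(np.mean(ref_values))
            reports.append(rep)
    return reports
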