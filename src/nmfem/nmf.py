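"""Rank-k non-negative matrix factorization with multiplicative KL updates.

Implements the Brunet-style solver used for subpopulation discovery in
single-cell expression matrices: alternating multiplicative updates that
minimize the generalized Kullback-Leibler divergence D(A || WH), consensus
clustering over random restarts, and cophenetic-coefficient rank selection.

The data matrix ``A`` is oriented genes x samples (n x m, n >> k).  Columns
of ``W`` (n x k) are *meta-genes*; row i of ``W`` holds gene i's *loadings*.
``H`` (k x m) gives each sample's weight on every meta-gene, and the sample's
cluster is the meta-gene with the largest weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "kl_divergence",
    "update_h",
    "update_w",
    "assign_clusters",
    "KLNMF",
    "fit_nmf",
    "ConsensusResult",
    "consensus_cluster",
    "select_rank",
]

#: Floor added to denominators and to the initialization so that
#: multiplicative updates never divide by zero or create absorbing zeros.
EPS = 1e-16


def _as_array(A) -> np.ndarray:
    A = np.asarray(getattr(A, "values", A), dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.isfinite(A).all():
        raise ValueError("matrix contains non-finite entries")
    if (A < 0).any():
        raise ValueError("matrix contains negative entries; NMF requires non-negative input")
    return A


def kl_divergence(A, WH) -> float:
    """Generalized KL divergence sum(A log(A/WH) - A + WH), with 0 log 0 = 0.

    Requires ``WH > 0`` wherever ``A > 0``; both matrices must be
    non-negative and of equal shape.
    """
    A = _as_array(A)
    WH = _as_array(WH)
    if A.shape != WH.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {WH.shape}")
    pos = A > 0
    if (WH[pos] == 0).any():
        raise ValueError("WH is zero where A is positive; divergence is infinite")
    a = A[pos]
    return float(np.sum(a * np.log(a / WH[pos])) - A.sum() + WH.sum())


def update_h(W, H, A) -> np.ndarray:
    """One multiplicative H step: H_au <- H_au * [sum_i W_ia A_iu / (WH)_iu] / sum_k W_ka."""
    W = np.asarray(W, float)
    H = np.asarray(H, float)
    A = np.asarray(A, float)
    R = A / (W @ H + EPS)
    return H * (W.T @ R) / (W.sum(axis=0)[:, None] + EPS)


def update_w(W, H, A) -> np.ndarray:
    """One multiplicative W step: W_ia <- W_ia * [sum_u H_au A_iu / (WH)_iu] / sum_v H_av."""
    W = np.asarray(W, float)
    H = np.asarray(H, float)
    A = np.asarray(A, float)
    R = A / (W @ H + EPS)
    return W * (R @ H.T) / (H.sum(axis=1)[None, :] + EPS)


def assign_clusters(H) -> np.ndarray:
    """Hard sample labels from H: label_u = argmax_a H_au, 1-based, ties to the lowest index."""
    H = np.asarray(H, float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    return np.argmax(H, axis=0) + 1


def _nmf_loop(A, W, H, max_iter, check_every, stationary_iters, tol, use_tol):
    # Hot loop: BLAS matmuls with preallocated buffers; the ratio A/(WH+eps)
    # reuses the WH buffer, so each half-update costs two gemms + one
    # elementwise pass.  The divergence is evaluated only at checkpoints.
    n, m = A.shape
    pos = A > 0
    a_pos = A[pos]
    const = float(np.sum(a_pos * np.log(a_pos)) - A.sum())
    WH = np.empty((n, m))
    numW = np.empty_like(W)
    trace = np.empty(max_iter // check_every + 1)
    n_checks = 0
    prev_labels = None
    prev_div = np.inf
    stable = 0
    it = 0
    while it < max_iter:
        for _ in range(min(check_every, max_iter - it)):
            np.dot(W, H, out=WH)
            WH += EPS
            np.divide(A, WH, out=WH)               # WH now holds the ratio
            H *= (W.T @ WH) / (W.sum(axis=0)[:, None] + EPS)
            np.dot(W, H, out=WH)
            WH += EPS
            np.divide(A, WH, out=WH)
            np.dot(WH, H.T, out=numW)
            W *= numW / (H.sum(axis=1)[None, :] + EPS)
            it += 1
        np.dot(W, H, out=WH)
        div = const - float(np.sum(a_pos * np.log(WH[pos] + EPS))) + float(WH.sum())
        trace[n_checks] = div
        n_checks += 1
        labels = H.argmax(axis=0)
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            stable += check_every
        else:
            stable = 0
        prev_labels = labels
        if use_tol:
            if prev_div - div < tol * abs(div):
                break
            prev_div = div
        elif stable >= stationary_iters:
            break
    return it, trace[:n_checks]


class KLNMF(BaseEstimator):
    """Non-negative matrix factorization by multiplicative KL-divergence updates.

    Parameters
    ----------
    n_components : int
        Factorization rank k.  Subpopulation analyses use k >= 2; k = 1 is
        permitted (rank-one fits are exactly representable and useful for
        validation).
    max_iter : int
        Hard cap on alternating update rounds.
    stop : {"connectivity", "divergence"}
        Stopping rule.  ``"connectivity"`` (default, the convention of the
        original Brunet implementation) stops once the argmax-of-H sample
        assignment has been unchanged for ``stationary_iters`` consecutive
        iterations; ``"divergence"`` stops when the relative KL decrease over
        ``check_every`` iterations falls below ``tol``.
    tol : float
        Convergence threshold for the ``"divergence"`` rule.
    check_every : int
        Iterations between convergence checks / divergence evaluations.
    stationary_iters : int
        Stationarity horizon for the ``"connectivity"`` rule.
    random_state : int or None
        Seed for the uniform initialization on [eps, max(A)]; fits are
        bitwise reproducible for a fixed seed.

    Attributes
    ----------
    W_ : ndarray of shape (n_genes, k)
    H_ : ndarray of shape (k, n_samples)
    divergence_trace_ : ndarray
        KL divergence sampled every ``check_every`` rounds (non-increasing).
    n_iter_ : int
        Update rounds actually performed.
    labels_ : ndarray of shape (n_samples,)
        1-based argmax-of-H cluster assignment.
    """

    def __init__(self, n_components=2, max_iter=2000, stop="connectivity",
                 tol=1e-6, check_every=10, stationary_iters=40, random_state=None):
        self.n_components = n_components
        self.max_iter = max_iter
        self.stop = stop
        self.tol = tol
        self.check_every = check_every
        self.stationary_iters = stationary_iters
        self.random_state = random_state

    def fit(self, X, y=None):
        A = _as_array(X)
        n, m = A.shape
        k = int(self.n_components)
        if not 1 <= k <= min(n, m):
            raise ValueError(f"n_components={k} must be in [1, min(n, m)={min(n, m)}]")
        if self.stop not in ("connectivity", "divergence"):
            raise ValueError(f"unknown stop rule {self.stop!r}")
        row_zero = ~(A.sum(axis=1) > 0)
        col_zero = ~(A.sum(axis=0) > 0)
        if row_zero.any():
            raise ValueError(
                f"{row_zero.sum()} all-zero gene row(s); remove them first (filter_genes)")
        if col_zero.any():
            raise ValueError(
                f"{col_zero.sum()} all-zero sample column(s); remove them first (filter_samples)")

        rng = np.random.default_rng(self.random_state)
        hi = A.max()
        W = np.ascontiguousarray(rng.uniform(EPS, hi, size=(n, k)))
        H = np.ascontiguousarray(rng.uniform(EPS, hi, size=(k, m)))

        n_iter, trace = _nmf_loop(np.ascontiguousarray(A), W, H,
                             int(self.max_iter), max(1, int(self.check_every)),
                             int(self.stationary_iters), float(self.tol),
                             self.stop == "divergence")

        self.W_ = W
        self.H_ = H
        self.components_ = H  # sklearn-style alias
        self.divergence_trace_ = np.asarray(trace)
        self.n_iter_ = int(n_iter)
        self.reconstruction_err_ = float(trace[-1])
        self.labels_ = assign_clusters(H)
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the meta-gene weight matrix ``W_``."""
        return self.fit(X).W_

    def predict(self, X=None):
        """1-based cluster labels of the fitted samples (argmax of H)."""
        check_is_fitted(self, "H_")
        return self.labels_


def fit_nmf(A, k, seed=None, max_iter=2000, **kwargs) -> KLNMF:
    """Functional wrapper: fit a rank-``k`` KL-NMF and return the fitted estimator."""
    return KLNMF(n_components=k, max_iter=max_iter, random_state=seed, **kwargs).fit(A)


@dataclass
class ConsensusResult:
    """Consensus clustering of one rank over random NMF restarts."""

    k: int
    consensus: np.ndarray          # m x m co-clustering frequencies, diag exactly 1
    cophenetic: float              # correlation of (1 - consensus) with the tree's cophenetic distances
    labels: np.ndarray             # 1-based final labels from cutting the consensus tree
    n_runs: int
    run_seeds: list[int] = field(default_factory=list)
    linkage: np.ndarray | None = None


def consensus_cluster(A, k, n_runs=30, base_seed=0, **nmf_kwargs) -> ConsensusResult:
    """Average the co-clustering indicator over ``n_runs`` seeded NMF restarts.

    Run r uses seed ``base_seed + r``.  The final partition cuts an
    average-linkage tree on (1 - consensus) into k groups; the cophenetic
    coefficient measures how faithfully that tree represents the consensus
    distances and is the rank-selection statistic.
    """
    A = _as_array(A)
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (cophenetic coefficient undefined otherwise)")
    m = A.shape[1]
    consensus = np.zeros((m, m))
    seeds = [int(base_seed) + r for r in range(n_runs)]
    for seed in seeds:
        labels = KLNMF(n_components=k, random_state=seed, **nmf_kwargs).fit(A).labels_
        consensus += labels[:, None] == labels[None, :]
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    final = fcluster(Z, t=k, criterion="maxclust")
    if condensed.size and np.ptp(condensed) > 0:
        coph = float(cophenet(Z, condensed)[0])
    else:
        # All pairwise consensus distances equal: any tree is a perfect fit.
        coph = 1.0
    return ConsensusResult(k=int(k), consensus=consensus, cophenetic=coph,
                           labels=np.asarray(final), n_runs=int(n_runs),
                           run_seeds=seeds, linkage=Z)


def select_rank(A, k_range=range(2, 6), n_runs=30, base_seed=0, **kwargs):
    """Consensus-cluster every rank in ``k_range``; pick the best cophenetic coefficient.

    Returns ``(chosen_k, {k: ConsensusResult})``.  Ties go to the smallest k.
    Each rank gets a disjoint block of run seeds so restarts are independent
    across ranks while the whole scan stays reproducible from ``base_seed``.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    results = {}
    for i, k in enumerate(ks):
        results[k] = consensus_cluster(A, k, n_runs=n_runs,
                                       base_seed=int(base_seed) + i * n_runs, **kwargs)
    best = max(ks, key=lambda k: (results[k].cophenetic, -k))
    return best, results
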