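"""D-score feature ranking from a rank-2 factorization.

For a two-meta-gene factorization A ~ WH, gene i's D-score is

    D_i = | lambda * W_i1 - (1 - lambda) * W_i2 |

a discriminant importance measure: genes loading asymmetrically on the two
meta-genes (hence expressed differently between the two subpopulations)
score high.  The balancing factor ``lambda`` is calibrated so that a gene
expressed uniformly across all samples scores exactly 0: the constant sample
profile is projected onto the rows of H by non-negative least squares,
giving loadings (u1, u2), and ``lambda = u2 / (u1 + u2)`` makes
``lambda*u1 - (1-lambda)*u2 = 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["calibrate_lambda", "d_score", "rank_genes"]


def calibrate_lambda(H) -> float:
    """Balancing factor from the NNLS loadings of the all-ones profile on H's rows."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != 2:
        raise ValueError("H must be a 2 x m matrix (rank-2 factorization)")
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    u, _ = nnls(H.T, np.ones(H.shape[1]))
    total = u[0] + u[1]
    if total == 0:
        raise ValueError("degenerate H: the uniform profile has zero NNLS loadings")
    return float(u[1] / total)


def d_score(loading_1, loading_2, lam: float):
    """D_i = |lambda * W_i1 - (1 - lambda) * W_i2| (vectorized over loadings)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    l1 = np.asarray(loading_1, dtype=float)
    l2 = np.asarray(loading_2, dtype=float)
    if (l1 < 0).any() or (l2 < 0).any():
        raise ValueError("loadings must be non-negative")
    return np.abs(lam * l1 - (1.0 - lam) * l2)


def rank_genes(W, H, gene_ids, top_n: int = 500) -> pd.DataFrame:
    """Ranked D-score table for a rank-2 factorization.

    Parameters
    ----------
    W : array (n_genes, 2)
        Meta-gene weights; row i holds gene i's loadings.
    H : array (2, n_samples)
        Sample weights, used once to calibrate ``lambda``.
    gene_ids : sequence of str
    top_n : int
        Number of top-ranked rows flagged as feature genes (seed candidates
        for module detection).

    Returns
    -------
    DataFrame with columns gene_id, loading_1, loading_2, d_score, rank,
    is_feature, sorted by descending d_score; ties broken by gene id so the
    ranking is deterministic.  The calibrated lambda is stored in
    ``df.attrs["lambda"]``.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != 2:
        raise ValueError("D-score is defined for rank-2 factorizations (W must be n x 2)")
    if len(gene_ids) != W.shape[0]:
        raise ValueError("gene_ids length does not match W")
    lam = calibrate_lambda(H)
    scores = d_score(W[:, 0], W[:, 1], lam)
    df = pd.DataFrame({
        "gene_id": list(gene_ids),
        "loading_1": W[:, 0],
        "loading_2": W[:, 1],
        "d_score": scores,
    })
    df = df.sort_values(["d_score", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_feature"] = df["rank"] <= top_n
    df.attrs["lambda"] = lam
    return df
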