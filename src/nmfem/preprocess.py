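"""Count normalization and quality filters for expression matrices.

All functions operate on a genes x samples :class:`pandas.DataFrame` with
unique gene ids as the index and unique sample ids as the columns, the
orientation used throughout this package.

The processing order mirrors the analysis workflow: counts -> FPKM (skipped
for UMI molecule counts) -> median-of-ratios size-factor normalization ->
housekeeping-based sample filter -> zero-fraction gene filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "validate_matrix",
    "gene_length_from_annotation",
    "compute_fpkm",
    "size_factor_normalize",
    "SizeFactorNormalizer",
    "filter_samples",
    "filter_genes",
]


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants: non-negative, finite, unique ids."""
    if not isinstance(m, pd.DataFrame):
        m = pd.DataFrame(m)
    values = m.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite entries")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative entries")
    if m.index.duplicated().any():
        dup = m.index[m.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene identifiers: {dup}")
    if m.columns.duplicated().any():
        dup = m.columns[m.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample identifiers: {dup}")
    return m


def gene_length_from_annotation(exon_records: dict[str, list[tuple[int, int]]]) -> pd.Series:
    """Gene lengths (bp) as the union of each gene's exon intervals.

    ``exon_records`` maps gene id -> list of 1-based inclusive (start, end)
    genomic intervals.  Overlapping or duplicated exons are merged so shared
    bases count once.
    """
    lengths = {}
    for gene, intervals in exon_records.items():
        if not intervals:
            raise ValueError(f"gene {gene!r} has no exon records")
        merged_end = None
        merged_start = None
        total = 0
        for start, end in sorted(intervals):
            if end < start:
                raise ValueError(
                    f"gene {gene!r} has a reversed exon interval ({start}, {end})")
            if merged_end is None:
                merged_start, merged_end = start, end
            elif start <= merged_end + 1:
                merged_end = max(merged_end, end)
            else:
                total += merged_end - merged_start + 1
                merged_start, merged_end = start, end
        total += merged_end - merged_start + 1
        lengths[gene] = total
    return pd.Series(lengths, name="length", dtype=int)


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million: counts * 1e9 / (length * sample total)."""
    counts = validate_matrix(counts)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no gene length for: {missing.tolist()[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    length = lengths.reindex(counts.index).astype(float)
    if (length < 1).any():
        bad = length.index[length < 1].tolist()[:5]
        raise ValueError(f"gene lengths must be >= 1 bp: {bad}")
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total fragments: {zero}")
    fpkm = counts.to_numpy(dtype=float) * 1e9 / np.outer(length.to_numpy(), totals.to_numpy())
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def size_factor_normalize(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalization (the DESeq convention).

    Reference genes are those with positive expression in every sample (i.e.
    positive geometric mean).  Sample j's factor is the median over reference
    genes of ``value_ij / geomean_i``; factors are rescaled to geometric mean
    one, and each column is divided by its factor.

    Returns ``(normalized matrix, factors)``.
    """
    m = validate_matrix(m)
    values = m.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene is positive in every sample; add a pseudocount or skip "
            "size-factor normalization")
    ref = values[positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    out = pd.DataFrame(values / factors[None, :], index=m.index, columns=m.columns)
    return out, pd.Series(factors, index=m.columns, name="size_factor")


class SizeFactorNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios normalization as a transformer on genes x samples frames.

    ``fit`` estimates per-sample factors (``factors_``); ``transform``
    divides each sample column by its factor.
    """

    def fit(self, X, y=None):
        _, self.factors_ = size_factor_normalize(X)
        return self

    def transform(self, X):
        X = validate_matrix(X)
        factors = self.factors_.reindex(X.columns)
        if factors.isna().any():
            raise ValueError("transform saw samples absent at fit time")
        return X / factors


def _geometric_mean_rows(values: np.ndarray) -> np.ndarray:
    # Geometric mean per column over rows; any zero makes the mean zero
    # (deliberately no pseudocount: such samples are treated as abnormal).
    if (values == 0).any(axis=0).any():
        out = np.zeros(values.shape[1])
        ok = ~(values == 0).any(axis=0)
        if ok.any():
            out[ok] = np.exp(np.log(values[:, ok]).mean(axis=0))
        return out
    return np.exp(np.log(values).mean(axis=0))


def filter_samples(m: pd.DataFrame, housekeeping, threshold: float = 4.0) -> pd.DataFrame:
    """Drop samples whose housekeeping-gene geometric mean falls below ``threshold``.

    A sample is kept iff the geometric mean of its expression over the
    housekeeping genes present in the matrix is >= ``threshold`` (the
    boundary value itself is kept).  Gene set and sample order are preserved.
    """
    m = validate_matrix(m)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    hk = [g for g in housekeeping if g in m.index]
    if not hk:
        raise ValueError("none of the housekeeping genes are present in the matrix")
    geomean = _geometric_mean_rows(m.loc[hk].to_numpy(dtype=float))
    keep = geomean >= threshold
    if not keep.all():
        logger.info("filter_samples: removed %d of %d samples", (~keep).sum(), len(keep))
    return m.loc[:, keep]


def filter_genes(m: pd.DataFrame, max_zero_fraction: float = 0.7) -> pd.DataFrame:
    """Drop genes unexpressed in more than ``max_zero_fraction`` of the samples.

    A gene is kept iff its fraction of exactly-zero samples is <=
    ``max_zero_fraction`` (strictly greater is removed).  Gene order is
    preserved; an empty result is allowed with a warning.
    """
    m = validate_matrix(m)
    if m.shape[1] < 1:
        raise ValueError("matrix has no samples")
    zero_frac = (m.to_numpy(dtype=float) == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        logger.warning("filter_genes: no gene survived the zero-fraction filter")
    elif not keep.all():
        logger.info("filter_genes: removed %d of %d genes", (~keep).sum(), len(keep))
    return m.loc[keep]
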