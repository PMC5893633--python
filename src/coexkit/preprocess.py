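"""Normalization applied before embedding, search and correlation.

The standard pipeline for a count compendium is quantile normalization
across samples followed by a log2(x + 1) transform; per-gene z-scoring and
most-variable-gene selection serve visualization-style downstream steps.

Quantile normalization forces every column (sample) onto the same reference
distribution: the rank-wise mean of all sorted columns.  Tied values within
a column receive the mean of the reference values spanning their rank range
(the average-ties rule), so the procedure is deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizedMatrix",
    "quantile_normalize",
    "log2_transform",
    "zscore_genes",
    "top_variable_genes",
    "normalize",
]


@dataclass
class NormalizedMatrix:
    """A genes x samples matrix plus the ordered list of applied transforms."""

    values: np.ndarray
    provenance: list[tuple[str, dict]] = field(default_factory=list)


def quantile_normalize(m: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a genes x samples matrix.

    After normalization every column holds the same multiset of values:
    the r-th smallest value of each column is replaced by the mean over
    columns of the r-th smallest values; within-column ties receive the
    mean of the reference values over their rank span.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("quantile_normalize requires a non-empty 2-D matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("quantile_normalize requires finite entries")
    n, k = m.shape
    # reference distribution: rank-wise mean of sorted columns
    ref = np.mean(np.sort(m, axis=0), axis=1)
    ref_csum = np.concatenate(([0.0], np.cumsum(ref)))
    out = np.empty_like(m)
    for j in range(k):
        col = m[:, j]
        order = np.argsort(col, kind="stable")
        svals = col[order]
        # tie groups in sorted order
        starts = np.flatnonzero(np.concatenate(([True], svals[1:] != svals[:-1])))
        ends = np.append(starts[1:], n)
        means = (ref_csum[ends] - ref_csum[starts]) / (ends - starts)
        out[order, j] = np.repeat(means, ends - starts)
    return out


def log2_transform(m: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise ``log2(x + pseudocount)``; rejects negative entries."""
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("log2_transform requires non-negative entries")
    return np.log2(m + pseudocount)


def zscore_genes(m: np.ndarray) -> np.ndarray:
    """Center and scale each gene row to mean 0, unit sample (n-1) SD.

    Constant rows map to all-zero rows rather than NaN so that downstream
    projections stay finite.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("zscore_genes requires at least 2 samples (columns)")
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    out = m - mu
    np.divide(out, sd, out=out, where=sd > 0)
    out[np.broadcast_to(sd == 0, out.shape)] = 0.0
    return out


def top_variable_genes(
    m: np.ndarray,
    n: int = 500,
    gene_symbols: list[str] | None = None,
    pseudocount: float = 1.0,
) -> list[int]:
    """Indices of the ``n`` most variable genes, descending by variance.

    Variance is computed on log2(x + pseudocount) values; exact variance
    ties break by gene-symbol lexicographic order (row index when no
    symbols are given).
    """
    m = np.asarray(m, dtype=np.float64)
    if n > m.shape[0]:
        raise ValueError(f"n={n} exceeds the {m.shape[0]} available genes")
    var = np.var(log2_transform(m, pseudocount), axis=1)
    if gene_symbols is None:
        keys = [str(i) for i in range(m.shape[0])]
        order = sorted(range(m.shape[0]), key=lambda i: (-var[i], i))
    else:
        keys = list(gene_symbols)
        order = sorted(range(m.shape[0]), key=lambda i: (-var[i], keys[i]))
    return order[:n]


def normalize(
    m: np.ndarray,
    quantile: bool = True,
    log2: bool = True,
    zscore: bool = False,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Apply the standard transform chain and record provenance.

    Order is fixed: quantile normalization on the raw counts, then the
    log2 transform, then optional per-gene z-scoring.
    """
    values = np.asarray(m, dtype=np.float64)
    prov: list[tuple[str, dict]] = []
    if quantile:
        values = quantile_normalize(values)
        prov.append(("quantile_normalize", {}))
    if log2:
        values = log2_transform(values, pseudocount)
        prov.append(("log2_transform", {"pseudocount": pseudocount}))
    if zscore:
        values = zscore_genes(values)
        prov.append(("zscore_genes", {"ddof": 1}))
    return NormalizedMatrix(values=values, provenance=prov)
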