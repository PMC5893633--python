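"""Gene-gene correlation matrices with subsampling and chunked computation.

For compendia with very many samples, correlation matrices are built from a
random subsample (default 10,000 samples): prediction accuracy saturates
near that size while the pairwise-correlation cost keeps growing.  The
matrix itself is computed in row chunks so memory stays bounded at
N x chunk_size; the chunked result agrees with the unchunked one to
floating-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.stats import rankdata

from .compendium import Compendium
from .preprocess import NormalizedMatrix

__all__ = [
    "CorrelationMatrix",
    "subsample_samples",
    "gene_correlation_matrix",
    "write_correlation",
    "read_correlation",
]


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson (or Spearman) correlation matrix.

    ``zero_variance`` flags genes with constant expression: they carry
    correlation 0 to every other gene and a unit diagonal, and are retained
    so that gene indexing stays stable across operations.
    """

    values: np.ndarray
    gene_symbols: list[str]
    n_samples_used: int
    seed: int | None = None
    method: str = "pearson"
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        if self.zero_variance.size == 0:
            self.zero_variance = np.zeros(len(self.gene_symbols), dtype=bool)
        self._index = {g.upper(): i for i, g in enumerate(self.gene_symbols)}

    def gene_index(self, symbol: str) -> int | None:
        """Row index of a symbol, matched case-insensitively."""
        return self._index.get(str(symbol).upper())

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)


def subsample_samples(
    c: "Compendium | int", n: int = 10000, seed: int | None = None
) -> np.ndarray:
    """Draw min(n, M) distinct sample indices uniformly without replacement.

    ``c`` may be a :class:`Compendium` or the sample count M itself.  The
    draw is reproducible from ``seed``; indices are returned sorted so the
    subsampled matrix preserves compendium column order.
    """
    m = c.n_samples if isinstance(c, Compendium) else int(c)
    if n < 2:
        raise ValueError("subsample size n must be at least 2")
    rng = np.random.default_rng(seed)
    if n >= m:
        return np.arange(m)
    return np.sort(rng.choice(m, size=n, replace=False))


def gene_correlation_matrix(
    m: "NormalizedMatrix | np.ndarray",
    chunk_size: int = 2000,
    gene_symbols: list[str] | None = None,
    n_samples_used: int | None = None,
    seed: int | None = None,
    method: str = "pearson",
) -> CorrelationMatrix:
    """All pairwise gene correlations of a genes x samples matrix.

    Rows are standardized once; the N x N product is then accumulated in
    row chunks of ``chunk_size``, so the result is independent of the
    chunking.  Zero-variance genes get zero correlations (flagged) and a
    unit diagonal.  ``method`` is ``"pearson"`` (default) or ``"spearman"``
    (Pearson on within-gene ranks).
    """
    values = m.values if isinstance(m, NormalizedMatrix) else np.asarray(m)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("gene_correlation_matrix requires at least 3 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    n, msamp = values.shape
    if gene_symbols is None:
        gene_symbols = [f"G{i}" for i in range(n)]
    if len(gene_symbols) != n:
        raise ValueError("gene_symbols length does not match the matrix rows")

    if method == "spearman":
        values = rankdata(values, axis=1)

    mu = values.mean(axis=1, keepdims=True)
    z = values - mu
    norms = np.sqrt(np.einsum("ij,ij->i", z, z))
    const = norms == 0
    safe = np.where(const, 1.0, norms)
    z /= safe[:, None]
    z[const, :] = 0.0

    corr = np.empty((n, n), dtype=np.float64)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        corr[start:stop, :] = z[start:stop] @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(
        values=corr,
        gene_symbols=list(gene_symbols),
        n_samples_used=msamp if n_samples_used is None else int(n_samples_used),
        seed=seed,
        method=method,
        zero_variance=const,
    )


def write_correlation(cm: CorrelationMatrix, path: str) -> str:
    """Store a correlation matrix as HDF5 (/data/correlation + gene index)."""
    sdt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("data/correlation", data=cm.values)
        f.create_dataset("meta/genes/gene_symbol", data=cm.gene_symbols, dtype=sdt)
        f.create_dataset("meta/genes/zero_variance", data=cm.zero_variance)
        f.attrs["n_samples_used"] = cm.n_samples_used
        f.attrs["method"] = cm.method
        if cm.seed is not None:
            f.attrs["seed"] = cm.seed
    return path


def read_correlation(path: str) -> CorrelationMatrix:
    with h5py.File(path, "r") as f:
        values = f["data/correlation"][...]
        genes = [
            x.decode("utf-8") if isinstance(x, bytes) else str(x)
            for x in f["meta/genes/gene_symbol"][...]
        ]
        zv = (
            f["meta/genes/zero_variance"][...]
            if "meta/genes/zero_variance" in f
            else np.zeros(len(genes), dtype=bool)
        )
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return CorrelationMatrix(
            values=values,
            gene_symbols=genes,
            n_samples_used=int(f.attrs.get("n_samples_used", 0)),
            seed=seed,
            method=str(f.attrs.get("method", "pearson")),
            zero_variance=np.asarray(zv, dtype=bool),
        )
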