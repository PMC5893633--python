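"""HDF5-backed expression compendium: container, I/O, metadata search.

A compendium is a gene x sample matrix of non-negative expression values
(typically raw read counts) bound to unique gene symbols and per-sample
metadata records, persisted in a single HDF5 file with the layout::

    /data/expression            (N x M) counts, int32 where integral
    /meta/genes/gene_symbol     N strings
    /meta/samples/<field>       M strings per metadata field
    attrs: version, species, created

Metadata search is a token-AND, case-insensitive substring match over a
selected subset of metadata fields, which makes query semantics explicit
and reproducible.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "METADATA_FIELDS",
    "Compendium",
    "CompendiumError",
    "FormatError",
    "write_compendium",
    "read_compendium",
    "search_metadata",
    "export_series_matrix",
]

#: Per-sample metadata fields, mirroring the descriptive records that public
#: expression repositories attach to each sample.
METADATA_FIELDS = (
    "sample_id",
    "series_id",
    "title",
    "source",
    "characteristics",
    "organism",
    "instrument",
    "submission_date",
    "institute",
)

_FORMAT_VERSION = "1.0"


class CompendiumError(ValueError):
    """A compendium invariant is violated."""


class FormatError(ValueError):
    """An HDF5 file does not follow the declared compendium layout."""


@dataclass
class Compendium:
    """Gene x sample expression matrix with metadata.

    Parameters
    ----------
    expression
        (N, M) array of finite, non-negative values; rows are genes,
        columns are samples.
    gene_symbols
        N gene symbols, unique after case-folding.
    sample_ids
        M sample identifiers, unique.
    metadata
        DataFrame with one row per sample and the columns in
        :data:`METADATA_FIELDS`; missing optional fields are filled with
        empty strings.
    species
        Free-text species tag stored in the file attributes.
    """

    expression: np.ndarray
    gene_symbols: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame
    species: str = "synthetic"

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression)
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.sample_ids = [str(s) for s in self.sample_ids]
        meta = self.metadata.copy()
        for f in METADATA_FIELDS:
            if f not in meta.columns:
                meta[f] = ""
        self.metadata = meta[list(METADATA_FIELDS)].astype(str).reset_index(drop=True)

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`CompendiumError` naming the first violated invariant."""
        n, m = self.expression.shape if self.expression.ndim == 2 else (-1, -1)
        if self.expression.ndim != 2:
            raise CompendiumError("expression must be a 2-D genes x samples matrix")
        if n != len(self.gene_symbols):
            raise CompendiumError(
                f"expression has {n} rows but {len(self.gene_symbols)} gene_symbols"
            )
        if m != len(self.sample_ids):
            raise CompendiumError(
                f"expression has {m} columns but {len(self.sample_ids)} sample_ids"
            )
        folded = [g.upper() for g in self.gene_symbols]
        if len(set(folded)) != len(folded):
            dupes = sorted({g for g in folded if folded.count(g) > 1})[:5]
            raise CompendiumError(
                f"gene_symbols not unique after case-folding: {dupes}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CompendiumError("duplicate sample_id in sample_ids")
        if len(self.metadata) != m:
            raise CompendiumError(
                f"metadata has {len(self.metadata)} records for {m} samples"
            )
        if list(self.metadata["sample_id"]) != self.sample_ids:
            raise CompendiumError(
                "metadata sample_id column does not match sample_ids order"
            )
        if not np.all(np.isfinite(self.expression)):
            raise CompendiumError("expression contains non-finite values")
        if np.any(self.expression < 0):
            raise CompendiumError("expression contains negative values")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Compendium):
            return NotImplemented
        return (
            self.expression.shape == other.expression.shape
            and np.array_equal(self.expression, other.expression)
            and self.gene_symbols == other.gene_symbols
            and self.sample_ids == other.sample_ids
            and self.metadata.equals(other.metadata)
        )


def write_compendium(c: Compendium, path: str) -> str:
    """Persist a validated compendium to HDF5; returns ``path``.

    Counts that are integral and fit an int32 are stored as int32, all
    other matrices as float64; the choice is recorded in the dataset
    attribute ``stored_as`` so round-trips are bit-exact.
    """
    c.validate()
    expr = c.expression
    integral = (
        np.issubdtype(expr.dtype, np.integer)
        or (
            np.all(expr == np.floor(expr))
            and expr.size > 0
            and float(expr.max(initial=0)) <= np.iinfo(np.int32).max
        )
    )
    stored = expr.astype(np.int32) if integral else expr.astype(np.float64)
    sdt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data/expression", data=stored)
        d.attrs["stored_as"] = "int32" if integral else "float64"
        f.create_dataset("meta/genes/gene_symbol", data=c.gene_symbols, dtype=sdt)
        for col in METADATA_FIELDS:
            f.create_dataset(
                f"meta/samples/{col}", data=list(c.metadata[col]), dtype=sdt
            )
        f.attrs["version"] = _FORMAT_VERSION
        f.attrs["species"] = c.species
        f.attrs["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    return path


def read_compendium(path: str) -> Compendium:
    """Load a compendium written by :func:`write_compendium`.

    Raises :class:`FormatError` naming the missing dataset or the shape
    mismatch when the file does not follow the declared layout.  Optional
    metadata fields absent from the file are filled with empty strings.
    """
    with h5py.File(path, "r") as f:
        for req in ("data/expression", "meta/genes/gene_symbol", "meta/samples/sample_id"):
            if req not in f:
                raise FormatError(f"required dataset missing: /{req}")
        expr = f["data/expression"][...]
        genes = [_dec(x) for x in f["meta/genes/gene_symbol"][...]]
        meta = {}
        for col in METADATA_FIELDS:
            key = f"meta/samples/{col}"
            if key in f:
                meta[col] = [_dec(x) for x in f[key][...]]
        species = str(f.attrs.get("species", "unknown"))
    sample_ids = meta["sample_id"]
    m = len(sample_ids)
    if expr.ndim != 2 or expr.shape[0] != len(genes) or expr.shape[1] != m:
        raise FormatError(
            f"expression shape {expr.shape} does not match "
            f"{len(genes)} genes x {m} samples"
        )
    for col in METADATA_FIELDS:
        vals = meta.get(col, None)
        if vals is None:
            meta[col] = [""] * m
        elif len(vals) != m:
            raise FormatError(
                f"metadata field {col!r} has {len(vals)} entries for {m} samples"
            )
    return Compendium(
        expression=expr,
        gene_symbols=genes,
        sample_ids=sample_ids,
        metadata=pd.DataFrame(meta),
        species=species,
    )


def _dec(x) -> str:
    return x.decode("utf-8") if isinstance(x, bytes) else str(x)


def search_metadata(
    c: Compendium, query: str, fields: list[str] | None = None
) -> tuple[list[str], list[str]]:
    """Keyword search over sample metadata.

    A sample matches when every whitespace-separated token of ``query``
    occurs, case-insensitively, as a substring of the concatenation of its
    selected metadata fields.  Returns the matching sample ids (compendium
    order) and the deduplicated series ids of the hits (first-hit order).
    """
    if not query or not query.strip():
        raise ValueError("query must be a non-empty string")
    if fields is None:
        fields = list(METADATA_FIELDS)
    unknown = [f for f in fields if f not in METADATA_FIELDS]
    if unknown:
        raise ValueError(
            f"unknown metadata field(s) {unknown}; valid fields: {list(METADATA_FIELDS)}"
        )
    tokens = [t.lower() for t in query.split()]
    hits: list[str] = []
    series: list[str] = []
    seen = set()
    for i, sid in enumerate(c.sample_ids):
        haystack = " ".join(str(c.metadata.iloc[i][f]) for f in fields).lower()
        if all(t in haystack for t in tokens):
            hits.append(sid)
            ser = str(c.metadata.iloc[i]["series_id"])
            if ser not in seen:
                seen.add(ser)
                series.append(ser)
    return hits, series


def export_series_matrix(c: Compendium, series_id: str) -> str:
    """Tab-separated expression table for one series.

    One header row with ``gene_symbol`` followed by the series' sample ids
    in compendium order, then one row per gene with the raw stored counts.
    """
    mask = c.metadata["series_id"].astype(str) == str(series_id)
    if not mask.any():
        avail = sorted(set(c.metadata["series_id"].astype(str)))
        raise ValueError(f"unknown series_id {series_id!r}; available series: {avail}")
    cols = np.flatnonzero(mask.to_numpy())
    sub = c.expression[:, cols]
    integral = np.issubdtype(sub.dtype, np.integer) or np.all(sub == np.floor(sub))
    lines = ["\t".join(["gene_symbol"] + [c.sample_ids[j] for j in cols])]
    for i, g in enumerate(c.gene_symbols):
        if integral:
            vals = [str(int(v)) for v in sub[i]]
        else:
            vals = [repr(float(v)) for v in sub[i]]
        lines.append("\t".join([g] + vals))
    return "\n".join(lines) + "\n"
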