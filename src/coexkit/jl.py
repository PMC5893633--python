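"""Johnson-Lindenstrauss compression and signature similarity search.

A random Gaussian projection D (k x N, entries N(0, 1/k)) maps the gene
dimension of an expression matrix E (N genes x M samples) to a small fixed
k (default 1000) while approximately preserving inner products between
samples: cov(D s, D E) ~ cov(s, E).  Query signatures live in the same gene
index, are projected with the same stored D, and samples are then ranked by
Pearson correlation in the k-dimensional space, which makes similarity
search over very large compendia effectively instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "ProjectionMatrix",
    "ProjectedCompendium",
    "Signature",
    "build_projection",
    "project",
    "encode_signature",
    "search",
    "evaluate_fidelity",
    "write_projected",
    "read_projected",
]


@dataclass
class ProjectionMatrix:
    """k x N Gaussian random projection, reproducible from (n_genes, k, seed)."""

    values: np.ndarray
    k: int
    seed: int | None = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ProjectedCompendium:
    """k x M image of an expression matrix under a stored projection."""

    values: np.ndarray
    sample_ids: list[str]
    k: int
    projection_seed: int | None = None


@dataclass
class Signature:
    """A query vector over the compendium's gene index.

    Typically +1 on up-regulated genes and -1 on down-regulated genes, 0
    elsewhere; ``unmapped`` lists input symbols that were not found in the
    gene index.
    """

    values: np.ndarray
    unmapped: list[str]


def build_projection(
    n_genes: int, k: int = 1000, seed: int | None = None
) -> ProjectionMatrix:
    """Draw a k x n_genes projection with i.i.d. N(0, 1/k) entries."""
    if k < 1:
        raise ValueError("projection dimension k must be at least 1")
    if k >= n_genes:
        raise ValueError(
            f"k={k} >= n_genes={n_genes}: the projection would not reduce "
            "dimensionality; use the original matrix directly"
        )
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 1.0 / np.sqrt(k), size=(k, n_genes))
    return ProjectionMatrix(values=values, k=k, seed=seed)


def project(m: np.ndarray, p: ProjectionMatrix) -> np.ndarray:
    """Matrix product ``p.values @ m`` for a matrix or single gene vector."""
    m = np.asarray(m, dtype=np.float64)
    rows = m.shape[0]
    if rows != p.n_genes:
        raise ValueError(
            f"cannot project shape {m.shape} with a {p.values.shape} projection: "
            f"row count {rows} != {p.n_genes} genes"
        )
    return p.values @ m


def encode_signature(
    up: list[str], down: list[str], gene_index: list[str]
) -> Signature:
    """Encode up/down gene symbol lists as a +1/-1 vector over the index.

    Symbols are matched case-insensitively; unmatched symbols are reported,
    an empty mapping or an up/down overlap is an error.
    """
    index = {str(g).upper(): i for i, g in enumerate(gene_index)}
    up_f = {str(g).upper() for g in up}
    down_f = {str(g).upper() for g in down}
    overlap = up_f & down_f
    if overlap:
        raise ValueError(f"genes present in both up and down lists: {sorted(overlap)}")
    values = np.zeros(len(gene_index), dtype=np.float64)
    unmapped: list[str] = []
    for g in up:
        i = index.get(str(g).upper())
        if i is None:
            unmapped.append(str(g))
        else:
            values[i] = 1.0
    for g in down:
        i = index.get(str(g).upper())
        if i is None:
            unmapped.append(str(g))
        else:
            values[i] = -1.0
    if not np.any(values):
        raise ValueError("no up/down symbol maps into the gene index")
    return Signature(values=values, unmapped=unmapped)


def _standardize_columns(m: np.ndarray) -> np.ndarray:
    z = m - m.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", z, z))
    const = norms == 0
    z /= np.where(const, 1.0, norms)[None, :]
    z[:, const] = 0.0
    return z


def search(
    sig: "Signature | np.ndarray",
    pc: ProjectedCompendium,
    p: ProjectionMatrix,
    top_n: int = 10,
) -> list[tuple[str, float]]:
    """Rank samples by Pearson correlation to a projected signature.

    The signature is projected with the same stored projection as the
    compendium; scores are correlations across the k projected coordinates,
    sorted descending with ties broken by sample id.  Scores are invariant
    to positive rescaling of the signature.
    """
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    vec = sig.values if isinstance(sig, Signature) else np.asarray(sig, dtype=np.float64)
    if not np.any(pc.values):
        raise ValueError("projected compendium is all-zero; nothing to search")
    s_hat = project(vec, p)
    zc = _standardize_columns(pc.values)
    zs = s_hat - s_hat.mean()
    norm = np.linalg.norm(zs)
    if norm == 0:
        raise ValueError("projected signature has zero variance")
    zs /= norm
    scores = zs @ zc
    order = sorted(range(len(pc.sample_ids)), key=lambda j: (-scores[j], pc.sample_ids[j]))
    return [(pc.sample_ids[j], float(scores[j])) for j in order[:top_n]]


def _cosine_upper(z: np.ndarray) -> np.ndarray:
    norms = np.sqrt(np.einsum("ij,ij->j", z, z))
    zn = z / np.where(norms == 0, 1.0, norms)[None, :]
    c = zn.T @ zn
    iu = np.triu_indices(c.shape[0], k=1)
    return c[iu]


def _sample_correlations_upper(m: np.ndarray) -> np.ndarray:
    return _cosine_upper(m - m.mean(axis=0, keepdims=True))


def evaluate_fidelity(m: np.ndarray, p: ProjectionMatrix) -> float:
    """Preservation of the sample-sample correlation structure.

    Sample columns are centered once (so cosine similarity equals the
    Pearson correlation between samples), then compared before and after
    projection: the result is the Pearson correlation between the
    upper-triangle entries of the two sample-sample similarity matrices.
    A value near 1 means the k-dimensional subspace captures the original
    correlation structure; an orthonormal square projection preserves it
    exactly.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("evaluate_fidelity requires at least 3 samples")
    centered = m - m.mean(axis=0, keepdims=True)
    before = _cosine_upper(centered)
    after = _cosine_upper(p.values @ centered)
    if before.size < 2:
        raise ValueError("need at least 2 distinct sample pairs")
    return float(np.corrcoef(before, after)[0, 1])


def write_projected(
    pc: ProjectedCompendium, p: ProjectionMatrix, path: str
) -> str:
    """Store projection and projected data together so search is reproducible."""
    sdt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("data/projection", data=p.values)
        f.create_dataset("data/projected", data=pc.values)
        f.create_dataset("meta/samples/sample_id", data=pc.sample_ids, dtype=sdt)
        f.attrs["k"] = p.k
        if p.seed is not None:
            f.attrs["seed"] = p.seed
    return path


def read_projected(path: str) -> tuple[ProjectedCompendium, ProjectionMatrix]:
    with h5py.File(path, "r") as f:
        proj = f["data/projection"][...]
        data = f["data/projected"][...]
        sample_ids = [
            x.decode("utf-8") if isinstance(x, bytes) else str(x)
            for x in f["meta/samples/sample_id"][...]
        ]
        k = int(f.attrs["k"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    p = ProjectionMatrix(values=proj, k=k, seed=seed)
    pc = ProjectedCompendium(values=data, sample_ids=sample_ids, k=k, projection_seed=seed)
    return pc, p
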