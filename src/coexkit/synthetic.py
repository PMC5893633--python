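"""Synthetic compendium generator with planted modules and sample clusters.

The generator emulates the structure that co-expression methods exploit in
real compendia, without any download:

* genes belong to modules; samples belong to tissue-like clusters,
* log2 expression = gene baseline + module x cluster effect
  + a per-sample shared module factor + heteroscedastic noise,
* counts = rounded exponentiated values with a gamma overdispersion knob,
* metadata carries cluster-derived tissue names and synthetic series ids.

The shared module variance is calibrated on the latent log scale so that
the expected within-module gene-gene correlation equals ``module_corr``;
between-module effects are independent, so between-module correlations
center on zero.  Sample clusters are organized into a few parent lineages
(related tissues share part of their effect) and per-sample noise scales
are log-normally heterogeneous with mean power 1 — both features mimic the
wide spread of sample-sample correlations seen across heterogeneous public
RNA-seq collections, which the projection-fidelity and search components
depend on.

Ground-truth labels are returned alongside the compendium (and written to
a sidecar TSV by the CLI), never inside the HDF5 metadata, so the
compendium format stays honest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .compendium import Compendium
from .genesets import GeneSetLibrary, PPINetwork

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_compendium",
    "generate_gene_sets",
    "generate_ppi",
    "write_labels",
]

_TISSUES = (
    "liver",
    "brain cortex",
    "heart",
    "kidney",
    "lung",
    "spleen",
    "skeletal muscle",
    "pancreatic islet",
    "skin",
    "testis",
    "ovary",
    "thymus",
    "bone marrow",
    "adipose",
    "colon",
    "stomach",
    "retina",
    "placenta",
    "cerebellum",
    "whole blood",
)

_INSTITUTES = (
    "Institute of Synthetic Genomics",
    "Center for Simulated Biology",
    "Department of Computational Tissues",
)


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    ``module_corr`` is the target expected within-module gene-gene
    correlation on the latent log scale; ``noise_sd`` the base log2-scale
    noise SD; ``count_mean`` the mean count level (sets the baseline
    log2-expression scale); ``count_dispersion`` the variance of the
    multiplicative gamma overdispersion on counts (0 disables it).

    ``cluster_weight`` splits the shared module variance between the
    sample-cluster effect and the per-sample module factor;
    ``cluster_hierarchy`` is the fraction of cluster-effect variance shared
    within a parent tissue lineage; ``sample_noise_spread`` is the sigma of
    the log-normal per-sample noise-scale heterogeneity (normalized to mean
    noise power 1); ``gene_cluster_sd`` is the SD of gene-private tissue
    responses — cluster-driven expression changes each gene has on its own,
    which shape sample-sample similarity but count as noise for gene-gene
    correlations.
    """

    n_genes: int = 200
    n_samples: int = 500
    n_gene_modules: int = 10
    n_sample_clusters: int = 10
    module_corr: float = 0.7
    noise_sd: float = 1.0
    count_mean: float = 32.0
    count_dispersion: float = 0.1
    cluster_weight: float = 0.85
    cluster_hierarchy: float = 0.7
    cluster_size_skew: float = 0.8
    sample_noise_spread: float = 0.7
    gene_cluster_sd: float = 1.5
    baseline_shape: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 1 <= self.n_gene_modules <= self.n_genes:
            raise ValueError("n_gene_modules must be in [1, n_genes]")
        if not 1 <= self.n_sample_clusters <= self.n_samples:
            raise ValueError("n_sample_clusters must be in [1, n_samples]")
        if not 0.0 < self.module_corr < 1.0:
            raise ValueError("module_corr must lie in the open interval (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.count_mean <= 1:
            raise ValueError("count_mean must exceed 1")
        if self.count_dispersion < 0:
            raise ValueError("count_dispersion must be non-negative")
        if not 0.0 <= self.cluster_weight <= 1.0:
            raise ValueError("cluster_weight must lie in [0, 1]")
        if not 0.0 <= self.cluster_hierarchy <= 1.0:
            raise ValueError("cluster_hierarchy must lie in [0, 1]")
        if self.sample_noise_spread < 0:
            raise ValueError("sample_noise_spread must be non-negative")
        if self.gene_cluster_sd < 0:
            raise ValueError("gene_cluster_sd must be non-negative")
        if self.cluster_size_skew < 0:
            raise ValueError("cluster_size_skew must be non-negative")
        if self.baseline_shape <= 0:
            raise ValueError("baseline_shape must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted labels shipped alongside a synthetic compendium."""

    gene_symbols: list[str]
    gene_modules: np.ndarray
    sample_clusters: np.ndarray
    cluster_names: list[str]

    def genes_in_module(self, module: int) -> list[str]:
        return [
            g
            for g, m in zip(self.gene_symbols, self.gene_modules)
            if int(m) == int(module)
        ]


def _block_labels(n_items: int, n_blocks: int) -> np.ndarray:
    """Contiguous, nearly equal blocks: item i -> block label."""
    return np.repeat(
        np.arange(n_blocks), np.diff(np.linspace(0, n_items, n_blocks + 1).astype(int))
    )


def _skewed_block_labels(n_items: int, n_blocks: int, skew: float) -> np.ndarray:
    """Contiguous blocks with Zipf-like sizes (block b gets ~ (b+1)^-skew).

    Mirrors the heavy-tailed cluster sizes of public compendia, where a few
    tissues and cell lines contribute a large share of all samples.  Every
    block keeps at least one item; skew 0 reduces to equal blocks.
    """
    if skew == 0 or n_blocks == 1:
        return _block_labels(n_items, n_blocks)
    w = np.arange(1, n_blocks + 1, dtype=np.float64) ** -skew
    w /= w.sum()
    sizes = np.maximum(1, np.floor(w * n_items).astype(int))
    # settle the remainder deterministically: grow/shrink the largest blocks
    order = np.argsort(-w)
    i = 0
    while sizes.sum() < n_items:
        sizes[order[i % n_blocks]] += 1
        i += 1
    i = 0
    while sizes.sum() > n_items:
        j = order[i % n_blocks]
        if sizes[j] > 1:
            sizes[j] -= 1
        i += 1
    return np.repeat(np.arange(n_blocks), sizes)


def generate_compendium(cfg: SyntheticConfig) -> tuple[Compendium, GroundTruth]:
    """Simulate a count compendium with planted modules and clusters.

    Fully reproducible from ``cfg.seed``.  Returns the compendium plus the
    ground-truth gene-module and sample-cluster labels.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_genes, cfg.n_samples
    n_mod, n_clu = cfg.n_gene_modules, cfg.n_sample_clusters

    gene_modules = _block_labels(n, n_mod)
    sample_clusters = _skewed_block_labels(m, n_clu, cfg.cluster_size_skew)

    # gene baseline on the log2 scale: right-skewed, mean log2(count_mean)
    base_scale = np.log2(cfg.count_mean) / cfg.baseline_shape
    mu = rng.gamma(cfg.baseline_shape, base_scale, size=n)
    np.clip(mu, 0.0, 18.0, out=mu)

    # shared module variance calibrated to module_corr on the latent scale;
    # the multiplicative gamma overdispersion adds polygamma(1, 1/d)/ln(2)^2
    # of log2-scale variance, which counts as noise for correlations
    from scipy.special import polygamma

    disp_var = (
        float(polygamma(1, 1.0 / cfg.count_dispersion)) / np.log(2.0) ** 2
        if cfg.count_dispersion > 0
        else 0.0
    )
    gene_cluster_var = cfg.gene_cluster_sd**2 if n_clu > 1 else 0.0
    v_noise = cfg.noise_sd**2 + disp_var + gene_cluster_var
    v_shared = cfg.module_corr / (1.0 - cfg.module_corr) * v_noise
    sd_cluster = np.sqrt(cfg.cluster_weight * v_shared)
    sd_factor = np.sqrt((1.0 - cfg.cluster_weight) * v_shared)

    # hierarchical cluster effects: part of each tissue effect is shared
    # within a parent lineage so that between-cluster similarity varies
    n_parents = max(1, n_clu // 4)
    parent_of = _block_labels(n_clu, n_parents)
    w = cfg.cluster_hierarchy
    p_eff = rng.normal(size=(n_mod, n_parents))
    q_eff = rng.normal(size=(n_mod, n_clu))
    beta = np.sqrt(w) * p_eff[:, parent_of] + np.sqrt(1.0 - w) * q_eff
    # standardize each module's realized per-sample profile to variance
    # sd_cluster^2 exactly: with few clusters the realized variance of a raw
    # Gaussian draw fluctuates widely and correlation is concave in it, which
    # would bias the within-module correlation below its target
    profile_var = np.var(beta[:, sample_clusters], axis=1)
    usable = profile_var > 0
    beta -= beta[:, sample_clusters].mean(axis=1, keepdims=True)
    beta[usable] *= sd_cluster / np.sqrt(profile_var[usable, None])
    beta[~usable] = 0.0
    # degenerate cluster structure (e.g. a single cluster) carries the whole
    # shared variance on the per-sample factor instead
    sd_factor_mod = np.where(usable, sd_factor, np.sqrt(v_shared))

    # per-sample shared module factor (unit variance enforced) and
    # heteroscedastic noise scale with empirical mean power exactly 1
    factor = rng.normal(size=(n_mod, m))
    if m >= 2:
        factor -= factor.mean(axis=1, keepdims=True)
        fsd = factor.std(axis=1, keepdims=True)
        factor = np.divide(factor, fsd, out=factor, where=fsd > 0)
    tau = cfg.sample_noise_spread
    noise_scale = np.exp(tau * rng.normal(size=m))
    noise_scale /= np.sqrt(np.mean(noise_scale**2))  # mean noise power = 1

    # gene-private tissue responses: per (gene, cluster) shifts
    g_resp = (
        rng.normal(0.0, cfg.gene_cluster_sd, size=(n, n_clu))
        if gene_cluster_var > 0
        else np.zeros((n, n_clu))
    )

    # assemble log2 expression in place: noise, effects, baseline
    x = rng.normal(size=(n, m))
    x *= cfg.noise_sd * noise_scale[None, :]
    x += mu[:, None]
    for c in range(n_clu):
        cols = sample_clusters == c
        x[:, cols] += (beta[gene_modules, c] + g_resp[:, c])[:, None]
    for mo in range(n_mod):
        rows = gene_modules == mo
        x[rows, :] += sd_factor_mod[mo] * factor[mo][None, :]

    # counts: exponentiate, overdisperse, round
    np.exp2(x, out=x)
    x -= 1.0
    np.clip(x, 0.0, None, out=x)
    if cfg.count_dispersion > 0:
        d = cfg.count_dispersion
        g = rng.gamma(1.0 / d, d, size=x.shape)
        x *= g
        del g
    np.rint(x, out=x)

    width = max(5, len(str(n)))
    gene_symbols = [f"SYNG{i + 1:0{width}d}" for i in range(n)]
    sample_ids = [f"S{i + 1:06d}" for i in range(m)]
    cluster_names = [
        _TISSUES[c % len(_TISSUES)]
        + ("" if c < len(_TISSUES) else f" variant {c // len(_TISSUES) + 1}")
        for c in range(n_clu)
    ]
    tissues = [cluster_names[c] for c in sample_clusters]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "series_id": [f"SER{c + 1:04d}" for c in sample_clusters],
            "title": [
                f"{tissues[i]} RNA-seq sample {i + 1}" for i in range(m)
            ],
            "source": [f"adult {t}" for t in tissues],
            "characteristics": [
                f"tissue: {tissues[i]}; cluster: {sample_clusters[i]}"
                for i in range(m)
            ],
            "organism": ["synthetic organism"] * m,
            "instrument": ["SimSeq 2000"] * m,
            "submission_date": [
                f"2024-{(sample_clusters[i] % 12) + 1:02d}-{(i % 28) + 1:02d}"
                for i in range(m)
            ],
            "institute": [_INSTITUTES[c % len(_INSTITUTES)] for c in sample_clusters],
        }
    )
    comp = Compendium(
        expression=x,
        gene_symbols=gene_symbols,
        sample_ids=sample_ids,
        metadata=meta,
        species="synthetic",
    )
    truth = GroundTruth(
        gene_symbols=gene_symbols,
        gene_modules=gene_modules,
        sample_clusters=sample_clusters,
        cluster_names=cluster_names,
    )
    return comp, truth


def generate_gene_sets(
    labels: GroundTruth,
    n_true: int = 20,
    n_decoy: int = 20,
    contamination: float = 0.1,
    seed: int | None = 0,
    min_size: int = 5,
    max_size: int = 30,
) -> GeneSetLibrary:
    """Gene-set library with module-derived true sets and random decoys.

    Each true set samples from a single planted module, with a
    ``contamination`` fraction of its members replaced by off-module genes;
    decoys are size-matched uniform random sets.  Provenance (kind, source
    module) is recorded on the library.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must lie in [0, 1]")
    if n_true < 1 and n_decoy < 1:
        raise ValueError("need at least one true or decoy set")
    rng = np.random.default_rng(seed)
    symbols = np.asarray(labels.gene_symbols)
    modules = np.asarray(labels.gene_modules)
    module_ids = np.unique(modules)
    sets: dict[str, list[str]] = {}
    provenance: dict[str, dict] = {}
    sizes: list[int] = []
    for k in range(n_true):
        mod = int(rng.choice(module_ids))
        in_module = np.flatnonzero(modules == mod)
        hi = min(max_size, in_module.size)
        lo = min(min_size, hi)
        size = int(rng.integers(lo, hi + 1))
        n_off = int(round(contamination * size))
        n_in = size - n_off
        members = list(rng.choice(in_module, size=n_in, replace=False))
        off_module = np.flatnonzero(modules != mod)
        if n_off > 0 and off_module.size > 0:
            members += list(rng.choice(off_module, size=min(n_off, off_module.size), replace=False))
        name = f"true_set_{k + 1:03d}"
        sets[name] = [str(symbols[i]) for i in members]
        provenance[name] = {"kind": "true", "module": mod}
        sizes.append(len(sets[name]))
    for k in range(n_decoy):
        size = sizes[k % len(sizes)] if sizes else int(rng.integers(min_size, max_size + 1))
        members = rng.choice(len(symbols), size=min(size, len(symbols)), replace=False)
        name = f"decoy_set_{k + 1:03d}"
        sets[name] = [str(symbols[i]) for i in members]
        provenance[name] = {"kind": "decoy", "module": None}
    return GeneSetLibrary(name="synthetic_modules", sets=sets, provenance=provenance)


def generate_ppi(
    labels: GroundTruth,
    p_within: float = 0.3,
    p_between: float = 0.01,
    seed: int | None = 0,
) -> PPINetwork:
    """Planted-partition interaction network over the synthetic genes.

    Every unordered gene pair gets an edge with probability ``p_within``
    when both genes share a module and ``p_between`` otherwise; no
    self-loops.  Raises when the draw produces an empty network.
    """
    if not 0.0 <= p_within <= 1.0 or not 0.0 <= p_between <= 1.0:
        raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    modules = np.asarray(labels.gene_modules)
    n = modules.size
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(modules[iu] == modules[ju], p_within, p_between)
    keep = rng.random(prob.size) < prob
    if not keep.any():
        raise ValueError(
            "generated PPI network is empty; increase p_within/p_between"
        )
    symbols = labels.gene_symbols
    edges = [(symbols[a], symbols[b]) for a, b in zip(iu[keep], ju[keep])]
    return PPINetwork(edges=edges)


def write_labels(truth: GroundTruth, gene_path: str, sample_path: str) -> None:
    """Write ground-truth labels as two sidecar TSV files."""
    pd.DataFrame(
        {"gene_symbol": truth.gene_symbols, "module": truth.gene_modules}
    ).to_csv(gene_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_index": np.arange(truth.sample_clusters.size),
            "cluster": truth.sample_clusters,
            "cluster_name": [
                truth.cluster_names[c] for c in truth.sample_clusters
            ],
        }
    ).to_csv(sample_path, sep="\t", index=False)
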