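# Methods

`coexkit` implements the analytical core of a large, uniformly processed
RNA-seq compendium: normalization, gene–gene co-expression, guilt-by-
association prediction of gene function and protein–protein interactions
(PPI) with membership-AUC benchmarking, and compressed signature search via
a Johnson–Lindenstrauss (JL) random projection. This note records the
models, the numerical choices, and what the bundled synthetic generator
does and does not emulate.

## Normalization

Counts are quantile-normalized across samples and then log2(x+1)
transformed, in that order. Quantile normalization replaces the r-th
smallest value of every column by the mean over columns of the r-th
smallest values; tied values within a column receive the mean of the
reference values spanning their rank range (the average-ties rule). Two
consequences worth knowing:

* column **sums** equalize exactly, but identical column **multisets** and
  idempotence hold exactly only for tie-free columns — with ties, the rank
  spans re-average on a second pass. This is inherent to the average-ties
  rule, not an implementation artifact.
* quantile normalization removes any expression signal that acts as a pure
  column-level shift. A co-expression signal shared by *all* genes is
  therefore invisible after normalization, and with few gene modules a
  compositional coupling appears: when one module rises, the forced common
  marginal pushes the others slightly down, giving a small negative
  between-module correlation (about −0.07 with 10 modules of 20 genes).

Correlation matrices are built on quantile-normalized log2 counts by
default (configurable): Pearson by default, Spearman (Pearson on
within-gene ranks) behind a flag. Genes with zero variance keep their row
and column with correlation 0 and a flagged unit diagonal, so gene
indexing is stable. The matrix is accumulated in row chunks; chunking
changes memory use, not results (agreement ≤ 1e−10). For very large
compendia, correlations are computed on a uniform random subsample of
10,000 samples — prediction accuracy saturates near that size.

## Guilt-by-association prediction

For a gene set library GS, gene i and set j score

    GM[i, j] = mean over g in set_j, g ≠ i of cor(g_i, g)

with members absent from the correlation index ignored. When a set has no
member other than i itself, the mean is empty and the score is missing.
Per gene, sets are ranked by score (missing scores below all defined ones
— absence of evidence must not inflate the AUC) and the membership AUC is
the normalized area under the cumulative membership indicator, computed
via midranks so it equals the Mann–Whitney probability that a member set
outranks a non-member set, ties counting 1/2. Genes whose defined scores
are all-member or all-non-member cannot be ranked and are excluded but
counted. A per-set direction (rank genes within each set) is available
behind a flag. Report comparison uses the difference of medians and a
Welch (unequal-variance) t-test on the means.

PPI networks are converted to one gene set per protein containing its
interaction partners, then benchmarked identically. Two structural
properties of this construction are worth stating because they bound the
achievable AUC even with a perfect correlation oracle: a protein whose
partner has degree 1 contributes a singleton member set that is always
missing after self-exclusion; and within a co-expression module, member
and non-member partner sets draw from the same gene pool and tie near AUC
0.5 against each other, so cross-module edges and own-module partner sets
cap the per-gene AUC below 1.

## JL compression and signature search

The projection D is k × N with i.i.d. N(0, 1/k) entries (k defaults to
1000), reproducible from a stored seed that is persisted next to the
projected data. Search z-scores each gene across samples before
projection, so a +1/−1 up/down signature correlates with relative
expression; similarity is the Pearson correlation between the projected
signature and each projected sample over the k coordinates (scale-free,
invariant to positive rescaling of the signature).

Projection fidelity is the Pearson correlation between the upper-triangle
entries of the sample–sample correlation matrix before and after
projection. Sample columns are centered once before projecting, which
makes cosine similarity in both spaces equal Pearson correlation between
samples and makes an orthonormal square projection an exact isometry
(fidelity 1 to machine precision). Among the two readings of "average
correlation between samples before and after" we implement the
correlation of correlation matrices, and flag this choice.

## The synthetic compendium generator

Every component is testable offline against a planted-structure generator.
On the log2 scale, expression of gene g (module m) in sample s (cluster c)
is

    x[g,s] = mu_g + beta[m,c] + g_resp[g,c] + lambda_m * f[m,s] + sigma_s * eps

* `mu_g` — right-skewed gamma baseline (shape 2, mean log2(count_mean),
  default count_mean 32, clipped at 2^18), emulating the skewed abundance
  distribution of bulk RNA-seq.
* `beta[m,c]` — module × cluster effects shared by all genes of a module;
  clusters are organized into parent lineages (n_clusters // 4 parents,
  `cluster_hierarchy` = 0.7 of cluster variance shared within a lineage),
  emulating related tissues. Cluster sizes follow a Zipf-like profile
  (`cluster_size_skew` = 0.8) because a few tissues and cell lines
  dominate public compendia.
* `g_resp[g,c]` — gene-private tissue responses (`gene_cluster_sd` = 1.5
  log2 units): most tissue-specific expression in real data is not shared
  within co-expression modules. These shape sample–sample similarity but
  count as noise for gene–gene correlation.
* `f[m,s]` — per-sample shared module factor; `sigma_s` — heteroscedastic
  noise, log-normal across samples (`sample_noise_spread` = 0.7) with
  empirical mean power exactly 1, emulating quality variation.

Counts are `round((2^x − 1) · gamma(1/d, d))` with overdispersion
`d = count_dispersion = 0.1`, truncated at zero.

Calibration: the shared variance (cluster effect + module factor) is set
to `module_corr/(1−module_corr)` times the total non-shared variance,
where non-shared variance includes the white noise, the gene-private
cluster responses, and the closed-form log2-scale variance of the gamma
overdispersion, ψ₁(1/d)/ln²2. Realized cluster-effect profiles, module
factors, and noise power are standardized to their exact target second
moments: with few clusters the realized variance of a raw Gaussian draw
fluctuates widely, and because correlation is concave in the shared
variance this wobble would bias the mean within-module correlation well
below target. After calibration, the standard configuration (200 genes,
10 modules, 500 samples, module_corr 0.7) realizes a mean within-module
correlation of ~0.64–0.67 on quantile-normalized log2 counts — the
residual attenuation comes from count rounding/truncation of low-baseline
genes and the compositional effect of quantile normalization, both
deliberate realism features.

Under the defaults, sample–sample correlations of a 20-cluster compendium
span roughly 0.15–0.97 with SD ≈ 0.13, matching the wide spread seen
across heterogeneous public collections; this spread is what makes the
k = 1000 projection preserve the correlation structure with a coefficient
≥ 0.99 at full scale (34,198 genes × 2,000 samples).

What the generator does **not** emulate: batch effects and other
systematic per-series artifacts, sequencing-depth gradients (quantile
normalization would remove pure depth effects anyway), overlapping or
nested gene modules, count marginals of single-cell data, and real
gene-symbol vocabularies. Passing tests therefore certify the algorithms
on data with planted, well-separated structure; they do not certify
robustness to confounded real-world metadata or annotation noise.

Ground-truth labels ship in sidecar TSV files, never inside the HDF5
metadata. Gene-set libraries derived from modules carry a contamination
fraction of off-module members; decoy sets are size-matched uniform draws.
PPI networks are planted-partition graphs (edge probability p_within
within modules, p_between across).

## Problem sizes used by the test suite and acceptance script

The full-scale fidelity check runs at the compendium scale it refers to
(34,198 genes × 2,000 samples, k = 1000, ~1–5 min and < 3 GB). All other
checks use small instances: 200–600 genes, 120–500 samples, 1,000 random
AUC instances, 20 projection draws at 5,000 genes for self-retrieval. The
null-calibration and decoy checks use 120 random sets so that each gene's
AUC rests on enough member sets for a stable median.

## Known limitations

* Quantile normalization's tie rule makes the procedure only
  approximately idempotent on integer count matrices (see above).
* PPI benchmarking inherits the partner-set construction's AUC ceiling;
  absolute PPI AUCs are therefore conservative and are best used
  comparatively (between data sources), as in the report-comparison tool.
* The metadata search is token-AND case-insensitive substring matching;
  no stemming, synonyms, or ontology expansion.
* The HDF5 layout is fixed and versioned for bit-exact round-trips; no
  compatibility shim for externally produced files is provided.
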