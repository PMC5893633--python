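"""Guilt-by-association prediction of gene function and protein interactions.

Genes that co-express tend to share function and to interact physically.
Given a gene-gene correlation matrix C and a gene-set library GS, each gene
i is scored against each set j by the mean correlation of i to the set's
members, excluding i itself when it belongs to the set:

    GM[i, j] = mean_{g in set_j, g != i} C[i, g]

Prediction quality is benchmarked by a membership AUC: for each gene, sets
are ranked by GM score (high to low) and the area under the cumulative
membership indicator — normalized so that it equals the Mann-Whitney
probability that a true member set outranks a non-member set, with ties
contributing 1/2 — summarizes how well co-expression recovers known
annotations.  PPI networks are benchmarked the same way after conversion
to one gene set per protein containing its interaction partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coexpression import CorrelationMatrix
from .genesets import GeneSetLibrary, PPINetwork

__all__ = [
    "PredictionMatrix",
    "AUCReport",
    "score_gene_sets",
    "membership_auc",
    "compare_auc_reports",
    "ppi_to_gene_sets",
    "predict_ppi_auc",
    "interaction_correlation_quantile",
    "network_overlap",
]


@dataclass
class PredictionMatrix:
    """genes x sets mean-correlation scores; NaN marks undefined scores.

    A score is undefined when a set has no member other than the scored
    gene present in the correlation matrix.
    """

    scores: np.ndarray
    gene_symbols: list[str]
    set_names: list[str]


@dataclass
class AUCReport:
    """Per-gene membership AUCs with summary statistics.

    ``n_excluded`` counts genes that could not be evaluated (no defined
    score that is a member, or none that is a non-member).
    """

    labels: list[str]
    aucs: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.aucs = np.asarray(self.aucs, dtype=np.float64)

    @property
    def summary(self) -> dict:
        a = self.aucs
        return {
            "median": float(np.median(a)) if a.size else float("nan"),
            "mean": float(np.mean(a)) if a.size else float("nan"),
            "sd": float(np.std(a, ddof=1)) if a.size > 1 else float("nan"),
            "n": int(a.size),
        }


def score_gene_sets(
    corr: CorrelationMatrix, lib: GeneSetLibrary
) -> PredictionMatrix:
    """Mean correlation of every gene to every gene set, self-excluded.

    Set members are mapped onto the correlation index by case-folded
    symbol; members absent from the matrix are ignored.  Sets whose only
    mappable member is the scored gene itself yield NaN for that gene.
    """
    n = corr.n_genes
    set_names = list(lib.sets.keys())
    membership = np.zeros((n, len(set_names)), dtype=np.float64)
    any_mapped = False
    for j, sname in enumerate(set_names):
        for g in lib.sets[sname]:
            idx = corr.gene_index(g)
            if idx is not None:
                membership[idx, j] = 1.0
                any_mapped = True
    if not any_mapped:
        raise ValueError(
            f"no gene of library {lib.name!r} maps into the correlation matrix"
        )
    sums = corr.values @ membership  # includes the self term C[i,i]=1
    counts = membership.sum(axis=0)[None, :] - membership  # minus self
    sums = sums - membership  # remove the diagonal self-correlation
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return PredictionMatrix(
        scores=scores, gene_symbols=list(corr.gene_symbols), set_names=set_names
    )


def _rank_auc(scores: np.ndarray, members: np.ndarray) -> float:
    """Mann-Whitney AUC of members vs non-members under midrank ties.

    Equals the normalized trapezoidal area under the cumulative membership
    indicator of the descending score ranking, averaged over tie orderings.
    """
    n1 = int(members.sum())
    n0 = members.size - n1
    ranks = stats.rankdata(scores)  # ascending, ties -> midrank
    u = ranks[members].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def membership_auc(
    gm: PredictionMatrix, lib: GeneSetLibrary, direction: str = "genes"
) -> AUCReport:
    """Membership AUC per gene (default) or per set.

    ``direction="genes"``: for each gene, rank sets by score descending
    (undefined scores below all defined ones) and measure how far its known
    memberships concentrate at the top.  ``direction="sets"`` transposes
    the roles: for each set, rank genes.  Genes (or sets) whose defined
    scores are all-member or all-non-member are excluded and counted.
    """
    if direction not in ("genes", "sets"):
        raise ValueError(f"direction must be 'genes' or 'sets', got {direction!r}")
    membership = np.zeros_like(gm.scores, dtype=bool)
    index = {g.upper(): i for i, g in enumerate(gm.gene_symbols)}
    for j, sname in enumerate(gm.set_names):
        for g in lib.sets.get(sname, []):
            i = index.get(str(g).upper())
            if i is not None:
                membership[i, j] = True

    scores = gm.scores
    labels_all = gm.gene_symbols
    if direction == "sets":
        scores = scores.T
        membership = membership.T
        labels_all = gm.set_names

    labels: list[str] = []
    aucs: list[float] = []
    excluded = 0
    for i, label in enumerate(labels_all):
        row = scores[i]
        memb = membership[i]
        defined = ~np.isnan(row)
        nd = int(defined.sum())
        n1 = int(memb[defined].sum())
        if nd == 0 or n1 == 0 or n1 == nd:
            excluded += 1
            continue
        # undefined scores rank below every defined score
        filled = np.where(defined, row, -np.inf)
        labels.append(label)
        aucs.append(_rank_auc(filled, memb))
    return AUCReport(labels=labels, aucs=np.asarray(aucs), n_excluded=excluded)


def compare_auc_reports(a: AUCReport, b: AUCReport) -> dict:
    """Difference in median AUC and Welch t-test p-value on the means.

    ``delta_median`` is median(b) - median(a); a report compared with
    itself gives delta_median 0 and p-value 1.
    """
    if a.aucs.size < 2 or b.aucs.size < 2:
        raise ValueError("both AUC reports need at least 2 values")
    delta = float(np.median(b.aucs) - np.median(a.aucs))
    t, p = stats.ttest_ind(b.aucs, a.aucs, equal_var=False)
    return {"delta_median": delta, "p_value": float(p), "t_statistic": float(t)}


def ppi_to_gene_sets(net: PPINetwork) -> GeneSetLibrary:
    """One gene set per protein: its interaction partners.

    Set sizes equal node degrees and membership is symmetric
    (A in set(B) iff B in set(A)).
    """
    if len(net.edges) == 0:
        raise ValueError("cannot convert an empty PPI network")
    partners: dict[str, list[str]] = {}
    for a, b in net.edges:
        partners.setdefault(a.upper(), []).append(b)
        partners.setdefault(b.upper(), []).append(a)
    return GeneSetLibrary(name="ppi_partners", sets=dict(partners))


def predict_ppi_auc(
    corr: CorrelationMatrix, net: PPINetwork, direction: str = "genes"
) -> AUCReport:
    """Benchmark PPI recovery from co-expression.

    The network becomes a partner gene-set library, every gene is scored by
    mean correlation to each protein's partners, and the membership AUC
    asks whether known interactors of a protein outrank non-interactors.
    """
    lib = ppi_to_gene_sets(net)
    gm = score_gene_sets(corr, lib)
    return membership_auc(gm, lib, direction=direction)


def interaction_correlation_quantile(
    corr: CorrelationMatrix, net: PPINetwork, q: float = 0.75
) -> float:
    """q-quantile (linear interpolation) of correlations over network edges.

    Only edges with both endpoints in the correlation index contribute; a
    high upper quantile indicates that reported interactions are enriched
    for strongly co-expressed pairs.
    """
    vals = []
    for a, b in net.edges:
        ia, ib = corr.gene_index(a), corr.gene_index(b)
        if ia is not None and ib is not None:
            vals.append(corr.values[ia, ib])
    if not vals:
        raise ValueError("no network edge maps into the correlation matrix")
    return float(np.quantile(np.asarray(vals), q))


def network_overlap(
    nets: list[PPINetwork], names: list[str] | None = None
) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region edge counts for 2 or 3 networks.

    Keys are tuples of the network names a region belongs to; the counts
    over all regions sum to the size of the edge union.
    """
    if not 2 <= len(nets) <= 3:
        raise ValueError("network_overlap supports 2 or 3 networks")
    if names is None:
        names = [f"net{i + 1}" for i in range(len(nets))]
    if len(names) != len(nets):
        raise ValueError("names length must match nets")
    keysets = [n.edge_keys() for n in nets]
    universe = set().union(*keysets)
    out: dict[tuple[str, ...], int] = {}
    from itertools import combinations

    for r in range(1, len(nets) + 1):
        for combo in combinations(range(len(nets)), r):
            inside = set(universe)
            for i in combo:
                inside &= keysets[i]
            for i in range(len(nets)):
                if i not in combo:
                    inside -= keysets[i]
            out[tuple(names[i] for i in combo)] = len(inside)
    return out
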