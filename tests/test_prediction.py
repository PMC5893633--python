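"""Gene-set scoring, membership AUC, report comparison, PPI utilities."""

import numpy as np
import pytest
from scipy import stats

import coexkit as ck
from coexkit.coexpression import CorrelationMatrix
from coexkit.prediction import AUCReport, _rank_auc


def make_corr(values, symbols):
    values = np.asarray(values, dtype=float)
    return CorrelationMatrix(
        values=values, gene_symbols=symbols, n_samples_used=100
    )


def mw_auc_oracle(scores, members):
    """O(n^2) Mann-Whitney probability with 1/2 for ties."""
    pos = scores[members]
    neg = scores[~members]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestScoreGeneSets:
    def test_two_member_mean(self):
        c = np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.1], [0.4, 0.1, 1.0]])
        corr = make_corr(c, ["A", "B", "C"])
        lib = ck.GeneSetLibrary(name="t", sets={"s": ["B", "C"]})
        gm = ck.score_gene_sets(corr, lib)
        assert gm.scores[0, 0] == pytest.approx(0.6)

    def test_self_exclusion_singleton_is_missing(self):
        corr = make_corr(np.eye(2), ["A", "B"])
        lib = ck.GeneSetLibrary(name="t", sets={"s": ["A"]})
        gm = ck.score_gene_sets(corr, lib)
        assert np.isnan(gm.scores[0, 0])  # A scored against {A}: empty mean
        assert gm.scores[1, 0] == pytest.approx(0.0)  # B vs {A}: cor(B,A)

    def test_casefold_mapping_and_absent_members_ignored(self):
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        corr = make_corr(c, ["Actb", "Tp53"])
        lib = ck.GeneSetLibrary(name="t", sets={"s": ["ACTB", "NOT_A_GENE"]})
        gm = ck.score_gene_sets(corr, lib)
        assert gm.scores[1, 0] == pytest.approx(0.5)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(20)
        n = 10
        a = rng.normal(size=(n, 30))
        corr = ck.gene_correlation_matrix(a, gene_symbols=[f"g{i}" for i in range(n)])
        sets = {
            f"s{k}": [f"g{i}" for i in rng.choice(n, size=rng.integers(1, 6), replace=False)]
            for k in range(5)
        }
        lib = ck.GeneSetLibrary(name="r", sets=sets)
        gm = ck.score_gene_sets(corr, lib)
        for i in range(n):
            for j, sname in enumerate(gm.set_names):
                members = [
                    corr.gene_index(g) for g in lib.sets[sname] if corr.gene_index(g) != i
                ]
                if members:
                    expected = np.mean([corr.values[i, k] for k in members])
                    assert gm.scores[i, j] == pytest.approx(expected, abs=1e-12)
                else:
                    assert np.isnan(gm.scores[i, j])

    def test_invariant_to_order_and_duplicates(self):
        rng = np.random.default_rng(21)
        corr = ck.gene_correlation_matrix(
            rng.normal(size=(6, 20)), gene_symbols=list("ABCDEF")
        )
        a = ck.score_gene_sets(
            corr, ck.GeneSetLibrary(name="x", sets={"s": ["B", "C", "D"]})
        )
        b = ck.score_gene_sets(
            corr, ck.GeneSetLibrary(name="x", sets={"s": ["D", "c", "B", "b"]})
        )
        assert np.allclose(a.scores, b.scores, equal_nan=True)

    def test_unmappable_library_rejected(self):
        corr = make_corr(np.eye(2), ["A", "B"])
        lib = ck.GeneSetLibrary(name="t", sets={"s": ["X", "Y"]})
        with pytest.raises(ValueError, match="maps"):
            ck.score_gene_sets(corr, lib)


class TestMembershipAUC:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.1, 0.0])
        members = np.array([True, True, False, False])
        assert _rank_auc(scores, members) == 1.0

    def test_worst_ranking(self):
        scores = np.array([0.9, 0.8, 0.1, 0.0])
        members = np.array([False, False, True, True])
        assert _rank_auc(scores, members) == 0.0

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            n = int(rng.integers(5, 60))
            scores = rng.choice([0.0, 0.1, 0.2, 0.5, 0.7], size=n)  # force ties
            members = rng.random(n) < 0.3
            if members.all() or not members.any():
                continue
            assert _rank_auc(scores, members) == pytest.approx(
                mw_auc_oracle(scores, members), abs=1e-9
            )

    def test_report_excludes_degenerate_genes(self):
        corr = make_corr(
            np.array([[1, 0.5, 0.2], [0.5, 1, 0.1], [0.2, 0.1, 1]]), ["A", "B", "C"]
        )
        lib = ck.GeneSetLibrary(
            name="t", sets={"s1": ["A", "B", "C"], "s2": ["A", "B", "C"]}
        )
        # every gene is a member of every set: nothing can be ranked
        gm = ck.score_gene_sets(corr, lib)
        report = ck.membership_auc(gm, lib)
        assert report.aucs.size == 0 and report.n_excluded == 3

    def test_missing_scores_rank_last(self):
        # gene A: member singleton set -> missing score must sit at the bottom
        corr = make_corr(
            np.array([[1.0, 0.9, -0.5], [0.9, 1, 0.0], [-0.5, 0, 1]]), ["A", "B", "C"]
        )
        lib = ck.GeneSetLibrary(
            name="t",
            sets={"only_a": ["A"], "with_b": ["A", "B"], "c_set": ["C"]},
        )
        gm = ck.score_gene_sets(corr, lib)
        report = ck.membership_auc(gm, lib)
        a = dict(zip(report.labels, report.aucs))["A"]
        # defined member score 0.9 > defined non-member -0.5; the missing
        # member set ties at the bottom against nothing -> only pairs with
        # defined non-member count: (0.9 > -0.5) and (missing < -0.5)
        assert a == pytest.approx(0.5)

    def test_per_set_direction(self):
        rng = np.random.default_rng(23)
        corr = ck.gene_correlation_matrix(
            rng.normal(size=(12, 25)), gene_symbols=[f"g{i}" for i in range(12)]
        )
        lib = ck.GeneSetLibrary(
            name="t",
            sets={"s1": ["g0", "g1", "g2"], "s2": ["g3", "g4"], "s3": ["g5", "g6"]},
        )
        gm = ck.score_gene_sets(corr, lib)
        report = ck.membership_auc(gm, lib, direction="sets")
        assert set(report.labels) <= {"s1", "s2", "s3"}
        assert np.all((report.aucs >= 0) & (report.aucs <= 1))

    def test_summary_recomputable(self):
        r = AUCReport(labels=list("abcd"), aucs=np.array([0.5, 0.7, 0.9, 0.6]))
        s = r.summary
        assert s["median"] == pytest.approx(0.65)
        assert s["mean"] == pytest.approx(0.675)
        assert s["n"] == 4


class TestCompareReports:
    def test_report_vs_itself(self):
        r = AUCReport(labels=list("abc"), aucs=np.array([0.5, 0.7, 0.9]))
        out = ck.compare_auc_reports(r, r)
        assert out["delta_median"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_shift_moves_median(self):
        a = AUCReport(labels=list("abc"), aucs=np.array([0.5, 0.6, 0.7]))
        b = AUCReport(labels=list("abc"), aucs=a.aucs + 0.1)
        assert ck.compare_auc_reports(a, b)["delta_median"] == pytest.approx(0.1)

    def test_welch_t_matches_textbook_formula(self):
        rng = np.random.default_rng(24)
        x = rng.normal(0.7, 0.05, size=40)
        y = rng.normal(0.72, 0.08, size=55)
        out = ck.compare_auc_reports(
            AUCReport(labels=[str(i) for i in range(40)], aucs=x),
            AUCReport(labels=[str(i) for i in range(55)], aucs=y),
        )
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (y.mean() - x.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert out["p_value"] == pytest.approx(p, abs=1e-8)

    def test_tiny_report_rejected(self):
        r = AUCReport(labels=["a"], aucs=np.array([0.5]))
        with pytest.raises(ValueError):
            ck.compare_auc_reports(r, r)


class TestPPIConversion:
    def test_single_edge(self):
        lib = ck.ppi_to_gene_sets(ck.PPINetwork(edges=[("A", "B")]))
        assert lib.sets["A"] == ["B"] and lib.sets["B"] == ["A"]

    def test_star_degrees(self):
        net = ck.PPINetwork(edges=[("A", "B"), ("A", "C"), ("A", "D")])
        lib = ck.ppi_to_gene_sets(net)
        assert len(lib.sets["A"]) == 3
        assert all(len(lib.sets[x]) == 1 for x in "BCD")

    def test_set_sizes_equal_degree_sequence(self):
        rng = np.random.default_rng(25)
        nodes = [f"n{i}" for i in range(15)]
        edges = []
        for i in range(15):
            for j in range(i + 1, 15):
                if rng.random() < 0.2:
                    edges.append((nodes[i], nodes[j]))
        net = ck.PPINetwork(edges=edges)
        lib = ck.ppi_to_gene_sets(net)
        degrees = net.degrees()
        assert {k: len(v) for k, v in lib.sets.items()} == degrees

    def test_membership_symmetric(self):
        net = ck.PPINetwork(edges=[("A", "B"), ("B", "C")])
        lib = ck.ppi_to_gene_sets(net)
        for a, b in net.edges:
            assert b in lib.sets[a] and a in lib.sets[b]


class TestInteractionQuantile:
    def test_interpolation_example(self):
        c = np.eye(5)
        vals = [0.1, 0.2, 0.3, 0.4]
        symbols = list("ABCDE")
        for k, v in enumerate(vals):
            c[0, k + 1] = c[k + 1, 0] = v
        corr = make_corr(c, symbols)
        net = ck.PPINetwork(edges=[("A", x) for x in "BCDE"])
        assert ck.interaction_correlation_quantile(corr, net, q=0.75) == pytest.approx(0.325)
        assert ck.interaction_correlation_quantile(corr, net, q=0.0) == pytest.approx(0.1)

    def test_perfectly_correlated_edges(self):
        base = np.arange(5.0)
        m = np.vstack([base, base * 2 + 1, -base])
        corr = ck.gene_correlation_matrix(m, gene_symbols=["A", "B", "C"])
        net = ck.PPINetwork(edges=[("A", "B")])
        assert ck.interaction_correlation_quantile(corr, net) == pytest.approx(1.0)

    def test_no_mappable_edge_rejected(self):
        corr = make_corr(np.eye(2), ["A", "B"])
        net = ck.PPINetwork(edges=[("X", "Y")])
        with pytest.raises(ValueError):
            ck.interaction_correlation_quantile(corr, net)


class TestNetworkOverlap:
    def test_identical_networks_all_shared(self):
        net = ck.PPINetwork(edges=[("A", "B"), ("B", "C")])
        out = ck.network_overlap([net, net, net], names=["x", "y", "z"])
        assert out[("x", "y", "z")] == 2
        assert sum(v for k, v in out.items() if len(k) < 3) == 0

    def test_disjoint_networks(self):
        a = ck.PPINetwork(edges=[("A", "B")])
        b = ck.PPINetwork(edges=[("C", "D")])
        out = ck.network_overlap([a, b], names=["a", "b"])
        assert out == {("a",): 1, ("b",): 1, ("a", "b"): 0}

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(26)
        nodes = [f"n{i}" for i in range(10)]

        def random_net(seed):
            r = np.random.default_rng(seed)
            edges = [
                (nodes[i], nodes[j])
                for i in range(10)
                for j in range(i + 1, 10)
                if r.random() < 0.3
            ]
            return ck.PPINetwork(edges=edges)

        nets = [random_net(s) for s in (1, 2, 3)]
        out = ck.network_overlap(nets)
        keys = [n.edge_keys() for n in nets]
        union = keys[0] | keys[1] | keys[2]
        assert sum(out.values()) == len(union)
        assert out[("net1", "net2", "net3")] == len(keys[0] & keys[1] & keys[2])
        assert out[("net1",)] == len(keys[0] - keys[1] - keys[2])

    def test_more_than_three_rejected(self):
        net = ck.PPINetwork(edges=[("A", "B")])
        with pytest.raises(ValueError):
            ck.network_overlap([net] * 4)


class TestPlantedRecovery:
    def test_degree_one_partners_yield_undefined_scores(self):
        # in a pure single-edge network every gene's only member set is its
        # partner's singleton set, whose score is empty after self-exclusion,
        # so no gene is evaluable
        rng = np.random.default_rng(27)
        m = rng.normal(size=(4, 30))
        corr = ck.gene_correlation_matrix(m, gene_symbols=list("ABCD"))
        report = ck.predict_ppi_auc(corr, ck.PPINetwork(edges=[("A", "B"), ("C", "D")]))
        assert report.aucs.size == 0 and report.n_excluded == 4

    def test_correlated_triangle_outranks_decoys(self):
        # A,B,C mutually near-perfectly correlated and mutually interacting;
        # decoy genes interact among themselves with random expression
        rng = np.random.default_rng(27)
        base = rng.normal(size=40)
        m = np.vstack(
            [base, base + rng.normal(0, 0.01, 40), base + rng.normal(0, 0.01, 40)]
            + [rng.normal(size=40) for _ in range(6)]
        )
        symbols = list("ABCDEFGHI")
        corr = ck.gene_correlation_matrix(m, gene_symbols=symbols)
        edges = [("A", "B"), ("A", "C"), ("B", "C")]
        edges += [("D", "E"), ("E", "F"), ("F", "G"), ("G", "H"), ("H", "I"), ("D", "I")]
        report = ck.predict_ppi_auc(corr, ck.PPINetwork(edges=edges))
        by_gene = dict(zip(report.labels, report.aucs))
        # each triangle gene's member sets score ~1; the only competitive
        # non-member is its own partner set, which also scores ~1 (half win)
        for g in "ABC":
            assert by_gene[g] >= 0.9
        assert np.mean([by_gene[g] for g in "DEFGHI"]) < 0.8

    def test_shuffled_edges_give_null_auc(self, standard_correlation, standard_synthetic):
        _, _, truth = standard_synthetic
        rng = np.random.default_rng(28)
        symbols = np.array(truth.gene_symbols)
        edges = []
        seen = set()
        while len(edges) < 400:
            i, j = rng.choice(len(symbols), size=2, replace=False)
            key = frozenset((i, j))
            if key not in seen:
                seen.add(key)
                edges.append((symbols[i], symbols[j]))
        report = ck.predict_ppi_auc(standard_correlation, ck.PPINetwork(edges=edges))
        se = report.summary["sd"] / np.sqrt(report.summary["n"])
        assert abs(report.summary["mean"] - 0.5) < 3 * se
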