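"""Interaction-network features, Jaccard colocalization, Fisher enrichment."""

import numpy as np
import pytest
from scipy import stats

import paralogscope as ps
from paralogscope.network import (
    boxplot_stats,
    fisher_exact_2x2,
    filter_ppi_table,
    private_interactors,
    shared_interactor_count,
)


@pytest.fixture
def gi_network():
    edges = [
        ("a", "b", "gi", -0.20, 0.01),
        ("c", "d", "gi", -0.40, 0.01),
        ("e", "f", "gi", -0.20, 0.20),
        ("g", "h", "gi", 0.20, 0.01),
        ("i", "j", "gi", 0.10, 0.01),
        ("k", "l", "ppi", None, None),
    ]
    return ps.InteractionNetwork.from_edges(edges)


class TestGIFilter:
    def test_stringency_classes_on_moderate_negative(self, gi_network):
        passing = {
            cls: ("a", "b") in set(map(tuple, map(sorted, ps.filter_gi(gi_network, cls))))
            for cls in ("lenient", "intermediate", "stringent", "stringent_neg",
                        "synthetic_lethal")
        }
        assert passing == {
            "lenient": True, "intermediate": True, "stringent": True,
            "stringent_neg": True, "synthetic_lethal": False,
        }

    def test_synthetic_lethal_needs_strong_negative(self, gi_network):
        sl = set(map(tuple, map(sorted, ps.filter_gi(gi_network, "synthetic_lethal"))))
        assert sl == {("c", "d")}

    def test_p_gate_excludes_everything(self, gi_network):
        for cls in ("lenient", "intermediate", "stringent"):
            assert ("e", "f") not in set(
                map(tuple, map(sorted, ps.filter_gi(gi_network, cls)))
            )

    def test_positive_epsilon_stringent_branch(self, gi_network):
        st_edges = set(map(tuple, map(sorted, ps.filter_gi(gi_network, "stringent"))))
        assert ("g", "h") in st_edges  # eps 0.20 > 0.16
        assert ("i", "j") not in st_edges  # eps 0.10 passes neither branch

    def test_unknown_class_rejected(self, gi_network):
        with pytest.raises(ValueError):
            ps.filter_gi(gi_network, "bogus")


class TestNetworkCleaning:
    def test_self_loops_dropped_duplicates_keep_strongest(self):
        net = ps.InteractionNetwork.from_edges(
            [
                ("x", "x", "ppi", None, None),
                ("a", "b", "gi", -0.1, 0.04),
                ("b", "a", "gi", -0.3, 0.01),
            ]
        )
        assert "x" not in net.graph
        assert net.graph.edges["a", "b"]["epsilon"] == -0.3

    def test_ppi_table_filter_keeps_physical_high_throughput(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "geneA": ["a", "a", "a"],
                "geneB": ["b", "c", "d"],
                "experimental_system_type": ["physical", "genetic", "physical"],
                "throughput": ["High Throughput", "High Throughput", "Low Throughput"],
            }
        )
        kept = filter_ppi_table(table)
        assert kept["geneB"].tolist() == ["b"]


class TestSharedInteractors:
    def _net(self):
        edges = [("A", n, "ppi") for n in "xyz"] + [("B", n, "ppi") for n in "yzw"]
        edges += [("C", "x", "ppi"), ("D", "q", "ppi"), ("A", "B", "ppi")]
        return ps.InteractionNetwork.from_edges(edges)

    def test_count_excludes_pair_members(self):
        net = self._net()
        assert shared_interactor_count(net, "A", "B") == 2  # y and z

    def test_disjoint_neighborhoods_count_zero(self):
        net = self._net()
        assert shared_interactor_count(net, "C", "D") == 0

    def test_median_binning_ties_go_low(self):
        # cohort counts {0, 1, 2, 3} -> median 1.5; count 2 -> high
        net = ps.InteractionNetwork.from_edges(
            [("p1", f"n{i}", "ppi") for i in range(3)]
            + [("p2", f"n{i}", "ppi") for i in range(3)]  # shared 3
            + [("q1", f"m{i}", "ppi") for i in range(2)]
            + [("q2", f"m{i}", "ppi") for i in range(2)]  # shared 2
            + [("r1", "u", "ppi"), ("r2", "u", "ppi")]  # shared 1
            + [("s1", "v1", "ppi"), ("s2", "v2", "ppi")]  # shared 0
        )
        pairs = [("p1", "p2"), ("q1", "q2"), ("r1", "r2"), ("s1", "s2")]
        bin_, count = ps.shared_interactor_bin(net, "q1", "q2", pairs)
        assert (bin_, count) == ("high", 2)
        assert ps.shared_interactor_bin(net, "r1", "r2", pairs)[0] == "low"

    def test_absent_gene_flagged(self):
        net = self._net()
        with pytest.raises(KeyError):
            ps.shared_interactor_bin(net, "A", "ZZZ", [("A", "B")])


class TestPathLengthBin:
    def test_direct_edge_bins_one(self):
        net = ps.InteractionNetwork.from_edges([("A", "B", "ppi")])
        assert ps.path_length_bin(net, "A", "B") == ("1", 1.0)

    def test_two_hop_bins_one_plus(self):
        net = ps.InteractionNetwork.from_edges([("A", "X", "ppi"), ("X", "B", "ppi")])
        assert ps.path_length_bin(net, "A", "B") == ("1+", 2.0)

    def test_disconnected_bins_one_plus(self):
        net = ps.InteractionNetwork.from_edges([("A", "X", "ppi"), ("B", "Y", "ppi")])
        bin_, raw = ps.path_length_bin(net, "A", "B")
        assert bin_ == "1+" and np.isinf(raw)

    def test_triangle_inequality_on_sampled_triples(self):
        import networkx as nx

        g = nx.gnp_random_graph(30, 0.15, seed=4)
        net = ps.InteractionNetwork.from_edges(
            [(str(a), str(b), "ppi") for a, b in g.edges]
        )
        rng = np.random.default_rng(0)
        nodes = [str(n) for n in g.nodes if str(n) in net.graph]
        for _ in range(50):
            a, b, c = rng.choice(nodes, 3, replace=False)
            dab = ps.path_length_bin(net, a, b)[1]
            dbc = ps.path_length_bin(net, b, c)[1]
            dac = ps.path_length_bin(net, a, c)[1]
            assert dac <= dab + dbc


class TestColocJaccard:
    def test_identical_sets_100(self):
        val, coloc = ps.coloc_jaccard({"ER", "cytoplasm"}, {"ER", "cytoplasm"})
        assert val == 100.0 and coloc

    def test_half_overlap_inclusive_at_50(self):
        val, coloc = ps.coloc_jaccard({"ER", "cytoplasm"}, {"ER"})
        assert val == 50.0 and coloc

    def test_disjoint_zero(self):
        val, coloc = ps.coloc_jaccard({"ER"}, {"vacuole"})
        assert val == 0.0 and not coloc

    def test_symmetric_bounded_and_100_iff_equal(self):
        rng = np.random.default_rng(1)
        universe = list("abcdefg")
        for _ in range(50):
            a = set(rng.choice(universe, rng.integers(1, 6), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 6), replace=False))
            vab = ps.coloc_jaccard(a, b)[0]
            assert vab == ps.coloc_jaccard(b, a)[0]
            assert 0 <= vab <= 100
            assert (vab == 100.0) == (a == b)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ps.coloc_jaccard(set(), {"ER"})


def _hypergeom_two_sided(table):
    """Oracle: sum of hypergeometric probabilities <= that of the observed
    table, at fixed margins."""
    a, b, c, d = np.asarray(table).ravel()
    n = a + b + c + d
    r1, c1 = a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(kmin, kmax + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestFisherEnrichment:
    def test_cross_product_odds_ratio(self):
        orat, p = fisher_exact_2x2(np.array([[10, 2], [3, 9]]))
        assert orat == pytest.approx(15.0)

    def test_balanced_table_null(self):
        orat, p = fisher_exact_2x2(np.array([[5, 5], [5, 5]]))
        assert orat == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_correction(self):
        orat, _ = fisher_exact_2x2(np.array([[4, 0], [1, 5]]))
        assert orat == pytest.approx((4.5 * 5.5) / (0.5 * 1.5))

    def test_degenerate_margin_reports_undefined_or(self):
        orat, p = fisher_exact_2x2(np.array([[0, 0], [3, 4]]))
        assert orat is None and p == 1.0

    def test_p_matches_hypergeometric_oracle_sampled(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            t = rng.integers(0, 8, size=(2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) == 0:
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(_hypergeom_two_sided(t), abs=1e-9)

    def test_invariant_to_simultaneous_row_and_column_swap(self):
        t = np.array([[7, 2], [1, 8]])
        _, p = fisher_exact_2x2(t)
        _, p_sw = fisher_exact_2x2(t[::-1, ::-1])
        assert p == pytest.approx(p_sw)

    def test_enrichment_from_flags(self):
        redist = [True] * 10 + [False] * 10
        private = [True] * 8 + [False] * 2 + [True] * 2 + [False] * 8
        orat, p, table = ps.private_interactor_enrichment(redist, private)
        assert table.tolist() == [[8, 2], [2, 8]]
        assert orat == pytest.approx(16.0)
        assert p < 0.05

    def test_private_interactors_exclude_shared_and_sister(self):
        net = ps.InteractionNetwork.from_edges(
            [("A", "x", "ppi"), ("A", "y", "ppi"), ("B", "y", "ppi"),
             ("A", "B", "ppi")]
        )
        assert private_interactors(net, "A", "B") == {"x"}


class TestCompareScoreBins:
    def test_identical_bins_p_one(self):
        scores = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["low"] * 3 + ["high"] * 3
        out = ps.compare_score_bins(scores, labels)
        assert out["p"] == pytest.approx(1.0)

    def test_shifted_bins_small_p(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
        labels = ["low"] * 40 + ["high"] * 40
        assert ps.compare_score_bins(scores, labels)["p"] < 1e-6

    def test_boxplot_quartile_convention(self):
        stats_ = boxplot_stats(list(range(1, 10)))
        assert stats_["median"] == 5.0
        assert stats_["q1"] == 3.0 and stats_["q3"] == 7.0
        assert stats_["whisker_low"] == 3.0 - 6.0
        assert stats_["whisker_high"] == 7.0 + 6.0

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            ps.compare_score_bins([1.0, 2.0], ["low", "low"])
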