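"""Differential expression, correlation network and switch-gene cartography."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netmedsig as nm
from netmedsig.swim import CorrelationNetwork, _elbow_index


def make_expr(x: np.ndarray, n_case: int, prefix="g") -> nm.ExpressionMatrix:
    n_genes, n_samples = x.shape
    samples = [f"s{i}" for i in range(n_samples)]
    values = pd.DataFrame(x, index=[f"{prefix}{i:03d}" for i in range(n_genes)],
                          columns=samples)
    group = pd.Series(["case"] * n_case + ["control"] * (n_samples - n_case),
                      index=samples)
    return nm.ExpressionMatrix(values=values, group=group)


def pearson_two_pass(a, b):
    """Textbook two-pass Pearson correlation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    da, db = a - a.mean(), b - b.mean()
    return float((da * db).sum() / np.sqrt((da ** 2).sum() * (db ** 2).sum()))


class TestDifferentialExpression:
    def test_equal_means_never_retained(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 1, 40)
        x = np.vstack([np.concatenate([base[:20], base[:20]]),
                       rng.normal(7, 1, 40)])
        expr = make_expr(x, 20)
        full = nm.differential_expression(expr, filtered=False)
        assert full.loc["g000", "logFC"] == pytest.approx(0.0)
        table = nm.differential_expression(expr, fdr_threshold=0.9)
        assert "g000" not in table.index

    def test_planted_shift_recovered_with_bh_control(self):
        rng = np.random.default_rng(12)
        x = rng.normal(7, 1, (1001, 200))
        x[0, :100] += 2.0  # one planted gene, shift 2 sigma
        expr = make_expr(x, 100)
        table = nm.differential_expression(expr, fdr_threshold=0.001)
        assert "g000" in table.index
        assert len(table) - 1 <= 2  # false positives ~ 0-2 under BH at 0.001
        assert table.loc["g000", "direction"] == "up"

    def test_fc_threshold_one_is_inert(self):
        rng = np.random.default_rng(1)
        x = rng.normal(7, 1, (50, 40))
        x[:10, :20] += 1.5
        expr = make_expr(x, 20)
        with_fc = nm.differential_expression(expr, fc_threshold=1.0,
                                             fdr_threshold=0.01)
        no_fc = nm.differential_expression(expr, fc_threshold=0.0,
                                           fdr_threshold=0.01)
        assert list(with_fc.index) == list(no_fc.index)

    def test_small_group_is_error(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        expr = make_expr(x, 1)
        with pytest.raises(ValueError):
            nm.differential_expression(expr)


class TestCorrelationNetwork:
    def test_pearson_matches_two_pass(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 30))
        expr = make_expr(x, 30)
        net = nm.build_correlation_network(expr, expr.gene_ids, percentile=1.0,
                                           samples="case")
        for u, v, d in net.graph.edges(data=True):
            i, j = expr.gene_ids.index(u), expr.gene_ids.index(v)
            assert d["r"] == pytest.approx(pearson_two_pass(x[i], x[j]),
                                           abs=1e-12)

    def test_negative_correlation_kept_by_absolute_value(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=20)
        x = np.vstack([v, -v + rng.normal(0, 0.01, 20),
                       rng.normal(size=(2, 20))])
        expr = make_expr(x, 20)
        net = nm.build_correlation_network(expr, expr.gene_ids, percentile=80)
        assert net.graph.has_edge("g000", "g001")
        assert net.graph["g000"]["g001"]["r"] < -0.9

    def test_threshold_is_percentile_of_abs_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 25))
        expr = make_expr(x, 25)
        net = nm.build_correlation_network(expr, expr.gene_ids, percentile=60)
        # oracle: pandas corr + manual linear-interpolation percentile
        pop = []
        corr = expr.values.T.corr()
        genes = expr.gene_ids
        for i in range(10):
            for j in range(i + 1, 10):
                pop.append(abs(corr.loc[genes[i], genes[j]]))
        pop = np.sort(pop)
        h = 0.60 * (len(pop) - 1)
        lo, frac = int(np.floor(h)), h - np.floor(h)
        expected = pop[lo] + frac * (pop[lo + 1] - pop[lo]) if frac else pop[lo]
        assert net.threshold == pytest.approx(expected, abs=1e-12)
        for _, _, d in net.graph.edges(data=True):
            assert abs(d["r"]) > net.threshold

    def test_identical_genes_complete_graph(self):
        v = np.linspace(0, 1, 10)
        x = np.vstack([v, v, v, v])
        expr = make_expr(x, 10)
        net = nm.build_correlation_network(expr, expr.gene_ids, percentile=50)
        assert net.n_edges == 6  # complete graph on 4 nodes

    def test_edges_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 30))
        x[:4] += rng.normal(size=30) * 1.5  # correlated block
        expr = make_expr(x, 30)
        net1 = nm.build_correlation_network(expr, expr.gene_ids, percentile=83)
        perm_s = rng.permutation(expr.sample_ids).tolist()
        perm_g = rng.permutation(expr.gene_ids).tolist()
        expr2 = nm.ExpressionMatrix(values=expr.values.loc[perm_g, perm_s],
                                    group=expr.group.loc[perm_s])
        net2 = nm.build_correlation_network(expr2, perm_g, percentile=83)
        assert set(map(frozenset, net1.graph.edges)) == \
            set(map(frozenset, net2.graph.edges))

    def test_too_few_samples_is_error(self):
        x = np.random.default_rng(0).normal(size=(5, 4))
        expr = make_expr(x, 2)
        with pytest.raises(ValueError, match="3 samples"):
            nm.build_correlation_network(expr, expr.gene_ids, samples="case")


class TestConnectivityProfile:
    def test_threshold_extremes(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 20))
        expr = make_expr(x, 20)
        prof = nm.connectivity_profile(expr, expr.gene_ids, [0.0, 1.0])
        assert prof["lcc_fraction"].iloc[0] == 1.0      # complete graph
        assert prof["lcc_fraction"].iloc[1] == pytest.approx(1 / 8)

    def test_perfect_pair_fraction(self):
        v = np.linspace(0, 1, 12)
        rng = np.random.default_rng(7)
        x = np.vstack([v, v, rng.normal(size=12)])
        expr = make_expr(x, 12)
        prof = nm.connectivity_profile(expr, expr.gene_ids, [0.9])
        assert prof["lcc_fraction"].iloc[0] == pytest.approx(2 / 3)

    def test_empty_threshold_list_is_error(self):
        x = np.random.default_rng(0).normal(size=(3, 10))
        expr = make_expr(x, 10)
        with pytest.raises(ValueError):
            nm.connectivity_profile(expr, expr.gene_ids, [])


def _net_from_graph(g: nx.Graph) -> CorrelationNetwork:
    nodes = sorted(g.nodes)
    corr = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    for u, v, d in g.edges(data=True):
        corr.loc[u, v] = corr.loc[v, u] = d["r"]
    return CorrelationNetwork(graph=g, threshold=0.0, percentile=0.0, corr=corr)


class TestClustering:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(8)
        f1, f2 = rng.normal(size=40), rng.normal(size=40)
        x = np.vstack([f1 + rng.normal(0, 0.3, 40) for _ in range(6)]
                      + [f2 + rng.normal(0, 0.3, 40) for _ in range(6)])
        expr = make_expr(x, 40)
        net = nm.build_correlation_network(expr, expr.gene_ids, percentile=20)
        labels = nm.cluster_network(net, k=2, seed=0)
        block1 = {f"g{i:03d}" for i in range(6)} & set(labels.index)
        block2 = {f"g{i:03d}" for i in range(6, 12)} & set(labels.index)
        assert labels[list(block1)].nunique() == 1
        assert labels[list(block2)].nunique() == 1
        assert labels[next(iter(block1))] != labels[next(iter(block2))]

    def test_k_equal_node_count_gives_singletons(self):
        g = nx.Graph()
        for i in range(4):
            g.add_edge(f"a{i}", f"a{(i + 1) % 4}", r=0.9)
        net = _net_from_graph(g)
        rng = np.random.default_rng(9)
        net.corr.iloc[:, :] += rng.normal(0, 0.01, net.corr.shape)
        labels = nm.cluster_network(net, k=4, seed=0)
        assert labels.nunique() == 4

    def test_k_above_node_count_is_error(self):
        g = nx.Graph()
        g.add_edge("a", "b", r=0.9)
        with pytest.raises(ValueError):
            nm.cluster_network(_net_from_graph(g), k=3, seed=0)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(15, 30))
        expr = make_expr(x, 30)
        net = nm.build_correlation_network(expr, expr.gene_ids, percentile=10)
        l1 = nm.cluster_network(net, k=3, seed=5)
        l2 = nm.cluster_network(net, k=3, seed=5)
        assert l1.equals(l2)

    def test_elbow_picks_knee(self):
        inertias = np.array([100.0, 30.0, 10.0, 8.0, 7.0, 6.5])
        assert _elbow_index(inertias) in (1, 2)


class TestApccAndHubs:
    def test_apcc_limits(self):
        g = nx.Graph()
        for i in range(6):
            g.add_edge("hub", f"n{i}", r=-1.0)
        assert nm.compute_apcc(_net_from_graph(g))["hub"] == pytest.approx(-1.0)
        for _, _, d in g.edges(data=True):
            d["r"] = 1.0
        assert nm.compute_apcc(_net_from_graph(g))["hub"] == pytest.approx(1.0)

    def test_apcc_symmetric_mean_is_zero(self):
        g = nx.Graph()
        for i, r in enumerate([0.9, 0.9, 0.9, -0.9, -0.9, -0.9]):
            g.add_edge("hub", f"n{i}", r=r)
        assert nm.compute_apcc(_net_from_graph(g))["hub"] == pytest.approx(0.0)

    def test_non_hubs_absent(self):
        g = nx.Graph()
        for i in range(5):  # degree 5 is not a hub
            g.add_edge("h", f"n{i}", r=0.5)
        assert "h" not in nm.compute_apcc(_net_from_graph(g))

    def test_classification_rules(self):
        apcc = pd.Series({"f": -0.3, "d": 0.2, "p": 0.9, "edge": 0.9})
        degree = pd.Series({"f": 8, "d": 7, "p": 10, "edge": 5})
        classes = nm.classify_hubs(apcc, degree)
        assert classes["f"] == "fight-club"
        assert classes["d"] == "date"
        assert classes["p"] == "party"
        assert classes["edge"] == "non-hub"  # degree 5 boundary


class TestCartography:
    def _labelled_net(self):
        g = nx.Graph()
        # cluster 0: triangle a0-a1-a2; cluster 1: pair b0-b1
        for u, v in [("a0", "a1"), ("a1", "a2"), ("a0", "a2"), ("b0", "b1")]:
            g.add_edge(u, v, r=0.9)
        g.add_edge("a0", "b0", r=-0.9)  # one inter-cluster edge
        labels = pd.Series({"a0": 0, "a1": 0, "a2": 0, "b0": 1, "b1": 1})
        return _net_from_graph(g), labels

    def test_kpi_limits_and_z_convention(self):
        net, labels = self._labelled_net()
        carto = nm.compute_cartography(net, labels)
        assert carto.loc["a1", "Kpi"] == pytest.approx(0.0)  # all edges internal
        assert carto.loc["b1", "Kpi"] == pytest.approx(0.0)
        # a node with every edge outside its cluster
        g = nx.Graph()
        g.add_edge("x", "y", r=0.9)
        labels2 = pd.Series({"x": 0, "y": 1})
        carto2 = nm.compute_cartography(_net_from_graph(g), labels2)
        assert carto2.loc["x", "Kpi"] == pytest.approx(1.0)
        # degenerate cluster: all kappa equal -> z = 0
        assert carto.loc["b0", "z"] == 0.0 and carto.loc["b1", "z"] == 0.0

    def test_z_sums_to_zero_within_cluster(self, swim_results):
        _, carto, _ = swim_results
        for _, sub in carto.groupby("cluster"):
            if sub["z"].abs().sum() > 0:  # skip degenerate clusters
                assert abs(sub["z"].sum()) < 1e-8
        assert ((carto["Kpi"] >= 0) & (carto["Kpi"] <= 1)).all()
        assert np.isfinite(carto["z"]).all()

    def test_unlabelled_node_is_error(self):
        net, labels = self._labelled_net()
        with pytest.raises(ValueError):
            nm.compute_cartography(net, labels.drop("a0"))


class TestSwitchCalling:
    def test_rule_conjunction(self):
        carto = pd.DataFrame({
            "hub_class": ["fight-club", "party", "fight-club", "fight-club"],
            "Kpi": [0.9, 0.9, 0.5, 0.95],
            "z": [1.0, 1.0, 1.0, 3.0],
        }, index=["yes", "wrong_class", "low_kpi", "high_z"])
        assert nm.call_switch_genes(carto) == {"yes"}

    def test_switch_implies_fight_club(self, swim_results):
        _, carto, _ = swim_results
        switch = carto[carto["is_switch"]]
        assert (switch["hub_class"] == "fight-club").all()
        assert (switch["Kpi"] > 0.8).all()
        assert (switch["z"] < 2.5).all()
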