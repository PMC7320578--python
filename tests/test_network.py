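"""CLR, prevalence filtering, network inference, robustness analysis."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from skinpah import (
    attack_stability,
    clr,
    filter_weak_edges,
    infer_network,
    natural_connectivity,
    network_summary,
    prevalence_filter,
    simulate_graph_community,
)
from skinpah.errors import EmptyTableError
from skinpah.network import AssociationNetwork
from skinpah.tables import TaxonTable


def make_table(counts, domain="bacteria"):
    counts = np.asarray(counts)
    df = pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(counts.shape[0])],
        columns=[f"T{i}" for i in range(counts.shape[1])],
    )
    return TaxonTable(df, pd.Series(domain, index=df.columns))


def signed_net(edges, nodes=None, domains=None):
    g = nx.Graph()
    for n in nodes or []:
        g.add_node(n, domain=(domains or {}).get(n, "bacteria"))
    for u, v, w in edges:
        for x in (u, v):
            if x not in g:
                g.add_node(x, domain=(domains or {}).get(x, "bacteria"))
        g.add_edge(u, v, weight=w, sign="positive" if w > 0 else "negative")
    return AssociationNetwork(graph=g)


class TestPrevalenceFilter:
    def test_boundary_is_inclusive(self):
        counts = np.zeros((20, 2), dtype=int)
        counts[:5, 0] = 1  # 5/20 = 25% -> retained
        counts[:4, 1] = 1  # 4/20 = 20% -> removed
        t = make_table(np.hstack([counts, np.ones((20, 1), dtype=int)]))
        out = prevalence_filter(t, 0.25)
        assert "T0" in out.taxon_ids and "T1" not in out.taxon_ids

    def test_idempotent(self, random_table):
        once = prevalence_filter(random_table, 0.25)
        twice = prevalence_filter(once, 0.25)
        assert list(once.taxon_ids) == list(twice.taxon_ids)

    def test_all_removed_raises(self):
        t = make_table(np.eye(30, 3, dtype=int))
        with pytest.raises(EmptyTableError):
            prevalence_filter(t, 0.9)


class TestClr:
    def test_equal_counts_give_zero_row(self):
        t = make_table(np.full((2, 5), 7))
        assert np.allclose(clr(t).to_numpy(), 0.0)

    def test_hand_computed_values(self):
        t = make_table([[1, 2, 4]])
        out = clr(t, pseudocount=0).to_numpy()[0]
        np.testing.assert_allclose(out, [-0.6931, 0.0, 0.6931], atol=1e-4)

    def test_rows_sum_to_zero(self, random_table):
        assert np.allclose(clr(random_table).sum(axis=1), 0.0, atol=1e-10)


class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        assert natural_connectivity(signed_net([], nodes=list("abcde"))) == (
            pytest.approx(0.0)
        )

    def test_triangle_closed_form(self):
        # spectrum {2, -1, -1}: ln((e^2 + 2 e^-1)/3) = 0.996311
        net = signed_net([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        expected = np.log((np.e**2 + 2 / np.e) / 3)
        assert natural_connectivity(net) == pytest.approx(expected, abs=1e-10)

    def test_path_closed_form(self):
        # spectrum {sqrt2, 0, -sqrt2}: ln((e^sqrt2 + 1 + e^-sqrt2)/3) = 0.579593
        net = signed_net([("a", "b", 1), ("b", "c", 1)])
        s2 = np.sqrt(2)
        expected = np.log((np.exp(s2) + 1 + np.exp(-s2)) / 3)
        assert natural_connectivity(net) == pytest.approx(expected, abs=1e-10)

    def test_matches_walk_sum_oracle_on_random_graphs(self):
        """Eigen route agrees with sum_k closed-walks/k! on graphs <= 8 nodes."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 9)
            A = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
            A = A + A.T
            trace = 0.0
            P = np.eye(n)
            fact = 1.0
            for k in range(60):
                trace += np.trace(P) / fact
                P = P @ A
                fact *= k + 1
            expected = np.log(trace / n)
            g = nx.from_numpy_array(A)
            assert natural_connectivity(g) == pytest.approx(expected, abs=1e-8)

    def test_edge_deletion_never_increases_connectivity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            base = natural_connectivity(g)
            u, v = list(g.edges)[0]
            g.remove_edge(u, v)
            assert natural_connectivity(g) <= base + 1e-12


class TestAttackStability:
    def test_star_hub_removed_first_and_collapses(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        curve = attack_stability(signed_net(edges), fraction=1.0)
        assert curve.removal_order[0] == "hub"
        assert curve.connectivity[1] == pytest.approx(0.0)
        assert curve.percent_reduction[1] == pytest.approx(100.0)

    def test_curve_length_matches_removals(self):
        edges = [("a", "b", 1), ("b", "c", 1), ("c", "d", -0.5)]
        curve = attack_stability(signed_net(edges), fraction=0.5)
        assert len(curve.connectivity) == len(curve.removal_order) + 1

    def test_isolated_node_removal_keeps_zero(self):
        curve = attack_stability(signed_net([], nodes=["a", "b"]), fraction=0.5)
        assert np.allclose(curve.connectivity, 0.0)
        assert np.allclose(curve.percent_reduction, 0.0)


class TestEdgeFilter:
    def test_boundary_weight_removed(self):
        net = signed_net([("a", "b", 0.15), ("c", "d", -0.2), ("e", "f", 0.151)])
        out = filter_weak_edges(net, 0.15)
        kept = {frozenset(e) for e in out.graph.edges}
        assert kept == {frozenset({"c", "d"}), frozenset({"e", "f"})}
        assert out.graph.number_of_nodes() == 6  # isolated nodes retained

    def test_zero_threshold_keeps_nonzero_edges(self):
        net = signed_net([("a", "b", 0.01)])
        assert filter_weak_edges(net, 0.0).graph.number_of_edges() == 1


class TestNetworkSummary:
    def test_complete_graph_degrees(self):
        edges = [(u, v, 1.0) for u, v in itertools.combinations("abcd", 2)]
        s = network_summary(signed_net(edges))
        assert s["average_degree"] == pytest.approx(3.0)
        assert s["degree_histogram"] == {3: 4}

    def test_interdomain_edge_counted_once(self):
        net = signed_net(
            [("b1", "f1", 0.5)], domains={"b1": "bacteria", "f1": "fungi"}
        )
        s = network_summary(net)
        assert s["edge_counts"]["positive_bacteria-fungi"] == 1
        assert sum(s["edge_counts"].values()) == 1

    def test_category_partition_sums_to_edge_total(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(12)]
        domains = {
            n: ("bacteria" if i < 7 else "fungi") for i, n in enumerate(nodes)
        }
        edges = [
            (u, v, float(rng.normal()))
            for u, v in itertools.combinations(nodes, 2)
            if rng.random() < 0.3
        ]
        edges = [(u, v, w) for u, v, w in edges if w != 0]
        s = network_summary(signed_net(edges, domains=domains))
        assert sum(s["edge_counts"].values()) == s["n_edges"]


class TestInference:
    def test_huge_penalty_yields_empty_graph(self):
        tb, tf, _ = simulate_graph_community([], 6, 4, 40, depth=500, seed=0)
        net = infer_network(
            clr(tb), clr(tf), penalty_path=np.array([1e6]), n_subsamples=5, seed=0
        )
        assert net.graph.number_of_edges() == 0

    def test_reproducible_under_fixed_seed(self):
        tb, tf, _ = simulate_graph_community(
            [(0, 1, 1), (1, 2, 1)], 6, 4, 60, depth=800, seed=1
        )
        n1 = infer_network(clr(tb), clr(tf), n_subsamples=10, seed=3)
        n2 = infer_network(clr(tb), clr(tf), n_subsamples=10, seed=3)
        assert sorted(n1.graph.edges) == sorted(n2.graph.edges)
        assert n1.chosen_penalty == n2.chosen_penalty

    def test_looser_threshold_never_sparser(self):
        tb, tf, _ = simulate_graph_community(
            [(i, i + 1, 1) for i in range(9)], 6, 4, 80, depth=1000, seed=2
        )
        cb, cf = clr(tb), clr(tf)
        tight = infer_network(cb, cf, n_subsamples=15, stability_threshold=0.03, seed=5)
        loose = infer_network(cb, cf, n_subsamples=15, stability_threshold=0.1, seed=5)
        assert loose.graph.number_of_edges() >= tight.graph.number_of_edges()

    def test_column_order_invariance(self):
        tb, tf, _ = simulate_graph_community(
            [(0, 1, 1), (2, 3, -1)], 6, 4, 60, depth=800, seed=4
        )
        cb = clr(tb)
        net1 = infer_network(cb, clr(tf), n_subsamples=10, seed=6)
        perm = list(cb.columns[::-1])
        net2 = infer_network(cb[perm], clr(tf), n_subsamples=10, seed=6)
        assert {frozenset(e) for e in net1.graph.edges} == {
            frozenset(e) for e in net2.graph.edges
        }
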