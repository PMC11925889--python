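import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microkeystone as mk
from microkeystone.containers import RelAbundanceTable, ValidationError
from microkeystone.network import (
    CooccurrenceNetwork,
    _eigenvector_centrality,
    _stress_centrality,
    build_network,
    keystone_nodes,
    node_centralities,
    spearman_matrix,
)


def _net_from_graph(g: nx.Graph) -> CooccurrenceNetwork:
    return CooccurrenceNetwork(graph=g, rho_min=0.6, alpha=0.05, correction="bh")


class TestSpearmanMatrix:
    def test_diagonal_and_monotone(self):
        df = pd.DataFrame(
            {"s1": [1, 1], "s2": [2, 4], "s3": [3, 9], "s4": [4, 16], "s5": [5, 25]},
            index=["x", "y"], dtype=float,
        )
        rho, p = spearman_matrix(df)
        assert rho.loc["x", "x"] == 1.0
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 5, size=(6, 12)).astype(float)  # many ties
        df = pd.DataFrame(
            data, index=[f"f{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(12)],
        )
        rho, p = spearman_matrix(df)
        expected_rho, expected_p = stats.spearmanr(data, axis=1)
        np.testing.assert_allclose(rho.to_numpy(), expected_rho, atol=1e-12)
        mask = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(
            p.to_numpy()[mask], expected_p[mask], atol=1e-10
        )

    def test_constant_feature_missing(self):
        df = pd.DataFrame(
            [[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]], index=["c", "v"],
            columns=[f"s{j}" for j in range(5)], dtype=float,
        )
        rho, _ = spearman_matrix(df)
        assert np.isnan(rho.loc["c", "v"])

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        with pytest.raises(ValidationError, match="5 samples"):
            spearman_matrix(df)


class TestBuildNetwork:
    def test_triangle_from_perfect_correlation(self):
        base = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        df = pd.DataFrame(
            [base, base * 2, base + 1], index=list("abc"),
            columns=[f"s{j}" for j in range(8)],
        )
        rho, p = spearman_matrix(df)
        net = build_network(rho, p)
        assert net.n_edges == 3
        assert set(net.graph.edges) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_zero_correlation_gives_edgeless_network(self):
        n = 10
        ids = list("abcd")
        rho = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        p = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=ids, columns=ids)
        net = build_network(rho, p)
        assert net.n_edges == 0
        assert net.n_nodes == 4

    def test_edge_count_matches_brute_force(self, community):
        table, meta, _ = community
        filt = mk.prevalence_filter(mk.to_relative_abundance(table), meta)
        rho, p = spearman_matrix(filt)
        net = build_network(rho, p, rho_min=0.6, alpha=0.05, correction="none")
        ids = list(rho.index)
        count = 0
        for i, j in itertools.combinations(range(len(ids)), 2):
            r, pv = rho.iloc[i, j], p.iloc[i, j]
            if not np.isnan(r) and abs(r) >= 0.6 and pv < 0.05:
                count += 1
        assert net.n_edges == count

    def test_invariant_to_feature_order(self, community):
        table, meta, _ = community
        filt = mk.prevalence_filter(mk.to_relative_abundance(table), meta)
        rho, p = spearman_matrix(filt)
        net1 = build_network(rho, p)
        perm = np.random.default_rng(0).permutation(len(rho))
        rho2 = rho.iloc[perm, perm]
        p2 = p.iloc[perm, perm]
        net2 = build_network(rho2, p2)
        assert set(map(frozenset, net1.graph.edges)) == set(
            map(frozenset, net2.graph.edges)
        )

    def test_bad_threshold_rejected(self):
        ids = ["a", "b"]
        rho = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        with pytest.raises(ValidationError):
            build_network(rho, rho, rho_min=1.5)


class TestCentralities:
    def test_star_graph(self):
        g = nx.star_graph(5)  # node 0 is the hub
        net = node_centralities(_net_from_graph(g))
        t = net.node_table
        assert t.loc[0, "degree"] == 5
        assert t.loc[0, "betweenness"] == pytest.approx(10.0)  # C(5,2) pairs
        assert t.loc[0, "stress"] == pytest.approx(10.0)
        assert (t.loc[1:, "betweenness"] == 0).all()
        ks = keystone_nodes(net)
        assert set(ks.loc[ks["metric"] == "degree", "node"]) == {0}
        assert set(ks["node"]) == {0}  # hub tops all four metrics

    def test_path_graph(self):
        g = nx.path_graph(4)  # a-b-c-d
        net = node_centralities(_net_from_graph(g))
        t = net.node_table
        assert t.loc[1, "betweenness"] == pytest.approx(2.0)
        assert t.loc[2, "betweenness"] == pytest.approx(2.0)
        assert t.loc[1, "stress"] == pytest.approx(2.0)

    def test_cycle_eigenvector_uniform(self):
        g = nx.cycle_graph(6)
        net = node_centralities(_net_from_graph(g))
        np.testing.assert_allclose(net.node_table["eigenvector"], 1.0)

    def test_degree_sum_is_twice_edges(self, community):
        table, meta, _ = community
        filt = mk.prevalence_filter(mk.to_relative_abundance(table), meta)
        rho, p = spearman_matrix(filt)
        net = node_centralities(build_network(rho, p))
        assert net.node_table["degree"].sum() == 2 * net.n_edges

    def test_matches_path_enumeration_on_small_graphs(self):
        """Betweenness and stress against exhaustive shortest-path listing."""
        rng = np.random.default_rng(9)
        for trial in range(12):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1e6)))
            net = node_centralities(_net_from_graph(g))
            bet = {v: 0.0 for v in g.nodes}
            stress = {v: 0.0 for v in g.nodes}
            for s, t in itertools.combinations(g.nodes, 2):
                if not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                for v in g.nodes:
                    if v in (s, t):
                        continue
                    through = sum(v in path for path in paths)
                    bet[v] += through / len(paths)
                    stress[v] += through
            for v in g.nodes:
                assert net.node_table.loc[v, "betweenness"] == pytest.approx(bet[v])
                assert net.node_table.loc[v, "stress"] == pytest.approx(stress[v])

    def test_eigenvector_matches_power_iteration(self):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        res = _eigenvector_centrality(g)
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            sub = g.subgraph(comp)
            if sub.number_of_edges() == 0:
                continue
            a = nx.to_numpy_array(sub, nodelist=comp)
            v = np.ones(len(comp))
            for _ in range(500):
                v = a @ v
                v /= np.linalg.norm(v)
            v /= v.max()
            for node, val in zip(comp, v):
                assert res[node] == pytest.approx(val, abs=1e-8)

    def test_empty_network_all_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        net = node_centralities(_net_from_graph(g))
        assert (net.node_table[["degree", "betweenness", "stress", "eigenvector"]] == 0).all().all()


class TestModulesAndKeystones:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        net = mk.detect_modules(node_centralities(_net_from_graph(g)))
        modules = {net.graph.nodes[v]["module"] for v in g.nodes}
        assert len(modules) == 2
        assert net.graph.nodes["a"]["module"] == net.graph.nodes["b"]["module"]

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        net = mk.detect_modules(node_centralities(_net_from_graph(g)))
        assert len({net.graph.nodes[v]["module"] for v in g.nodes}) == 1

    def test_planted_two_block_recovery(self):
        """Two internally-correlated blocks are recovered as two modules."""
        agree = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n = 40
            za = rng.standard_normal(n)
            zb = rng.standard_normal(n)
            rows = []
            for k in range(8):
                base = za if k < 4 else zb
                rows.append(0.9 * base + np.sqrt(1 - 0.81) * rng.standard_normal(n))
            df = pd.DataFrame(
                rows, index=[f"f{k}" for k in range(8)],
                columns=[f"s{j}" for j in range(n)],
            )
            rho, p = spearman_matrix(df)
            net = mk.detect_modules(node_centralities(build_network(rho, p)))
            m = [net.graph.nodes[f"f{k}"]["module"] for k in range(8)]
            ok = len(set(m[:4])) == 1 and len(set(m[4:])) == 1 and m[0] != m[4]
            agree += ok
        assert agree >= 9

    def test_tied_hubs_both_reported(self):
        g = nx.Graph()
        # two symmetric stars joined by one bridge edge between their hubs
        for leaf in range(3):
            g.add_edge("h1", f"a{leaf}")
            g.add_edge("h2", f"b{leaf}")
        g.add_edge("h1", "h2")
        net = node_centralities(_net_from_graph(g))
        ks = keystone_nodes(net)
        deg = ks[ks["metric"] == "degree"]
        assert set(deg["node"]) == {"h1", "h2"}

    def test_planted_hub_is_degree_keystone(self, community):
        table, meta, truth = community
        filt = mk.prevalence_filter(mk.to_relative_abundance(table), meta)
        rho, p = spearman_matrix(filt)
        net = node_centralities(build_network(rho, p))
        ks = keystone_nodes(net)
        assert truth.hub_id in set(ks.loc[ks["metric"] == "degree", "node"])
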