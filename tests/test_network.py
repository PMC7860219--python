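"""Co-expression network construction, k-core, hubs, and contrast."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from npomics import (
    CoexpressionNetworkBuilder,
    ValidationError,
    build_network,
    contrast_networks,
    kcore_decompose,
    pairwise_pearson,
    rank_hubs,
)
from npomics.network import edge_table, node_table, topology_summary


def pair_frame(x, y):
    return pd.DataFrame([x, y], index=["a", "b"])


class TestPairwisePearson:
    def test_antisymmetric_pair(self, rng):
        x = rng.normal(size=5)
        res = pairwise_pearson(pair_frame(x, -x))
        assert res["r"].iloc[0] == pytest.approx(-1.0)
        assert res["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_location_shift_invariance(self, rng):
        x = rng.normal(size=5)
        res = pairwise_pearson(pair_frame(x, x + 3.0))
        assert res["r"].iloc[0] == pytest.approx(1.0)

    def test_needs_three_samples(self):
        with pytest.raises(ValidationError):
            pairwise_pearson(pd.DataFrame([[1, 2], [3, 4]]))

    def test_zero_variance_feature_excluded_with_warning(self, rng):
        df = pd.DataFrame(
            [rng.normal(size=4), np.full(4, 7.0), rng.normal(size=4)],
            index=["a", "flat", "b"],
        )
        with pytest.warns(UserWarning, match="flat"):
            res = pairwise_pearson(df)
        assert set(res["feature_a"]) | set(res["feature_b"]) == {"a", "b"}

    def test_p_matches_exhaustive_permutation_test_n6(self):
        # oracle: all 720 orderings of one profile; on fixtures without
        # leverage points the t-transform p agrees with the discrete
        # permutation null to a few permutation quanta
        fixtures = [
            ([0.1, 0.5, -0.3, 0.8, -0.6, 0.2], [0.3, -0.2, 0.4, 0.9, -0.5, -0.1]),
            ([-1.0, -0.6, -0.2, 0.2, 0.6, 1.0], [0.5, -0.4, 0.1, -0.2, 0.6, -0.6]),
        ]
        for x, y in fixtures:
            x, y = np.asarray(x, float), np.asarray(y, float)
            p_t = pairwise_pearson(pair_frame(x, y))["p"].iloc[0]
            r_obs = abs(np.corrcoef(x, y)[0, 1])
            hits = sum(
                abs(np.corrcoef(x, y[list(perm)])[0, 1]) >= r_obs - 1e-12
                for perm in itertools.permutations(range(6))
            )
            assert p_t == pytest.approx(hits / 720, abs=0.03)

    def test_p_monotone_decreasing_in_abs_r(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 8)))
        res = pairwise_pearson(data)
        order = res["r"].abs().sort_values().index
        assert (np.diff(res.loc[order, "p"].to_numpy()) <= 1e-12).all()

    def test_invariant_to_sample_and_feature_order(self, rng):
        data = pd.DataFrame(rng.normal(size=(6, 8)), index=[f"g{i}" for i in range(6)])
        res1 = pairwise_pearson(data)
        shuffled = data.iloc[rng.permutation(6), rng.permutation(8)]
        res2 = pairwise_pearson(shuffled)
        key = lambda df: {
            frozenset((r.feature_a, r.feature_b)): round(r.r, 12)
            for r in df.itertuples()
        }
        assert key(res1) == key(res2)


class TestBuildNetwork:
    def test_impossible_r_threshold_gives_empty_edges(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 6)), index=list("abcde"))
        corr = pairwise_pearson(data)
        net = build_network(corr, q_threshold=1.1, r_threshold=1.0)
        # only exactly |r| = 1 pairs could survive; random data has none
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 5  # isolated nodes retained

    def test_no_thresholds_gives_complete_graph(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 6)), index=list("abcde"))
        net = build_network(pairwise_pearson(data), q_threshold=1.1, r_threshold=0.0)
        assert net.number_of_edges() == 10

    def test_handshake_identity(self, rng):
        data = pd.DataFrame(rng.normal(size=(12, 8)))
        net = build_network(pairwise_pearson(data), q_threshold=0.5, r_threshold=0.3)
        assert sum(d for _, d in net.degree) == 2 * net.number_of_edges()

    def test_node_layers_tagged(self, rng):
        data = pd.DataFrame(rng.normal(size=(3, 6)), index=["p1", "m1", "b1"])
        net = build_network(
            pairwise_pearson(data),
            q_threshold=1.1,
            r_threshold=0.0,
            node_layers={"p1": "protein", "m1": "mrna", "b1": "both"},
        )
        assert net.nodes["b1"]["layer"] == "both"

    def test_planted_module_recovered(self):
        # 10-feature module at rho=0.95 within 60 features, 20 samples
        rng = np.random.default_rng(7)
        n_samp, rho = 20, 0.95
        noise = rng.standard_normal((60, n_samp))
        f = rng.standard_normal(n_samp)
        values = noise.copy()
        values[:10] = np.sqrt(rho) * f + np.sqrt(1 - rho) * noise[:10]
        data = pd.DataFrame(values, index=[f"g{i}" for i in range(60)])
        net = build_network(pairwise_pearson(data), q_threshold=0.05, r_threshold=0.8)
        module = [f"g{i}" for i in range(10)]
        within = [(a, b) for a, b in itertools.combinations(module, 2)]
        n_within = sum(net.has_edge(a, b) for a, b in within)
        assert n_within / len(within) >= 0.8
        background_edges = [
            e for e in net.edges if not (e[0] in module and e[1] in module)
        ]
        n_background_pairs = 60 * 59 // 2 - len(within)
        assert len(background_edges) / n_background_pairs < 0.10

    def test_estimator_wrapper_matches_function_route(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 6)), columns=list("abcdef"))
        builder = CoexpressionNetworkBuilder(q_threshold=0.5, r_threshold=0.3).fit(X)
        direct = build_network(
            pairwise_pearson(X.T), q_threshold=0.5, r_threshold=0.3
        )
        assert set(builder.graph_.edges) == set(direct.edges)


def kcore_pruning_oracle(G):
    """kcore(v) by repeatedly deleting nodes of degree < k, k = 1, 2, ..."""
    core = {v: 0 for v in G}
    k = 1
    H = G.copy()
    while H.number_of_nodes():
        while True:
            low = [v for v in H if H.degree[v] < k]
            if not low:
                break
            H.remove_nodes_from(low)
        for v in H:
            core[v] = k
        k += 1
    return core


class TestKCore:
    def test_triangle(self):
        net = kcore_decompose(nx.complete_graph(3))
        assert all(net.nodes[v]["kcore"] == 2 for v in net)

    def test_star(self):
        net = kcore_decompose(nx.star_graph(5))
        assert all(net.nodes[v]["kcore"] == 1 for v in net)

    def test_random_graphs_match_pruning_oracle(self, rng):
        for i in range(100):
            n = int(rng.integers(2, 51))
            G = nx.gnp_random_graph(n, float(rng.uniform(0.02, 0.5)), seed=int(rng.integers(1 << 30)))
            net = kcore_decompose(G.copy())
            oracle = kcore_pruning_oracle(G)
            for v in G:
                assert net.nodes[v]["kcore"] == oracle[v]
                assert net.nodes[v]["kcore"] <= net.nodes[v]["degree"]


class TestRankHubs:
    def test_singleton(self):
        net = kcore_decompose(nx.empty_graph(1))
        assert rank_hubs(net) == [0]

    def test_clique_outranks_pendant(self):
        G = nx.complete_graph(5)
        G.add_edge(4, 99)  # pendant
        net = kcore_decompose(G)
        ranks = rank_hubs(net)
        assert ranks.index(99) == 5

    def test_top_n_longer_than_graph_returns_all(self):
        net = kcore_decompose(nx.path_graph(3))
        assert len(rank_hubs(net, top_n=10)) == 3

    def test_planted_module_members_are_top_hubs(self):
        rng = np.random.default_rng(11)
        n_samp, rho = 20, 0.95
        noise = rng.standard_normal((40, n_samp))
        f = rng.standard_normal(n_samp)
        values = noise.copy()
        values[:10] = np.sqrt(rho) * f + np.sqrt(1 - rho) * noise[:10]
        data = pd.DataFrame(values, index=[f"g{i:02d}" for i in range(40)])
        net = build_network(pairwise_pearson(data), q_threshold=0.05, r_threshold=0.8)
        top = set(rank_hubs(net, top_n=10))
        true_members = {f"g{i:02d}" for i in range(10)}
        assert len(top & true_members) >= 8


class TestContrast:
    def test_identical_networks_zero_difference(self):
        G = kcore_decompose(nx.gnp_random_graph(10, 0.3, seed=1))
        contrast = contrast_networks(G, G.copy())
        assert all(v == 0 for v in contrast.difference.values())

    def test_extreme_graphs(self):
        full = kcore_decompose(nx.complete_graph(10))
        empty = kcore_decompose(nx.empty_graph(10))
        contrast = contrast_networks(full, empty)
        assert contrast.difference["density"] == pytest.approx(1.0)
        assert contrast.idd["n_components"] == 1
        assert contrast.ivd["n_components"] == 10

    def test_summary_fields(self):
        G = kcore_decompose(nx.path_graph(4))
        s = topology_summary(G)
        assert s["largest_component_fraction"] == 1.0
        assert s["mean_degree"] == pytest.approx(1.5)


class TestExport:
    def test_tables_roundtrip_edges_and_nodes(self, rng):
        data = pd.DataFrame(rng.normal(size=(6, 8)), index=[f"g{i}" for i in range(6)])
        net = build_network(pairwise_pearson(data), q_threshold=0.9, r_threshold=0.2)
        edges = edge_table(net)
        nodes = node_table(net)
        assert len(edges) == net.number_of_edges()
        assert len(nodes) == net.number_of_nodes()
        assert set(edges.columns) == {"node_a", "node_b", "r", "p", "q"}

    def test_graphml_roundtrip(self, rng, tmp_path):
        data = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)])
        net = build_network(pairwise_pearson(data), q_threshold=0.9, r_threshold=0.2)
        path = tmp_path / "net.graphml"
        nx.write_graphml(net, path)
        back = nx.read_graphml(path)
        assert back.number_of_edges() == net.number_of_edges()
        for v in net.nodes:
            assert back.nodes[str(v)]["kcore"] == net.nodes[v]["kcore"]
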