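import numpy as np
import pytest

import networkx as nx

from conftest import make_net, random_adjacency
from oracles import (
    best_modularity_partition,
    brute_average_path_length,
    brute_betweenness,
    brute_closeness_reciprocal_mean,
    brute_clustering,
    brute_distances,
)
from ptnet.errors import ConfigurationError, DegenerateNetworkError
from ptnet.graph_metrics import (
    betweenness_counts,
    clustering_coefficients,
    detect_communities,
    greedy_modularity_communities,
    identify_hubs,
    modularity,
    node_metrics,
    shortest_path_lengths,
    topology_metrics,
)

P3 = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
TRIANGLE = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
STAR5 = [[0, 1, 1, 1, 1]] + [[1, 0, 0, 0, 0] for _ in range(4)]


def two_triangles():
    a = np.zeros((6, 6), int)
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        a[i, j] = a[j, i] = 1
    return a


class TestNodeMetrics:
    def test_path_graph(self):
        nm = node_metrics(make_net(P3))
        assert [x.degree for x in nm] == [1, 2, 1]
        assert nm[1].closeness == pytest.approx(1.0)
        assert nm[1].betweenness == pytest.approx(1.0)
        assert nm[0].betweenness == 0.0

    def test_star_center_routes_all_pairs(self):
        nm = node_metrics(make_net(STAR5))
        center, leaves = nm[0], nm[1:]
        assert center.degree == 4
        assert center.betweenness == pytest.approx(6.0)  # C(4,2) pairs
        assert all(leaf.betweenness == 0.0 for leaf in leaves)
        assert center.closeness == pytest.approx(1.0)

    def test_complete_graph_symmetry(self):
        k5 = np.ones((5, 5), int)
        np.fill_diagonal(k5, 0)
        nm = node_metrics(make_net(k5))
        assert all(x.degree == 4 and x.closeness == 1.0 and x.betweenness == 0.0
                   for x in nm)

    def test_isolated_node_closeness_zero(self):
        a = np.zeros((3, 3), int)
        a[0, 1] = a[1, 0] = 1
        nm = node_metrics(make_net(a))
        assert nm[2].closeness == 0.0 and nm[2].degree == 0

    def test_closeness_is_reciprocal_mean_not_reciprocal_sum(self):
        # star leaf: distances (1, 2, 2, 2) -> mean 1.75 -> C = 4/7
        nm = node_metrics(make_net(STAR5))
        assert nm[1].closeness == pytest.approx(4.0 / 7.0)

    def test_tied_shortest_paths_share_betweenness(self):
        # 4-cycle: two tied 2-step paths between each diagonal pair
        c4 = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]])
        b = betweenness_counts(c4)
        assert np.allclose(b, 0.5)


class TestBruteForceEquivalence:
    """Random-graph agreement with exhaustive path enumeration."""

    @pytest.mark.parametrize("trial", range(25))
    def test_metrics_agree_with_oracles(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 9))
        a = random_adjacency(rng, n, p=float(rng.uniform(0.2, 0.8)))
        assert np.allclose(shortest_path_lengths(a), brute_distances(a))
        assert np.allclose(betweenness_counts(a), brute_betweenness(a), atol=1e-9)
        assert np.allclose(clustering_coefficients(a), brute_clustering(a),
                           atol=1e-9)
        nm = node_metrics(make_net(a))
        assert np.allclose([x.closeness for x in nm],
                           brute_closeness_reciprocal_mean(a), atol=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_betweenness_matches_networkx(self, trial):
        rng = np.random.default_rng(2000 + trial)
        a = random_adjacency(rng, int(rng.integers(3, 9)))
        g = nx.from_numpy_array(a)
        expected = nx.betweenness_centrality(g, normalized=False)
        b = betweenness_counts(a)
        assert np.allclose(b, [expected[i] for i in range(a.shape[0])], atol=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_modularity_matches_networkx(self, trial):
        rng = np.random.default_rng(3000 + trial)
        a = random_adjacency(rng, 7)
        if a.sum() == 0:
            return
        labels = rng.integers(0, 3, size=7)
        g = nx.from_numpy_array(a)
        comms = [set(np.nonzero(labels == c)[0].tolist())
                 for c in np.unique(labels)]
        assert modularity(a, labels) == pytest.approx(
            nx.community.modularity(g, comms), abs=1e-9
        )


class TestTopologyMetrics:
    def test_triangle(self):
        t = topology_metrics(make_net(TRIANGLE))
        assert t.edge_density == 1.0
        assert t.average_path_length == 1.0
        assert t.average_clustering == 1.0
        assert t.modularity == pytest.approx(0.0)
        assert t.n_modules == 1

    def test_path_p3(self):
        t = topology_metrics(make_net(P3))
        assert t.edge_density == pytest.approx(2 / 3)
        assert t.average_path_length == pytest.approx(4 / 3)
        assert t.average_clustering == 0.0

    def test_two_disjoint_triangles(self):
        a = two_triangles()
        t = topology_metrics(make_net(a))
        assert t.n_modules == 2
        assert t.modularity == pytest.approx(0.5)
        assert modularity(a, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_empty_network_conventions(self):
        t = topology_metrics(make_net(np.zeros((4, 4), int)))
        assert t.edge_density == 0.0
        assert np.isnan(t.average_path_length)
        assert t.average_clustering == 0.0
        assert t.modularity == 0.0
        assert t.n_modules == 4  # one module per node

    def test_single_node_degenerate(self):
        with pytest.raises(DegenerateNetworkError):
            topology_metrics(make_net(np.zeros((1, 1), int)))

    def test_al_excludes_disconnected_pairs(self):
        a = np.zeros((4, 4), int)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        t = topology_metrics(make_net(a))
        assert t.average_path_length == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(15))
    def test_al_matches_brute_force(self, trial):
        rng = np.random.default_rng(4000 + trial)
        a = random_adjacency(rng, int(rng.integers(3, 9)))
        t = topology_metrics(make_net(a))
        expected = brute_average_path_length(a)
        if np.isnan(expected):
            assert np.isnan(t.average_path_length)
        else:
            assert t.average_path_length == pytest.approx(expected, abs=1e-9)

    def test_relabeling_invariance(self, rng):
        a = random_adjacency(rng, 8)
        perm = rng.permutation(8)
        b = a[np.ix_(perm, perm)]
        t1 = topology_metrics(make_net(a))
        t2 = topology_metrics(make_net(b))
        assert t1.edge_density == pytest.approx(t2.edge_density)
        assert np.allclose(t1.average_path_length, t2.average_path_length,
                           equal_nan=True)
        assert t1.average_clustering == pytest.approx(t2.average_clustering)
        nm1 = sorted(x.degree for x in node_metrics(make_net(a)))
        nm2 = sorted(x.degree for x in node_metrics(make_net(b)))
        assert nm1 == nm2

    def test_adding_edge_never_decreases_density(self, rng):
        a = random_adjacency(rng, 6, p=0.3)
        t_before = topology_metrics(make_net(a))
        missing = [(i, j) for i in range(6) for j in range(i + 1, 6) if not a[i, j]]
        if not missing:
            return
        i, j = missing[0]
        a2 = a.copy()
        a2[i, j] = a2[j, i] = 1
        assert topology_metrics(make_net(a2)).edge_density > t_before.edge_density


class TestCommunityDetection:
    def test_all_in_one_module_q_is_zero(self, rng):
        a = random_adjacency(rng, 7, p=0.5)
        if a.sum() == 0:
            return
        assert modularity(a, [0] * 7) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(8))
    def test_greedy_q_close_to_exhaustive_optimum(self, trial):
        """Greedy agglomeration reaches the exhaustive-search optimum on
        tiny graphs (it is a heuristic, so allow a small gap)."""
        rng = np.random.default_rng(5000 + trial)
        a = random_adjacency(rng, 6, p=0.5)
        labels = greedy_modularity_communities(a)
        q = modularity(a, labels)
        q_best = best_modularity_partition(a)
        assert q <= q_best + 1e-12
        assert q >= q_best - 0.15

    def test_greedy_is_deterministic(self, rng):
        a = random_adjacency(rng, 10, p=0.4)
        assert greedy_modularity_communities(a) == greedy_modularity_communities(a)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_communities(np.zeros((3, 3), int), method="mystery")

    def test_louvain_alternative_runs(self):
        labels = detect_communities(two_triangles(), method="louvain", seed=1)
        assert len(set(labels)) == 2


class TestIdentifyHubs:
    def test_star_center_is_hub_and_mediator(self):
        nm = node_metrics(make_net(STAR5))
        rep = identify_hubs(nm, top_n=1)
        assert rep.hubs.iloc[0]["trait"] == "A"
        assert rep.mediators.iloc[0]["trait"] == "A"

    def test_complete_graph_ties_flagged_name_order(self):
        k4 = np.ones((4, 4), int)
        np.fill_diagonal(k4, 0)
        rep = identify_hubs(node_metrics(make_net(k4)), top_n=4)
        assert rep.tied_hubs and rep.tied_mediators
        assert list(rep.hubs["trait"]) == ["A", "B", "C", "D"]

    def test_distinct_degrees_rank_first(self):
        # degrees (3, 2, 2, 1): A-B, A-C, A-D, B-C
        a = np.zeros((4, 4), int)
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2)]:
            a[i, j] = a[j, i] = 1
        rep = identify_hubs(node_metrics(make_net(a)), top_n=2)
        assert rep.hubs.iloc[0]["trait"] == "A"
        assert rep.hubs.iloc[0]["k"] == 3

    def test_top_n_capped_with_warning(self):
        nm = node_metrics(make_net(P3))
        with pytest.warns(UserWarning, match="returning all"):
            rep = identify_hubs(nm, top_n=10)
        assert len(rep.hubs) == 3
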