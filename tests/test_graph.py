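import numpy as np
import pytest

import connrep as cr
from connrep.graph import (
    CoAssignmentMatrix,
    characteristic_path_length,
    global_measures,
    is_weighted,
    normalized_global_measures,
)
from oracles import brute_force_measures, random_connected_graph


def _triangle():
    a = np.ones((3, 3)) - np.eye(3)
    return a


def _path3():
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)


def _star(n):
    a = np.zeros((n, n))
    a[0, 1:] = a[1:, 0] = 1.0
    return a


class TestDistances:
    def test_triangle_all_unit_distances(self):
        d = cr.shortest_path_lengths(_triangle())
        off = d[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_path_graph_two_hops(self):
        d = cr.shortest_path_lengths(_path3())
        assert d[0, 2] == 2.0

    def test_weighted_edge_length_is_inverse_weight(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert cr.shortest_path_lengths(w)[0, 1] == pytest.approx(2.0)

    def test_unreachable_pairs_are_infinite(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        d = cr.shortest_path_lengths(a)
        assert np.isinf(d[0, 2])

    def test_negative_weight_rejected(self):
        w = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            cr.shortest_path_lengths(w)


class TestCharacteristicPathLength:
    def test_triangle_and_path(self):
        lam, nodal, n_inf = characteristic_path_length(
            cr.shortest_path_lengths(_triangle()))
        assert lam == pytest.approx(1.0) and n_inf == 0
        lam, nodal, _ = characteristic_path_length(
            cr.shortest_path_lengths(_path3()))
        assert lam == pytest.approx(4.0 / 3.0)
        np.testing.assert_allclose(nodal, [1.5, 1.0, 1.5])

    def test_complete_graph_unit_length(self):
        a = np.ones((6, 6)) - np.eye(6)
        lam, _, _ = characteristic_path_length(cr.shortest_path_lengths(a))
        assert lam == pytest.approx(1.0)

    def test_infinite_pairs_excluded_and_counted(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        lam, _, n_inf = characteristic_path_length(cr.shortest_path_lengths(a))
        assert lam == pytest.approx(1.0)
        assert n_inf == 8

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError, match="no finite"):
            characteristic_path_length(cr.shortest_path_lengths(np.zeros((3, 3))))


class TestClustering:
    def test_binary_triangle_and_star(self):
        np.testing.assert_allclose(cr.clustering_coefficient(_triangle()), 1.0)
        assert cr.clustering_coefficient(_star(5))[0] == 0.0

    def test_weighted_triangle_onnela_value(self):
        w = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.5], [1.0, 0.5, 0.0]])
        c = cr.clustering_coefficient(w)
        assert c[0] == pytest.approx(0.5 ** (1 / 3), abs=1e-9)
        assert c[0] == pytest.approx(0.7937, abs=1e-4)


class TestEfficiency:
    def test_complete_path_and_empty(self):
        a = np.ones((5, 5)) - np.eye(5)
        assert cr.efficiency(a) == pytest.approx(1.0)
        assert cr.efficiency(_path3()) == pytest.approx(5.0 / 6.0)
        assert cr.efficiency(np.zeros((4, 4))) == 0.0

    def test_nodal_efficiency_of_neighbor_subgraph(self):
        # star center's neighbors are mutually unreachable -> efficiency 0;
        # in a triangle every neighbor pair is adjacent -> efficiency 1
        _, nodal = cr.efficiency(_star(4), nodal=True)
        assert nodal[0] == 0.0
        _, nodal = cr.efficiency(_triangle(), nodal=True)
        np.testing.assert_allclose(nodal, 1.0)


class TestBetweenness:
    def test_path_middle_complete_and_star(self):
        assert cr.betweenness(_path3())[1] == pytest.approx(1.0)
        a = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(cr.betweenness(a), 0.0)
        assert cr.betweenness(_star(4))[0] == pytest.approx(1.0)

    def test_weighted_paths_use_inverse_weight_lengths(self):
        # strong 2-hop route (via node 1) beats the weak direct edge
        w = np.array([[0.0, 0.9, 0.1], [0.9, 0.0, 0.9], [0.1, 0.9, 0.0]])
        assert cr.betweenness(w)[1] == pytest.approx(1.0)


class TestOracleEquivalence:
    def test_random_small_graphs_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(3, 8))
            adj = random_connected_graph(rng, n)
            ours = global_measures(adj)
            ref = brute_force_measures(adj)
            for key in ("lambda", "clustering", "efficiency", "betweenness"):
                assert ours[key] == pytest.approx(ref[key], abs=1e-12), key

    def test_unit_weight_networks_reduce_to_binary(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            adj = random_connected_graph(rng, 6)
            binary = global_measures(adj, weighted=False)
            asweighted = global_measures(adj, weighted=True)
            for key in binary:
                assert binary[key] == pytest.approx(asweighted[key], abs=1e-12)

    def test_permutation_equivariance(self, rng):
        w = np.abs(cr.pearson_correlation(rng.normal(size=(80, 12))))
        perm = rng.permutation(12)
        nm = cr.nodal_measures(w)
        nm_p = cr.nodal_measures(w[np.ix_(perm, perm)])
        np.testing.assert_allclose(nm_p.clustering, nm.clustering[perm])
        np.testing.assert_allclose(nm_p.betweenness, nm.betweenness[perm])
        g = global_measures(w)
        g_p = global_measures(w[np.ix_(perm, perm)])
        for key in g:
            assert g[key] == pytest.approx(g_p[key])


class TestHubScores:
    def test_selection_size_is_twenty_percent(self, rng):
        w = np.abs(cr.pearson_correlation(rng.normal(size=(200, 50))))
        hubs = cr.hub_scores(cr.nodal_measures(w, include_efficiency=False))
        assert hubs.score.max() <= 4
        # each criterion selects exactly round(0.2 * 50) = 10 nodes
        assert hubs.score.sum() == 40

    def test_node_best_on_all_criteria_is_a_hub(self):
        from connrep.graph import NodalMeasures
        p = 10
        nm = NodalMeasures(
            degree=np.arange(p, dtype=float),  # node 9 highest
            path_length=np.arange(p, 0, -1, dtype=float),  # node 9 lowest
            clustering=np.arange(p, 0, -1, dtype=float),  # node 9 lowest
            efficiency=np.zeros(p),
            betweenness=np.arange(p, dtype=float),  # node 9 highest
        )
        hubs = cr.hub_scores(nm)
        assert hubs.score[9] == 4 and hubs.is_hub[9]

    def test_single_criterion_is_not_enough(self):
        from connrep.graph import NodalMeasures
        p = 10
        nm = NodalMeasures(
            degree=np.r_[np.zeros(p - 1), 10.0],  # node 9 top degree only
            path_length=np.r_[np.arange(1, p, dtype=float), 9.0],
            clustering=np.r_[np.arange(1, p, dtype=float), 9.0],
            efficiency=np.zeros(p),
            betweenness=np.r_[np.arange(p - 1, 0, -1, dtype=float), 0.0],
        )
        hubs = cr.hub_scores(nm)
        assert hubs.score[9] == 1 and not hubs.is_hub[9]


class TestNewmanCoassignment:
    def test_two_cliques_recovered_with_certainty(self):
        a = np.zeros((10, 10))
        a[:5, :5] = 1.0
        a[5:, 5:] = 1.0
        np.fill_diagonal(a, 0.0)
        cm, labels = cr.newman_coassignment(a, n_realizations=20, seed=0)
        assert np.all(cm.matrix[:5, :5] == 1.0)
        assert np.all(cm.matrix[5:, 5:] == 1.0)
        assert np.all(cm.matrix[:5, 5:] == 0.0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        assert labels.min() == 1

    def test_single_realization_is_binary(self, rng):
        w = np.abs(cr.pearson_correlation(rng.normal(size=(60, 12))))
        cm, _ = cr.newman_coassignment(w, n_realizations=1, seed=1)
        assert set(np.unique(cm.matrix)) <= {0.0, 1.0}

    def test_probabilities_well_formed(self, rng):
        w = np.abs(cr.pearson_correlation(rng.normal(size=(60, 15))))
        cm, _ = cr.newman_coassignment(w, n_realizations=25, seed=2)
        assert np.allclose(cm.matrix, cm.matrix.T)
        assert np.all(np.diag(cm.matrix) == 1.0)
        assert cm.matrix.min() >= 0.0 and cm.matrix.max() <= 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cr.newman_coassignment(np.zeros((4, 4)))


class TestNullNetworks:
    def test_binary_null_preserves_edge_count(self, rng):
        adj = cr.binarize_by_density(
            np.abs(cr.pearson_correlation(rng.normal(size=(100, 30)))), 0.2)
        for null in cr.equivalent_random_networks(adj, n_null=5, seed=3):
            assert null.sum() == adj.sum()
            assert np.all(np.diag(null) == 0.0)

    def test_weighted_null_preserves_weight_multiset(self, rng):
        w = np.abs(cr.pearson_correlation(rng.normal(size=(100, 20))))
        iu = np.triu_indices(20, 1)
        for null in cr.equivalent_random_networks(w, n_null=5, seed=4):
            np.testing.assert_allclose(np.sort(null[iu]), np.sort(w[iu]))
            assert is_weighted(null)

    def test_different_seeds_give_different_nulls(self, rng):
        w = np.abs(cr.pearson_correlation(rng.normal(size=(100, 20))))
        a = cr.equivalent_random_networks(w, n_null=1, seed=0)[0]
        b = cr.equivalent_random_networks(w, n_null=1, seed=1)[0]
        assert not np.array_equal(a, b)


class TestNormalization:
    def test_value_equal_to_null_mean_gives_one(self):
        assert cr.normalize(2.5, [2.0, 3.0]) == pytest.approx(1.0)

    def test_zero_null_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cr.normalize(1.0, [0.0, 0.0])

    def test_er_graph_self_normalizes_to_one(self, rng):
        # an ER graph is itself a draw from the binary null ensemble
        p, k = 60, 350
        iu = np.triu_indices(p, 1)
        adj = np.zeros((p, p))
        sel = rng.choice(iu[0].size, k, replace=False)
        adj[iu[0][sel], iu[1][sel]] = 1.0
        adj += adj.T
        res = normalized_global_measures(adj, n_null=30, seed=8)
        for name, r in res.items():
            band = 3.2 * r["null_sd"] / r["null_mean"]
            assert abs(r["normalized"] - 1.0) <= band, name
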