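import numpy as np
import networkx as nx
import pytest

import oracles
from hdbn.netmetrics import (assortativity, clustering_weighted, compute_metrics,
                             density, global_efficiency, local_efficiency,
                             path_length, rich_club, rich_club_curve,
                             ring_lattice_with_shortcuts, small_worldness,
                             transitivity_weighted)


def unit_complete(n):
    return np.ones((n, n)) - np.eye(n)


def unit_path3():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    return w


def unit_star(n):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


class TestHandExamples:
    def test_density(self):
        assert density(unit_complete(5)) == 1.0
        assert density(np.zeros((4, 4))) == 0.0
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            w[i, j] = w[j, i] = 0.7
        assert density(w) == pytest.approx(0.5)

    def test_clustering_triangle_unit(self):
        c, mean = clustering_weighted(unit_complete(3))
        assert np.allclose(c, 1.0)
        assert mean == pytest.approx(1.0)

    def test_clustering_path_middle_zero(self):
        c, _ = clustering_weighted(unit_path3())
        assert c[1] == 0.0

    def test_clustering_weighted_triangle(self):
        # weights (1, 1, 0.125): every node C = 0.125^(1/3) = 0.5
        w = np.array([[0, 1, 1], [1, 0, 0.125], [1, 0.125, 0]], dtype=float)
        c, _ = clustering_weighted(w)
        assert np.allclose(c, 0.5)

    def test_transitivity_unit_triangle(self):
        assert transitivity_weighted(unit_complete(3)) == pytest.approx(1.0)

    def test_transitivity_star_is_zero_single_edge_nan(self):
        # the star hub has connected triples but no triangles -> 0
        assert transitivity_weighted(unit_star(4)) == 0.0
        # no node of degree >= 2 -> the 0/0 case is reported as missing
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert np.isnan(transitivity_weighted(w))

    def test_path_length(self):
        assert path_length(unit_complete(4)) == pytest.approx(1.0)
        assert path_length(unit_path3()) == pytest.approx(4 / 3)

    def test_path_length_scales_inversely_with_weights(self):
        w = unit_path3()
        assert path_length(w * 0.5) == pytest.approx(2 * path_length(w))

    def test_global_efficiency(self):
        assert global_efficiency(unit_complete(4)) == pytest.approx(1.0)
        assert global_efficiency(unit_path3()) == pytest.approx(5 / 6)
        assert global_efficiency(np.zeros((3, 3))) == 0.0

    def test_local_efficiency(self):
        _, m = local_efficiency(unit_complete(4))
        assert m == pytest.approx(1.0)
        vals, m = local_efficiency(unit_star(5))
        assert np.allclose(vals, 0.0) and m == 0.0

    def test_assortativity_star_minus_one(self):
        assert assortativity(unit_star(5)) == pytest.approx(-1.0)

    def test_assortativity_undefined_cases(self):
        assert np.isnan(assortativity(unit_complete(4)))
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        assert np.isnan(assortativity(w))

    def test_rich_club(self):
        assert rich_club(unit_complete(5), 2) == pytest.approx(1.0)
        assert np.isnan(rich_club(unit_star(5), 1))  # only the hub survives


class TestOracleEquivalence:
    """Every metric matches brute-force enumeration on random small graphs."""

    @pytest.mark.parametrize("trial", range(30))
    def test_all_metrics_match_bruteforce(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 9))
        w = oracles.random_weighted_graph(rng, n, p_edge=0.6)
        if not w.any():
            return
        assert density(w) == pytest.approx(oracles.bf_density(w), abs=1e-9)
        c, _ = clustering_weighted(w)
        assert np.allclose(c, oracles.bf_clustering(w), atol=1e-9)
        t_ours = transitivity_weighted(w)
        t_bf = oracles.bf_transitivity(w)
        assert (np.isnan(t_ours) and np.isnan(t_bf)) or t_ours == pytest.approx(t_bf, abs=1e-9)
        assert global_efficiency(w) == pytest.approx(oracles.bf_global_efficiency(w), abs=1e-9)
        le, _ = local_efficiency(w)
        assert np.allclose(le, oracles.bf_local_efficiency(w), atol=1e-9)
        a_ours, a_bf = assortativity(w), oracles.bf_assortativity(w)
        assert (np.isnan(a_ours) and np.isnan(a_bf)) or a_ours == pytest.approx(a_bf, abs=1e-9)
        for k in range(n):
            r_ours, r_bf = rich_club(w, k), oracles.bf_rich_club(w, k)
            assert (np.isnan(r_ours) and np.isnan(r_bf)) or r_ours == pytest.approx(r_bf, abs=1e-9)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert path_length(w) == pytest.approx(oracles.bf_path_length(w), abs=1e-9)

    def test_clustering_matches_networkx_onnela(self, rng):
        w = oracles.random_weighted_graph(rng, 8, p_edge=0.7)
        w = w / w.max()  # networkx's Onnela form rescales by the max weight
        g = nx.from_numpy_array(w)
        expected = nx.clustering(g, weight="weight")  # networkx uses Onnela's form
        c, _ = clustering_weighted(w)
        for i in range(8):
            assert c[i] == pytest.approx(expected[i], abs=1e-9)


class TestInvariances:
    def test_permutation_invariance(self, rng):
        w = oracles.random_weighted_graph(rng, 7, p_edge=0.6)
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        assert density(w) == pytest.approx(density(wp))
        assert clustering_weighted(w)[1] == pytest.approx(clustering_weighted(wp)[1])
        assert transitivity_weighted(w) == pytest.approx(transitivity_weighted(wp))
        assert global_efficiency(w) == pytest.approx(global_efficiency(wp))
        assert local_efficiency(w)[1] == pytest.approx(local_efficiency(wp)[1])

    def test_density_increases_with_edge(self, rng):
        w = oracles.random_weighted_graph(rng, 6, p_edge=0.4)
        zeros = np.argwhere((np.triu(np.ones((6, 6)), 1) > 0) & (w == 0))
        if len(zeros) == 0:
            return
        i, j = zeros[0]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 0.5
        assert density(w2) > density(w)

    def test_global_efficiency_monotone_in_weight(self, rng):
        w = oracles.random_weighted_graph(rng, 6, p_edge=0.6)
        edges = np.argwhere(np.triu(w, 1) > 0)
        i, j = edges[0]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = min(1.0, w[i, j] * 1.5)
        assert global_efficiency(w2) >= global_efficiency(w) - 1e-12


class TestSmallWorldness:
    def test_complete_graph_sigma_exactly_one(self):
        res = small_worldness(unit_complete(8), n_null=5, seed=1)
        assert res.sigma == pytest.approx(1.0)
        assert res.c_rand_sd == 0.0

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        w = ring_lattice_with_shortcuts(seed=7)
        res = small_worldness(w, n_null=30, seed=7)
        assert res.sigma > 1.0

    def test_deterministic_given_seed(self):
        w = ring_lattice_with_shortcuts(seed=3)
        a = small_worldness(w, n_null=10, seed=11)
        b = small_worldness(w, n_null=10, seed=11)
        assert a.sigma == b.sigma
        assert a.c_rand_mean == b.c_rand_mean

    def test_random_graph_sigma_near_one(self):
        # Erdos-Renyi-like graph is its own null: sigma within the null spread
        rng = np.random.default_rng(5)
        w = oracles.random_weighted_graph(rng, 36, p_edge=0.12)
        res = small_worldness(w, n_null=50, seed=5)
        rel_sd = max(res.c_rand_sd / res.c_rand_mean, res.l_rand_sd / res.l_rand_mean)
        assert abs(res.sigma - 1.0) < 6 * max(rel_sd, 0.02)

    def test_rewiring_preserves_degree_sequence(self):
        from hdbn.netmetrics import _rewire_degree_preserving
        rng = np.random.default_rng(0)
        w = ring_lattice_with_shortcuts(seed=1)
        a = (w > 0).astype(int)
        ar = _rewire_degree_preserving(a, 10, rng)
        assert np.array_equal(ar.sum(0), a.sum(0))
        assert np.array_equal(ar, ar.T)
        assert not np.diag(ar).any()
        assert not np.array_equal(ar, a)  # actually rewired something


def test_compute_metrics_full_set(rng):
    w = oracles.random_weighted_graph(rng, 10, p_edge=0.6)
    m = compute_metrics(w, n_null=5, seed=0, rich_club_levels=True)
    d = m.to_dict()
    assert set(d) >= {"density", "clustering_mean", "transitivity", "path_length",
                      "global_efficiency", "local_efficiency_mean", "assortativity",
                      "small_worldness"}
    assert m.rich_club  # curve populated
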