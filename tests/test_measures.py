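import numpy as np
import pytest

import oracles
from wmnet.measures import (
    betweenness,
    global_measures,
    local_clustering,
    measure_network,
    nodal_path_length,
    node_degree,
    node_strength,
    shortest_path_distances,
)


def star(n=5, w=1.0):
    a = np.zeros((n, n))
    a[0, 1:] = w
    a[1:, 0] = w
    return a


def chain3(w=1.0):
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = w
    a[1, 2] = a[2, 1] = w
    return a


def triangle(wab=1.0, wac=1.0, wbc=1.0):
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = wab
    a[0, 2] = a[2, 0] = wac
    a[1, 2] = a[2, 1] = wbc
    return a


class TestExamples:
    def test_degree_triangle_and_star(self):
        assert node_degree(triangle()).tolist() == [2, 2, 2]
        assert node_degree(star()).tolist() == [4, 1, 1, 1, 1]

    def test_strength_handshake_identity(self):
        rng = np.random.default_rng(3)
        w = oracles.random_weighted_graph(rng, 8, 0.5)
        s = node_strength(w)
        assert s.sum() == pytest.approx(2 * np.triu(w, 1).sum())

    def test_onnela_clustering_hand_example(self):
        # w_ab = w_ac = 1, w_bc = 0.125 -> C_a = (1*1*0.125)^(1/3) = 0.5
        c = local_clustering(triangle(1.0, 1.0, 0.125))
        assert c[0] == pytest.approx(0.5)

    def test_clustering_uniform_triangle_is_one_path_is_zero(self):
        assert local_clustering(triangle()).tolist() == pytest.approx([1, 1, 1])
        assert local_clustering(chain3()).tolist() == [0, 0, 0]

    def test_distances_inverse_weight_mapping(self):
        a = np.zeros((2, 2))
        a[0, 1] = a[1, 0] = 2.0
        assert shortest_path_distances(a)[0, 1] == pytest.approx(0.5)

    def test_distances_chain_and_disconnection(self):
        d = shortest_path_distances(chain3())
        assert d[0, 2] == pytest.approx(2.0)
        two = np.zeros((4, 4))
        two[0, 1] = two[1, 0] = 1.0
        two[2, 3] = two[3, 2] = 1.0
        d = shortest_path_distances(two)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_nodal_path_length_star(self):
        d = shortest_path_distances(star())
        lp = nodal_path_length(d)
        assert lp[0] == pytest.approx(1.0)
        assert lp[1] == pytest.approx((1 + 3 * 2) / 4)

    def test_nodal_path_length_isolated_node_warns(self):
        d = shortest_path_distances(np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="isolated"):
            lp = nodal_path_length(d)
        assert lp.tolist() == [0, 0, 0]

    def test_betweenness_star_closed_form(self):
        bc = betweenness(star())
        assert bc[0] == pytest.approx(4 * 3 / 2)
        assert bc[1:].tolist() == [0, 0, 0, 0]

    def test_betweenness_complete_uniform_zero(self):
        w = np.ones((5, 5)) - np.eye(5)
        assert betweenness(w).tolist() == [0] * 5

    def test_global_chain_hand_enumeration(self):
        g = global_measures(chain3())
        assert g.path_length == pytest.approx(4 / 3)
        assert g.global_efficiency == pytest.approx(5 / 6)

    def test_global_complete_unit_graph(self):
        w = np.ones((6, 6)) - np.eye(6)
        g = global_measures(w)
        assert g.path_length == pytest.approx(1.0)
        assert g.global_efficiency == pytest.approx(1.0)

    def test_edgeless_network_flagged(self):
        with pytest.warns(UserWarning):
            g = global_measures(np.zeros((3, 3)))
        assert np.isnan(g.path_length)
        assert g.global_efficiency == 0.0


class TestOracleEquivalence:
    """All measures match exhaustive brute-force implementations."""

    @pytest.mark.parametrize("seed", range(4))
    def test_random_networks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            w = oracles.random_weighted_graph(rng, n, float(rng.uniform(0.3, 0.9)))
            loc, glob = measure_network(w)
            assert np.allclose(loc.degree, oracles.brute_degree(w), atol=1e-9)
            assert np.allclose(loc.strength, oracles.brute_strength(w), atol=1e-9)
            assert np.allclose(loc.clustering, oracles.brute_onnela_clustering(w), atol=1e-9)
            bd = oracles.brute_distances(w)
            d = shortest_path_distances(w)
            assert np.allclose(
                np.where(np.isfinite(d), d, -1), np.where(np.isfinite(bd), bd, -1), atol=1e-9
            )
            assert np.allclose(loc.path_length, oracles.brute_nodal_path_length(bd), atol=1e-9)
            assert np.allclose(loc.betweenness, oracles.brute_betweenness(w), atol=1e-9)
            bg = oracles.brute_global(w)
            got = glob.as_dict()
            for key, val in bg.items():
                if np.isnan(val):
                    assert np.isnan(got[key])
                else:
                    assert got[key] == pytest.approx(val, abs=1e-9)


class TestInvariances:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        w = oracles.random_weighted_graph(rng, 8, 0.6)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        loc, glob = measure_network(w)
        locp, globp = measure_network(wp)
        for name, vec in loc.as_dict().items():
            assert np.allclose(locp.as_dict()[name], vec[perm], atol=1e-9), name
        for key, val in glob.as_dict().items():
            if val is not None:
                assert globp.as_dict()[key] == pytest.approx(val, abs=1e-9)

    def test_weight_scaling_behavior(self):
        rng = np.random.default_rng(12)
        w = oracles.random_weighted_graph(rng, 8, 0.6)
        c = 3.7
        loc, _ = measure_network(w)
        locc, _ = measure_network(c * w)
        assert np.array_equal(locc.degree, loc.degree)
        assert np.allclose(locc.clustering, loc.clustering, atol=1e-12)
        assert np.allclose(locc.strength, c * loc.strength, atol=1e-9)
        assert np.allclose(locc.betweenness, loc.betweenness, atol=1e-9)
        d = shortest_path_distances(w)
        dc = shortest_path_distances(c * w)
        assert np.allclose(dc, d / c, atol=1e-12)
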