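import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemiconn.metrics import (
    asymmetry_index, cohort_metric_tables, global_efficiency,
    local_efficiency, mean_nodal_ai, nodal_efficiency, network_metrics,
    shortest_paths,
)

from conftest import random_weighted_graph


def brute_force_shortest_paths(w, rule="inverse"):
    """Exhaustive simple-path enumeration oracle (small n only)."""
    n = w.shape[0]
    conv = (lambda x: 1.0 / x) if rule == "inverse" else (lambda x: -np.log(x))
    L = np.full((n, n), np.inf)
    np.fill_diagonal(L, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = np.inf
            others = [k for k in range(n) if k not in (i, j)]
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    path = (i,) + mid + (j,)
                    tot = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        tot += conv(w[a, b])
                    if ok:
                        best = min(best, tot)
            L[i, j] = best
    return L


class TestShortestPaths:
    def test_three_node_chain_hand_value(self):
        """Chain A-B-C with weights 0.5: L_AC = 1/0.5 + 1/0.5 = 4."""
        w = np.array([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
        L = shortest_paths(w).lengths
        assert L[0, 2] == pytest.approx(4.0)
        assert L[0, 1] == pytest.approx(2.0)

    def test_complete_unit_graph(self):
        w = np.ones((4, 4)) - np.eye(4)
        L = shortest_paths(w).lengths
        assert np.allclose(L[~np.eye(4, dtype=bool)], 1.0)

    def test_disconnected_pair_is_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        L = shortest_paths(w).lengths
        assert np.isinf(L[0, 2]) and np.isinf(L[2, 1])

    @pytest.mark.parametrize("rule", ["inverse", "neglog"])
    def test_matches_bruteforce_enumeration(self, rule):
        rng = np.random.default_rng(7)
        for _ in range(100):
            w = random_weighted_graph(rng, 6, density=0.5)
            L = shortest_paths(w, rule).lengths
            oracle = brute_force_shortest_paths(w, rule)
            assert np.allclose(L, oracle, atol=1e-10, equal_nan=False)

    def test_asymmetric_matrix_rejected(self):
        w = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            shortest_paths(w)


class TestGlobalEfficiency:
    def test_complete_unit_graph_is_one(self):
        w = np.ones((5, 5)) - np.eye(5)
        assert global_efficiency(shortest_paths(w)) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(shortest_paths(np.zeros((4, 4)))) == 0.0

    def test_three_node_unit_path_hand_enumeration(self):
        """A-B-C unit weights: ordered pairs give 2*(1 + 1 + 1/2)/6 = 5/6."""
        w = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
        assert global_efficiency(shortest_paths(w)) == pytest.approx(5.0 / 6.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((1, 1)))


class TestLocalEfficiency:
    def test_unit_triangle_is_one(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert local_efficiency(w) == pytest.approx(1.0)

    def test_star_is_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert local_efficiency(w) == 0.0

    def test_matches_subgraph_extraction_oracle(self):
        """Independent route: extract each neighbour subgraph explicitly and
        evaluate its efficiency by brute-force path enumeration."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            w = random_weighted_graph(rng, 6, density=0.6)
            total = 0.0
            for i in range(6):
                nbrs = np.nonzero(w[i] > 0)[0]
                if len(nbrs) < 2:
                    continue
                sub = w[np.ix_(nbrs, nbrs)]
                Lb = brute_force_shortest_paths(sub)
                inv = 1.0 / Lb[~np.eye(len(nbrs), dtype=bool)]
                inv[~np.isfinite(inv)] = 0.0
                total += inv.sum() / (len(nbrs) * (len(nbrs) - 1))
            assert local_efficiency(w) == pytest.approx(total / 6, abs=1e-10)


class TestNodalEfficiency:
    def test_star_hub_is_one(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert nodal_efficiency(shortest_paths(w), 0) == pytest.approx(1.0)

    def test_isolated_node_is_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        assert nodal_efficiency(shortest_paths(w), 3) == 0.0

    def test_mean_equals_global_efficiency(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            w = random_weighted_graph(rng, 8, density=0.4)
            L = shortest_paths(w)
            assert np.mean(nodal_efficiency(L)) == pytest.approx(
                global_efficiency(L), abs=1e-12)


class TestAsymmetryIndex:
    def test_equal_measures_give_zero(self):
        assert asymmetry_index(0.4, 0.4) == 0.0

    def test_rightward_value(self):
        assert asymmetry_index(0.6, 0.3) == pytest.approx(1.0 / 3.0)

    def test_leftward_boundary(self):
        assert asymmetry_index(0.0, 0.5) == -1.0

    def test_undefined_when_both_zero(self):
        with pytest.warns(UserWarning, match="AI undefined"):
            assert np.isnan(asymmetry_index(0.0, 0.0))

    def test_negative_measure_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(-0.1, 0.5)

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        ai = asymmetry_index(a, b)
        assert -1.0 <= ai <= 1.0
        assert asymmetry_index(b, a) == -ai


class TestMeanNodalAI:
    def test_singleton_subset(self):
        assert mean_nodal_ai([0.1, -0.3, 0.5], [2]) == 0.5

    def test_zero_vector(self):
        assert mean_nodal_ai(np.zeros(10), range(10)) == 0.0

    def test_matches_independent_mean(self, rng):
        v = rng.normal(0, 0.1, 64)
        sub = rng.choice(64, 20, replace=False)
        assert mean_nodal_ai(v, sub) == pytest.approx(sum(v[sub]) / 20)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mean_nodal_ai([0.1], [])


class TestInvariants:
    def test_permutation_invariance(self, rng):
        w = random_weighted_graph(rng, 8, density=0.5)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        g, l, nod = network_metrics(w)
        gp, lp, nodp = network_metrics(wp)
        assert gp == pytest.approx(g, abs=1e-12)
        assert lp == pytest.approx(l, abs=1e-12)
        assert np.allclose(nodp, nod[perm], atol=1e-12)

    def test_raising_a_weight_never_decreases_efficiency(self, rng):
        for _ in range(20):
            w = random_weighted_graph(rng, 7, density=0.4)
            i, j = rng.choice(7, 2, replace=False)
            w2 = w.copy()
            w2[i, j] = w2[j, i] = min(1.0, max(w[i, j], 0.01) + 0.3)
            L1, L2 = shortest_paths(w), shortest_paths(w2)
            assert global_efficiency(L2) >= global_efficiency(L1) - 1e-12
            assert np.all(nodal_efficiency(L2) >= nodal_efficiency(L1) - 1e-12)

    def test_identical_networks_have_zero_ai_everywhere(self, rng):
        w = random_weighted_graph(rng, 10, density=0.5)
        mtab, atab = cohort_metric_tables([("s", w, w.copy())])
        finite = atab["ai"].dropna()
        assert (finite == 0.0).all()

    def test_distance_rule_recorded(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert shortest_paths(w, "neglog").distance_rule == "neglog"


def test_cohort_tables_shapes(rng):
    w1, w2 = (random_weighted_graph(rng, 6, 0.6) for _ in range(2))
    mtab, atab = cohort_metric_tables([("a", w1, w2)])
    assert len(mtab) == 2 * (2 + 6)
    assert len(atab) == 2 + 6
    assert set(mtab["measure"]) == {"e_glob", "e_loc", "e_nodal"}
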