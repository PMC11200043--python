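"""Centrality, predictability and layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepnet import (BinarySymptomTable, IsingModel, centrality_table,
                      expected_influence, fr_layout, global_strength,
                      path_centralities, predictability, sample_ising,
                      standardize, strength)

from conftest import random_model
from _oracles import brute_force_path_centralities


def three_node_model():
    omega = np.array([[0.0, 0.3, -0.2],
                      [0.3, 0.0, 0.0],
                      [-0.2, 0.0, 0.0]])
    return IsingModel(np.zeros(3), omega)


class TestStrengthAndInfluence:
    def test_hand_computed_strengths(self):
        m = three_node_model()
        np.testing.assert_allclose(strength(m), [0.5, 0.3, 0.2])
        assert global_strength(m) == pytest.approx(0.5)

    def test_empty_network_zero(self):
        m = IsingModel(np.zeros(4), np.zeros((4, 4)))
        np.testing.assert_array_equal(strength(m), 0.0)
        assert global_strength(m) == 0.0

    def test_signed_vs_absolute(self):
        m = three_node_model()
        ei = expected_influence(m)
        assert ei[0] == pytest.approx(0.1)  # +0.3 − 0.2
        np.testing.assert_allclose(expected_influence(m)[1:], [0.3, -0.2])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariants_random_models(self, seed):
        m = random_model(10, np.random.default_rng(seed))
        s = strength(m)
        assert np.sum(s) == pytest.approx(2 * global_strength(m))
        assert np.all(np.abs(expected_influence(m)) <= s + 1e-12)

    def test_all_positive_network_ei_equals_strength(self):
        rng = np.random.default_rng(5)
        m = random_model(8, rng)
        pos = IsingModel(m.thresholds, np.abs(m.weights))
        np.testing.assert_allclose(expected_influence(pos), strength(pos))


class TestPathCentralities:
    def test_three_node_chain_hand_computed(self):
        omega = np.zeros((3, 3))
        omega[0, 1] = omega[1, 0] = 0.5
        omega[1, 2] = omega[2, 1] = 0.5
        m = IsingModel(np.zeros(3), omega)  # lengths 2 and 2
        closeness, betweenness = path_centralities(m)
        np.testing.assert_allclose(betweenness, [0.0, 1.0, 0.0])
        assert closeness[1] == pytest.approx(0.25)
        assert closeness[0] == pytest.approx(1.0 / 6.0)

    def test_empty_network_all_zero(self):
        m = IsingModel(np.zeros(5), np.zeros((5, 5)))
        closeness, betweenness = path_centralities(m)
        np.testing.assert_array_equal(closeness, 0.0)
        np.testing.assert_array_equal(betweenness, 0.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 9))
        m = random_model(p, rng, density=0.4)
        closeness, betweenness = path_centralities(m)
        ref_close, ref_between = brute_force_path_centralities(m.weights)
        np.testing.assert_allclose(closeness, ref_close, atol=1e-9)
        np.testing.assert_allclose(betweenness, ref_between, atol=1e-9)

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(77)
        m = random_model(7, rng)
        perm = rng.permutation(7)
        mp = IsingModel(m.thresholds[perm], m.weights[np.ix_(perm, perm)])
        c0, b0 = path_centralities(m)
        c1, b1 = path_centralities(mp)
        np.testing.assert_allclose(c1, c0[perm], atol=1e-12)
        np.testing.assert_allclose(b1, b0[perm], atol=1e-12)
        np.testing.assert_allclose(strength(mp), strength(m)[perm])


class TestStandardize:
    def test_z_scores(self):
        table = centrality_table(three_node_model())
        z = standardize(table)
        assert z["strength"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["strength"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_zeros_with_warning(self):
        m = IsingModel(np.zeros(3), np.zeros((3, 3)))
        table = centrality_table(m)
        with pytest.warns(RuntimeWarning, match="constant"):
            z = standardize(table)
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_ranking_preserved(self):
        table = centrality_table(three_node_model())
        z = standardize(table)
        assert (z["strength"].rank() == table["strength"].rank()).all()


class TestPredictability:
    def test_independent_node_scores_zero(self, independent_p10, fast_config):
        from sleepnet import estimate_ising
        table = sample_ising(independent_p10, 3000, seed=3, method="exact")
        model = estimate_ising(table, fast_config)
        values = predictability(table, model)["predictability"]
        assert values.max() < 0.05

    def test_duplicated_column_near_one(self):
        rng = np.random.default_rng(4)
        x = (rng.random(2000) < 0.4).astype(float)
        other = (rng.random(2000) < 0.5).astype(float)
        values = np.column_stack([x, x, other])
        table = BinarySymptomTable(values, ("a", "a_copy", "b"))
        omega = np.zeros((3, 3))
        omega[0, 1] = omega[1, 0] = 1.0
        model = IsingModel(np.zeros(3), omega)
        vals = predictability(table, model)["predictability"]
        assert vals["a"] > 0.95
        assert vals["a_copy"] > 0.95

    @pytest.mark.parametrize("method", ["r2", "normalized_accuracy"])
    def test_values_in_unit_interval(self, method, sample_p10, planted_p10):
        vals = predictability(sample_p10, planted_p10, method)["predictability"]
        assert ((vals >= 0.0) & (vals <= 1.0)).all()

    def test_dimension_mismatch_raises(self, sample_p10):
        small = IsingModel(np.zeros(3), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="p="):
            predictability(sample_p10, small)


class TestLayout:
    def test_deterministic_given_seed(self):
        m = random_model(8, np.random.default_rng(0))
        np.testing.assert_array_equal(fr_layout(m, seed=5), fr_layout(m, seed=5))

    def test_linked_pair_closer_than_isolate(self):
        omega = np.zeros((3, 3))
        omega[0, 1] = omega[1, 0] = 2.0
        m = IsingModel(np.zeros(3), omega)
        xy = fr_layout(m, seed=1)
        pair = np.linalg.norm(xy[0] - xy[1])
        assert pair < np.linalg.norm(xy[0] - xy[2])
        assert pair < np.linalg.norm(xy[1] - xy[2])

    def test_empty_network_in_unit_box(self):
        m = IsingModel(np.zeros(6), np.zeros((6, 6)))
        xy = fr_layout(m, seed=3)
        assert xy.shape == (6, 2)
        assert (xy >= 0.0).all() and (xy <= 1.0).all()
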