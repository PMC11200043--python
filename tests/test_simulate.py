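"""Synthetic-data generator: exact oracle, samplers, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from sleepnet import (GraphSpec, GroupSpec, IsingModel, Perturbation,
                      ScenarioSpec, exact_distribution, global_strength,
                      make_group_scenario, perturb_model, plant_model,
                      sample_ising)

from conftest import random_model


class TestExactDistribution:
    def test_uniform_when_all_parameters_zero(self):
        d = exact_distribution(IsingModel(np.zeros(3), np.zeros((3, 3))))
        np.testing.assert_allclose(d.probabilities, np.full(8, 1 / 8))

    def test_two_node_positive_edge(self):
        # states (0,0),(1,0),(0,1),(1,1) have weights 1,1,1,e
        d = exact_distribution(IsingModel([0, 0], [[0, 1], [1, 0]]))
        e = np.e
        np.testing.assert_allclose(sorted(d.probabilities),
                                   sorted(np.array([1, 1, 1, e]) / (3 + e)))
        both = d.states.sum(axis=1) == 2
        np.testing.assert_allclose(d.probabilities[both], e / (3 + e))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 1000), st.integers(2, 7))
    def test_normalizes_and_moment_consistency(self, seed, p):
        model = random_model(p, np.random.default_rng(seed))
        d = exact_distribution(model)
        assert abs(d.probabilities.sum() - 1.0) < 1e-12
        # pairwise diagonal equals marginals; E[x_i x_j] <= min marginal
        np.testing.assert_allclose(np.diag(d.pairwise), d.marginals)
        for i in range(p):
            for j in range(p):
                assert d.pairwise[i, j] <= min(d.marginals[i],
                                               d.marginals[j]) + 1e-12

    def test_refuses_large_p(self):
        with pytest.raises(ValueError, match="p <= 12"):
            exact_distribution(IsingModel(np.zeros(13), np.zeros((13, 13))))

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 1000))
    def test_zero_one_relabel_threshold_flip_symmetry(self, seed):
        """Flipping x -> 1-x maps (τ, Ω) to (−τ − Ω·1, Ω) with the same law."""
        model = random_model(5, np.random.default_rng(seed))
        flipped = IsingModel(-model.thresholds - model.weights.sum(axis=1),
                             model.weights)
        d = exact_distribution(model)
        df = exact_distribution(flipped)
        np.testing.assert_allclose(d.marginals, 1.0 - df.marginals,
                                   atol=1e-10)


class TestPlantModel:
    def test_zero_density_half_prevalence_gives_zero_model(self):
        m = plant_model(GraphSpec(density=0.0), [0.5] * 4, seed=0)
        np.testing.assert_allclose(m.thresholds, 0.0, atol=1e-12)
        np.testing.assert_array_equal(m.weights, 0.0)

    def test_zero_density_closed_form_threshold(self):
        m = plant_model(GraphSpec(density=0.0), [0.25, 0.5, 0.5], seed=0)
        np.testing.assert_allclose(m.thresholds[0], logit(0.25), atol=1e-9)

    def test_calibration_hits_targets_exactly_evaluated(self):
        m = plant_model(GraphSpec(density=0.25), [0.3] * 8, seed=11)
        marg = exact_distribution(m).marginals
        assert np.abs(marg - 0.3).max() < 0.02

    def test_infeasible_raises_with_worst_node(self):
        with pytest.raises(RuntimeError, match="worst node"):
            plant_model(GraphSpec(density=0.0), [0.3] * 4, seed=0,
                        max_iterations=0)


class TestSampleIsing:
    def test_independent_marginals(self):
        m = IsingModel(np.zeros(2), np.zeros((2, 2)))
        t = sample_ising(m, 10_000, seed=1, method="exact")
        se = 0.5 / np.sqrt(10_000)
        assert np.abs(t.values.mean(axis=0) - 0.5).max() < 3 * se

    def test_same_seed_identical(self):
        m = random_model(6, np.random.default_rng(3))
        a = sample_ising(m, 200, seed=9, method="gibbs")
        b = sample_ising(m, 200, seed=9, method="gibbs")
        np.testing.assert_array_equal(a.values, b.values)

    def test_gibbs_matches_exact_moments(self, planted_p10):
        """Gibbs univariate/pairwise moments within 4·SE of enumeration."""
        d = exact_distribution(planted_p10)
        n = 20_000
        t = sample_ising(planted_p10, n, seed=5, method="gibbs")
        emp_pair = t.values.T @ t.values / n
        se = np.sqrt(d.pairwise * (1 - d.pairwise) / n)
        # thinning leaves mild autocorrelation; 4·SE with a small floor
        assert np.abs(emp_pair - d.pairwise).max() < np.maximum(
            4 * se, 0.004).max()

    def test_invalid_inputs(self, planted_p10):
        with pytest.raises(ValueError, match="n >= 1"):
            sample_ising(planted_p10, 0, seed=0)
        with pytest.raises(ValueError, match="method"):
            sample_ising(planted_p10, 5, seed=0, method="metropolis")


class TestGroupScenario:
    @staticmethod
    def _spec(**kw):
        defaults = dict(
            p=8,
            graph_spec=GraphSpec(density=0.25),
            prevalence_targets=(0.3,) * 8,
            groups=(GroupSpec("a", 300), GroupSpec("b", 200)),
            seed=4,
            sampler="exact",
        )
        defaults.update(kw)
        return ScenarioSpec(**defaults)

    def test_identical_truths_without_perturbation(self):
        _, truths = make_group_scenario(self._spec())
        np.testing.assert_array_equal(truths[0].weights, truths[1].weights)

    def test_global_scale_perturbation_scales_global_strength(self):
        spec = self._spec(groups=(
            GroupSpec("a", 100),
            GroupSpec("b", 100, Perturbation(scale=1.2))))
        _, truths = make_group_scenario(spec)
        assert global_strength(truths[1]) == pytest.approx(
            1.2 * global_strength(truths[0]))

    def test_table_shape_and_group_factor(self):
        spec = self._spec(groups=(GroupSpec("a", 2000), GroupSpec("b", 900)))
        table, _ = make_group_scenario(spec)
        assert table.n == 2900
        assert table.group_levels("group") == ("a", "b")
        assert (table.group_labels["group"] == "a").sum() == 2000

    def test_perturbing_missing_edge_raises(self):
        m = plant_model(GraphSpec(density=0.0), [0.4, 0.4, 0.4], seed=0)
        with pytest.raises(ValueError, match="nonexistent edge"):
            perturb_model(m, Perturbation(scale=2.0, edge_subset=((0, 1),)))
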