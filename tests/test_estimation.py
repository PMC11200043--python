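"""Nodewise eLasso estimation: EBIC, path behavior, recovery, symmetrization."""

import numpy as np
import pytest
from scipy.special import logit

from sleepnet import (BinarySymptomTable, EstimationConfig, IsingModel, ebic,
                      estimate_ising, fit_node_lasso, sample_ising)
from sleepnet.estimation import _symmetrize, make_lambda_path


def ebic_reference(loglik, k, n, p_cand, gamma):
    """Independently coded criterion for cross-checking."""
    import math
    return -2 * loglik + k * math.log(n) + 2 * gamma * k * math.log(p_cand)


class TestEbic:
    def test_penalty_vanishes_at_k_zero(self):
        assert ebic(-100.0, 0, 1000, 38, 0.25) == 200.0

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5, 1.0])
    @pytest.mark.parametrize("k,n,p_cand", [(2, 1000, 38), (5, 200, 9),
                                            (1, 50_000, 38)])
    def test_matches_reference_formula(self, gamma, k, n, p_cand):
        ours = ebic(-100.0, k, n, p_cand, gamma)
        assert ours == pytest.approx(
            ebic_reference(-100.0, k, n, p_cand, gamma), abs=1e-9)

    def test_gamma_zero_is_bic(self):
        assert ebic(-50.0, 3, 500, 20, 0.0) == pytest.approx(
            100.0 + 3 * np.log(500), abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ebic(-1.0, -1, 10, 5, 0.25)
        with pytest.raises(ValueError):
            ebic(-1.0, 0, 0, 5, 0.25)


class TestNodewisePath:
    def test_full_shrinkage_limit(self, sample_p10, fast_config):
        """At very large λ all neighbor coefficients are exactly zero and the
        intercept equals the logit of the node prevalence."""
        lams = np.array([10.0, 5.0])
        fit = fit_node_lasso(sample_p10, 0, lambda_path=lams,
                             config=fast_config)
        np.testing.assert_array_equal(fit.coefficient_path, 0.0)
        prev = sample_p10.values[:, 0].mean()
        assert fit.intercept_path[0] == pytest.approx(logit(prev), abs=1e-5)

    def test_support_monotone_along_path(self, sample_p10, fast_config):
        fit = fit_node_lasso(sample_p10, 3, config=fast_config)
        supports = [frozenset(np.flatnonzero(c)) for c in
                    fit.coefficient_path]
        for larger_lam, smaller_lam in zip(supports, supports[1:]):
            assert larger_lam <= smaller_lam

    def test_selected_index_minimizes_ebic(self, sample_p10, fast_config):
        fit = fit_node_lasso(sample_p10, 5, config=fast_config)
        assert fit.selected_index == int(np.argmin(fit.ebic_values))
        assert np.all(np.isfinite(fit.ebic_values))
        assert np.all(np.diff(fit.lambda_path) < 0)

    def test_two_node_positive_edge_recovered_with_sign(self):
        model = IsingModel([logit(0.4), logit(0.4)], [[0, 0.8], [0.8, 0]])
        table = sample_ising(model, 5000, seed=2, method="exact")
        fit = fit_node_lasso(table, 0)
        assert fit.selected_coefficients[0] > 0.2

    def test_nonconvergence_is_flagged(self, sample_p10):
        starved = EstimationConfig(lambda_count=5, max_iterations=1,
                                   convergence_tolerance=1e-12)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit_node_lasso(sample_p10, 0, config=starved)

    def test_constant_column_rejected(self, fast_config):
        values = np.array([[1, 0], [1, 1], [1, 0], [1, 1]])
        t = BinarySymptomTable(values, ("const", "b"))
        with pytest.raises(ValueError, match="constant"):
            fit_node_lasso(t, 0, config=fast_config)

    def test_agrees_with_saga_reference(self, sample_p10):
        """Dual-route check: our coordinate descent against scikit-learn's
        saga solver on the same penalized objective."""
        from sklearn.linear_model import LogisticRegression
        y = sample_p10.values[:, 0]
        X = np.delete(sample_p10.values, 0, axis=1)
        n = len(y)
        lams = make_lambda_path(X, y, EstimationConfig(lambda_count=12))
        fit = fit_node_lasso(sample_p10, 0, lambda_path=lams)
        for k in (3, 7, 11):
            ref = LogisticRegression(C=1.0 / (n * lams[k]), penalty="l1",
                                     l1_ratio=1.0, solver="saga", tol=1e-10,
                                     max_iter=50_000).fit(X, y)
            np.testing.assert_allclose(fit.coefficient_path[k], ref.coef_[0],
                                       atol=2e-5)


class TestEstimateIsing:
    def test_weights_symmetric_zero_diagonal(self, sample_p10, fast_config):
        m = estimate_ising(sample_p10, fast_config)
        np.testing.assert_array_equal(m.weights, m.weights.T)
        np.testing.assert_array_equal(np.diag(m.weights), 0.0)

    def test_empty_network_under_independence(self, independent_p10,
                                              fast_config):
        table = sample_ising(independent_p10, 5000, seed=42, method="exact")
        m = estimate_ising(table, fast_config)
        assert m.n_edges == 0

    def test_prevalence_band_guard(self, fast_config):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 2, size=(400, 3)).astype(float)
        values[:, 1] = 0.0
        values[0, 1] = 1.0  # prevalence 1/400 < 0.005
        t = BinarySymptomTable(values, ("a", "rare", "c"))
        with pytest.raises(ValueError, match="rare"):
            estimate_ising(t, fast_config)

    def test_and_or_symmetrization_rules(self):
        directed = np.array([[0.0, 0.4, 0.0],
                             [0.2, 0.0, 0.6],
                             [0.0, 0.0, 0.0]])
        and_w = _symmetrize(directed, "AND")
        or_w = _symmetrize(directed, "OR")
        assert and_w[0, 1] == pytest.approx(0.3)   # both directions present
        assert and_w[1, 2] == 0.0                  # one direction missing
        assert or_w[1, 2] == pytest.approx(0.3)    # absent treated as zero
        np.testing.assert_array_equal(and_w, and_w.T)
        np.testing.assert_array_equal(or_w, or_w.T)

    def test_39_nodes_741_potential_pairs(self):
        m = IsingModel(np.zeros(39), np.zeros((39, 39)))
        assert m.n_potential_edges == 741

    def test_recovery_f1_nondecreasing_in_n(self, planted_p10, fast_config):
        """More data never hurts edge recovery on a fixed sparse truth."""
        iu = np.triu_indices(10, 1)
        true_edges = planted_p10.weights[iu] != 0
        f1s = []
        for n in (500, 2000, 10_000):
            table = sample_ising(planted_p10, n, seed=31, method="exact")
            est = estimate_ising(table, fast_config).weights[iu] != 0
            tp = (true_edges & est).sum()
            fp = (~true_edges & est).sum()
            fn = (true_edges & ~est).sum()
            f1s.append(2 * tp / (2 * tp + fp + fn))
        assert f1s[0] <= f1s[1] + 1e-12 <= f1s[2] + 1e-12
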