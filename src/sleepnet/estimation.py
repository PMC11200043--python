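"""Sparse Ising network estimation from binary data (the eLasso approach).

Each node is regressed on all remaining nodes by L1-penalized logistic
regression (pseudo-likelihood: logit P(x_i = 1 | x_−i) = τ_i + Σ_j ω_ij x_j),
the penalty is selected per node by the extended Bayesian information
criterion, and the two directed coefficient sets are symmetrized into one
undirected weight matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._solver import lambda_max, logistic_lasso_path
from .datatypes import BinarySymptomTable, EstimationConfig, IsingModel

__all__ = ["NodewiseFit", "fit_node_lasso", "ebic", "estimate_ising",
           "make_lambda_path", "prevalence_violations"]


@dataclass(frozen=True)
class NodewiseFit:
    """One node's penalized logistic path with EBIC model selection."""

    node_index: int
    lambda_path: np.ndarray          # strictly decreasing
    intercept_path: np.ndarray       # per-λ unpenalized intercept
    coefficient_path: np.ndarray     # (L, p-1) neighbor coefficients
    loglik_path: np.ndarray          # per-λ conditional log-likelihood
    ebic_values: np.ndarray
    selected_index: int

    @property
    def selected_intercept(self) -> float:
        return float(self.intercept_path[self.selected_index])

    @property
    def selected_coefficients(self) -> np.ndarray:
        return self.coefficient_path[self.selected_index]


def ebic(loglik: float, k_nonzero: int, n: int, p_candidates: int,
         gamma: float) -> float:
    """Extended BIC: −2ℓ + k·log n + 2γ·k·log(p_candidates).

    ``p_candidates`` is the number of candidate predictors (p − 1 in the
    nodewise regressions). ``gamma = 0`` reduces to the ordinary BIC.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if k_nonzero < 0:
        raise ValueError("need k_nonzero >= 0")
    if gamma < 0:
        raise ValueError("need gamma >= 0")
    return (-2.0 * loglik + k_nonzero * np.log(n)
            + 2.0 * gamma * k_nonzero * np.log(p_candidates))


def make_lambda_path(X: np.ndarray, y: np.ndarray,
                     config: EstimationConfig) -> np.ndarray:
    """Log-spaced decreasing path from just above λ_max down to
    λ_max·lambda_min_ratio.

    The first grid point sits a hair above λ_max so that it yields the exact
    empty model (all neighbor coefficients zero) despite floating-point
    rounding — EBIC selection must always be able to fall back to k = 0.
    """
    lmax = lambda_max(X, y)
    if lmax <= 0.0:
        lmax = 1e-3  # response uncorrelated with every predictor
    return np.geomspace(lmax * 1.001, lmax * config.lambda_min_ratio,
                        config.lambda_count)


def prevalence_violations(table: BinarySymptomTable,
                          config: EstimationConfig) -> list[str]:
    """Names of columns whose prevalence falls outside the admissible band.

    Nodewise pseudo-likelihood is ill-conditioned for (near-)constant
    columns, so prevalences outside [min_prevalence, 1 − min_prevalence] are
    rejected rather than silently estimated.
    """
    prev = table.values.mean(axis=0)
    lo = config.min_prevalence
    bad = (prev < lo) | (prev > 1.0 - lo)
    return [table.variable_names[i] for i in np.flatnonzero(bad)]


def _ebic_path(logliks: np.ndarray, coefs: np.ndarray, n: int,
               p_candidates: int, gamma: float) -> np.ndarray:
    k = np.count_nonzero(coefs, axis=1)
    return (-2.0 * logliks + k * np.log(n)
            + 2.0 * gamma * k * np.log(p_candidates))


def _estimate_raw(values: np.ndarray,
                  config: EstimationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Nodewise eLasso on a bare (n, p) 0/1 array; no validation.

    Internal fast path for permutation and bootstrap loops, which re-estimate
    thousands of networks; :func:`estimate_ising` is the validated public
    entry point. Returns (thresholds, weights).
    """
    n, p = values.shape
    directed = np.zeros((p, p))
    thresholds = np.zeros(p)
    cols = np.arange(p)
    for i in range(p):
        y = np.ascontiguousarray(values[:, i])
        X = np.ascontiguousarray(np.delete(values, i, axis=1))
        lams = make_lambda_path(X, y, config)
        intercepts, coefs, logliks, iters = logistic_lasso_path(
            X, y, lams, config.convergence_tolerance, config.max_iterations)
        if iters.max() >= config.max_iterations:
            warnings.warn(f"nodewise fit for node {i} did not converge to "
                          f"tolerance {config.convergence_tolerance} within "
                          f"{config.max_iterations} iterations", RuntimeWarning)
        sel = int(np.argmin(_ebic_path(logliks, coefs, n, p - 1,
                                       config.ebic_gamma)))
        directed[i, np.delete(cols, i)] = coefs[sel]
        thresholds[i] = intercepts[sel]
    return thresholds, _symmetrize(directed, config.symmetrization_rule)


def fit_node_lasso(table: BinarySymptomTable, node: int,
                   lambda_path: np.ndarray | None = None,
                   config: EstimationConfig = EstimationConfig()) -> NodewiseFit:
    """L1-penalized logistic path of one node on all other columns.

    The intercept is unpenalized; solutions are warm-started along the
    decreasing λ path; the selected model minimizes the EBIC.
    """
    p = table.p
    if not 0 <= node < p:
        raise IndexError(f"node {node} out of range for p={p}")
    y = np.ascontiguousarray(table.values[:, node])
    if y.min() == y.max():
        raise ValueError(
            f"column {table.variable_names[node]!r} is constant; exclude it "
            "before estimation")
    X = np.ascontiguousarray(np.delete(table.values, node, axis=1))
    if lambda_path is None:
        lambda_path = make_lambda_path(X, y, config)
    lambda_path = np.asarray(lambda_path, dtype=np.float64)
    if lambda_path.ndim != 1 or np.any(np.diff(lambda_path) >= 0):
        raise ValueError("lambda_path must be strictly decreasing")
    intercepts, coefs, logliks, iters = logistic_lasso_path(
        X, y, lambda_path, config.convergence_tolerance, config.max_iterations)
    if not np.all(np.isfinite(logliks)):
        warnings.warn(f"nodewise fit for node {node} produced non-finite "
                      "log-likelihoods; solution flagged", RuntimeWarning)
    if iters.max() >= config.max_iterations:
        warnings.warn(f"nodewise fit for node {node} did not converge to "
                      f"tolerance {config.convergence_tolerance} within "
                      f"{config.max_iterations} iterations", RuntimeWarning)
    ebics = _ebic_path(logliks, coefs, table.n, p - 1, config.ebic_gamma)
    selected = int(np.argmin(ebics))
    return NodewiseFit(node, lambda_path, intercepts, coefs, logliks, ebics,
                       selected)


def _symmetrize(directed: np.ndarray, rule: str) -> np.ndarray:
    """Combine the p×p directed coefficient matrix into symmetric weights."""
    both = (directed != 0.0) & (directed.T != 0.0)
    either = (directed != 0.0) | (directed.T != 0.0)
    mean = (directed + directed.T) / 2.0
    if rule == "AND":
        omega = np.where(both, mean, 0.0)
    else:  # OR: mean treating the absent direction as 0
        omega = np.where(either, mean, 0.0)
    np.fill_diagonal(omega, 0.0)
    return omega


def estimate_ising(table: BinarySymptomTable,
                   config: EstimationConfig = EstimationConfig()) -> IsingModel:
    """Estimate the full Ising network: nodewise eLasso then symmetrization.

    Raises if any column's prevalence leaves the admissible band (the
    per-node error message names the offending columns).
    """
    bad = prevalence_violations(table, config)
    if bad:
        raise ValueError(
            "columns with prevalence outside "
            f"[{config.min_prevalence}, {1 - config.min_prevalence}]: {bad}; "
            "exclude or merge them before estimation")
    thresholds, omega = _estimate_raw(table.values, config)
    return IsingModel(thresholds, omega)
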