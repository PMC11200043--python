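"""Bootstrap robustness of estimated networks.

Two resampling schemes: a nonparametric bootstrap of edge weights (rows
resampled with replacement, network re-estimated per draw, percentile
intervals per edge) and a case-dropping subset bootstrap for centrality
stability, summarized by the correlation-stability (CS) coefficient — the
largest proportion of respondents that can be dropped while, with 95%
probability, the correlation between subset-sample and full-sample node
strengths stays at or above 0.70. A CS coefficient of at least 0.25 is the
conventional minimum for interpreting centrality orderings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr, pearsonr

from .datatypes import BinarySymptomTable, EstimationConfig
from .estimation import _estimate_raw, estimate_ising
from .metrics import strength

logger = logging.getLogger(__name__)

__all__ = ["EdgeBootstrapResult", "StabilityResult", "edge_bootstrap",
           "case_dropping_bootstrap", "cs_coefficient"]

DEFAULT_DROP_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass(frozen=True)
class EdgeBootstrapResult:
    """Per-edge nonparametric bootstrap summary."""

    full_weights: np.ndarray      # (p, p) full-sample estimate
    boot_mean: np.ndarray         # (p, p)
    lower: np.ndarray             # (p, p) percentile lower bound
    upper: np.ndarray             # (p, p) percentile upper bound
    level: float
    n_boot: int
    seed: int
    n_redrawn: int = 0

    def interval(self, i: int, j: int) -> tuple[float, float]:
        return float(self.lower[i, j]), float(self.upper[i, j])


@dataclass(frozen=True)
class StabilityResult:
    """Case-dropping bootstrap curves and the CS coefficient."""

    drop_proportions: tuple[float, ...]
    correlations: dict[float, np.ndarray]   # per proportion, n_boot draws
    cs_coefficient: float
    cor_threshold: float
    prob_threshold: float
    n_boot: int
    seed: int
    full_strength: np.ndarray
    correlation_type: str = "spearman"
    skipped_proportions: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "drop_proportions": list(self.drop_proportions),
            "correlations": {str(q): v.tolist()
                             for q, v in self.correlations.items()},
            "cs_coefficient": self.cs_coefficient,
            "cor_threshold": self.cor_threshold,
            "prob_threshold": self.prob_threshold,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "correlation_type": self.correlation_type,
            "skipped_proportions": list(self.skipped_proportions),
        }


def edge_bootstrap(table: BinarySymptomTable,
                   config: EstimationConfig = EstimationConfig(),
                   n_boot: int = 2000, seed: int = 0,
                   level: float = 0.95) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of the edge weights.

    Rows are resampled with replacement and the network re-estimated per
    draw; per-edge percentile intervals (default 2.5/97.5) and the bootstrap
    mean are reported alongside the full-sample estimate. Draws in which a
    column leaves the admissible prevalence band are redrawn (counted).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for percentile intervals")
    full = estimate_ising(table, config)
    rng = np.random.default_rng(seed)
    p = table.p
    draws = np.empty((n_boot, p, p))
    n_redrawn = 0
    b = 0
    lo = config.min_prevalence
    while b < n_boot:
        idx = rng.integers(0, table.n, size=table.n)
        vals = table.values[idx]
        prev = vals.mean(axis=0)
        if np.any(prev < lo) or np.any(prev > 1.0 - lo):
            n_redrawn += 1
            if n_redrawn > 50 * n_boot:
                raise RuntimeError("too many bootstrap draws violated the "
                                   "prevalence band")
            continue
        draws[b] = _estimate_raw(vals, config)[1]
        b += 1
    if n_redrawn:
        logger.info("edge bootstrap: %d draws redrawn for prevalence "
                    "violations", n_redrawn)
    tail = (1.0 - level) / 2.0
    return EdgeBootstrapResult(
        full_weights=full.weights,
        boot_mean=draws.mean(axis=0),
        lower=np.quantile(draws, tail, axis=0),
        upper=np.quantile(draws, 1.0 - tail, axis=0),
        level=level,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def _stability_correlation(sub: np.ndarray, full: np.ndarray,
                           kind: str) -> float:
    """Correlation between subset and full-sample strengths.

    Exactly identical vectors score 1 (covers degenerate perfectly stable
    estimation, including empty networks); otherwise a constant vector on
    either side carries no ordering information and scores 0.
    """
    if np.array_equal(sub, full):
        return 1.0
    if np.ptp(sub) == 0.0 or np.ptp(full) == 0.0:
        return 0.0
    if kind == "spearman":
        return float(spearmanr(sub, full).statistic)
    return float(pearsonr(sub, full).statistic)


def case_dropping_bootstrap(table: BinarySymptomTable,
                            config: EstimationConfig = EstimationConfig(),
                            drop_proportions: tuple[float, ...] = DEFAULT_DROP_GRID,
                            n_boot: int = 2000, seed: int = 0,
                            cor_threshold: float = 0.70,
                            prob_threshold: float = 0.95,
                            correlation_type: str = "spearman",
                            min_subset: int = 50) -> StabilityResult:
    """Case-dropping subset bootstrap of node strength.

    For each drop proportion q, draws ``n_boot`` subsets of
    ``round((1 − q)·n)`` rows without replacement, re-estimates the network
    and correlates (Spearman by default) the subset strengths with the
    full-sample strengths. Proportions whose retained subsets would fall
    below ``min_subset`` rows are skipped with a warning.
    """
    if correlation_type not in ("spearman", "pearson"):
        raise ValueError("correlation_type must be 'spearman' or 'pearson'")
    grid = tuple(sorted(float(q) for q in drop_proportions))
    if not grid or not all(0.0 < q < 1.0 for q in grid):
        raise ValueError("drop proportions must lie strictly inside (0, 1)")
    full = estimate_ising(table, config)
    full_strength = strength(full)
    rng = np.random.default_rng(seed)
    correlations: dict[float, np.ndarray] = {}
    kept_grid: list[float] = []
    skipped: list[float] = []
    for q in grid:
        m = int(round((1.0 - q) * table.n))
        if m < min_subset:
            logger.warning("drop proportion %.2f skipped: retained subset "
                           "of %d rows is below the minimum of %d", q, m,
                           min_subset)
            skipped.append(q)
            continue
        lo = config.min_prevalence
        cors = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(table.n, size=m, replace=False)
            vals = table.values[idx]
            prev = vals.mean(axis=0)
            if np.any(prev < lo) or np.any(prev > 1.0 - lo):
                cors[b] = 0.0
                continue
            sub_strength = np.abs(_estimate_raw(vals, config)[1]).sum(axis=1)
            cors[b] = _stability_correlation(sub_strength, full_strength,
                                             correlation_type)
        correlations[q] = cors
        kept_grid.append(q)
    if not correlations:
        raise ValueError("no drop proportion left a subset of admissible size")
    cs = _cs_from_curves(tuple(kept_grid), correlations, cor_threshold,
                         prob_threshold)
    return StabilityResult(
        drop_proportions=tuple(kept_grid),
        correlations=correlations,
        cs_coefficient=cs,
        cor_threshold=cor_threshold,
        prob_threshold=prob_threshold,
        n_boot=n_boot,
        seed=seed,
        full_strength=full_strength,
        correlation_type=correlation_type,
        skipped_proportions=tuple(skipped),
    )


def _cs_from_curves(grid: tuple[float, ...],
                    correlations: dict[float, np.ndarray],
                    cor_threshold: float, prob_threshold: float) -> float:
    cs = 0.0
    for q in grid:  # ascending; contiguity from the smallest proportion
        draws = correlations[q]
        if draws.size == 0:
            raise ValueError(f"no bootstrap draws at drop proportion {q}")
        frac = np.mean(draws >= cor_threshold)
        if frac >= prob_threshold:
            cs = q
        else:
            break
    return cs


def cs_coefficient(result: StabilityResult, cor_threshold: float = 0.70,
                   prob_threshold: float = 0.95) -> float:
    """Largest drop proportion q such that, for every q' ≤ q in the grid,
    the fraction of draws with correlation ≥ ``cor_threshold`` is at least
    ``prob_threshold``; 0 if the smallest proportion already fails."""
    if not result.drop_proportions:
        raise ValueError("StabilityResult contains no drop proportions")
    return _cs_from_curves(result.drop_proportions, result.correlations,
                           cor_threshold, prob_threshold)
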