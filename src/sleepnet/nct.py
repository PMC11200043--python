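"""Permutation-based two-network comparison (NCT).

Two groups' networks are compared via (1) the structure statistic M — the
maximum absolute edge-weight difference — and (2) the global-strength
statistic S — the absolute difference of the two networks' global strengths.
The null distribution is built by pooling respondents, randomly reassigning
group labels (preserving group sizes) and re-estimating both networks per
permutation; the same draws give local per-edge and per-node-strength
p-values. Unequal group sizes are handled by repeatedly subsampling the
larger group to the smaller size and averaging the results, without
multiple-testing adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BinarySymptomTable, EstimationConfig, IsingModel
from .estimation import _estimate_raw, estimate_ising
from .metrics import global_strength, strength

__all__ = ["NCTResult", "nct", "balanced_subsample_nct",
           "local_correlation_report"]

_MIN_PERMUTATIONS = 20


@dataclass(frozen=True)
class NCTResult:
    """Observed statistics, permutation p-values and local tests."""

    m_statistic: float
    p_m: float
    s_statistic: float
    p_s: float
    global_strengths: tuple[float, float]
    edge_p: np.ndarray            # (p, p) symmetric local edge p-values
    strength_p: np.ndarray        # (p,) local node-strength p-values
    n_permutations: int
    seed: int
    network_a: IsingModel
    network_b: IsingModel
    labels: tuple[str, str] = ("A", "B")
    subsample_repeats: int = 1
    per_repeat: tuple["NCTResult", ...] = ()
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        for name, val in (("p_m", self.p_m), ("p_s", self.p_s)):
            if not 0.0 < val <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {val}")
        if self.m_statistic < 0 or self.s_statistic < 0:
            raise ValueError("M and S statistics are nonnegative by definition")

    def to_dict(self) -> dict:
        """JSON-serializable summary (matrices as nested lists)."""
        return {
            "labels": list(self.labels),
            "m_statistic": self.m_statistic,
            "p_m": self.p_m,
            "s_statistic": self.s_statistic,
            "p_s": self.p_s,
            "global_strengths": list(self.global_strengths),
            "edge_p": self.edge_p.tolist(),
            "strength_p": self.strength_p.tolist(),
            "n_permutations": self.n_permutations,
            "subsample_repeats": self.subsample_repeats,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
        }


def _check_compatible(xa: BinarySymptomTable, xb: BinarySymptomTable) -> None:
    if xa.variable_names != xb.variable_names:
        raise ValueError("the two tables must share the same variables in "
                         "the same order")


def _in_band(values: np.ndarray, config: EstimationConfig) -> bool:
    prev = values.mean(axis=0)
    lo = config.min_prevalence
    return bool(np.all(prev >= lo) and np.all(prev <= 1.0 - lo))


def nct(xa: BinarySymptomTable, xb: BinarySymptomTable,
        config: EstimationConfig = EstimationConfig(), seed: int = 0,
        n_permutations: int = 2000,
        labels: tuple[str, str] = ("A", "B")) -> NCTResult:
    """Two-tailed permutation test comparing the networks of two groups.

    p-values use the add-one estimator (1 + #{perm ≥ observed}) /
    (1 + n_permutations), so they are never exactly zero. Pooled rows are
    put in a canonical (lexicographic) order before drawing permutations,
    making the p-values invariant to input row order for a given seed.
    Permuted splits in which a column leaves the admissible prevalence band
    are redrawn (and counted).
    """
    _check_compatible(xa, xb)
    if n_permutations < _MIN_PERMUTATIONS:
        raise ValueError(
            f"n_permutations must be >= {_MIN_PERMUTATIONS}: fewer "
            "permutations cannot resolve meaningful p-values")

    net_a = estimate_ising(xa, config)
    net_b = estimate_ising(xb, config)
    obs_edge_diff = np.abs(net_a.weights - net_b.weights)
    m_obs = float(obs_edge_diff.max())
    gs_a, gs_b = global_strength(net_a), global_strength(net_b)
    s_obs = abs(gs_a - gs_b)
    obs_strength_diff = np.abs(strength(net_a) - strength(net_b))

    n_a, n_b = xa.n, xb.n
    pooled = BinarySymptomTable(
        np.vstack([xa.values, xb.values]), xa.variable_names, xa.block_labels)
    order = pooled.canonical_row_order()
    pooled_values = pooled.values[order]

    rng = np.random.default_rng(seed)
    n = n_a + n_b
    p = xa.p
    count_m = 0
    count_s = 0
    count_edge = np.zeros((p, p), dtype=np.int64)
    count_strength = np.zeros(p, dtype=np.int64)
    n_redrawn = 0
    b = 0
    while b < n_permutations:
        perm = rng.permutation(n)
        va = pooled_values[perm[:n_a]]
        vb = pooled_values[perm[n_a:]]
        if not (_in_band(va, config) and _in_band(vb, config)):
            n_redrawn += 1
            if n_redrawn > 50 * n_permutations:
                raise RuntimeError("too many permuted splits violated the "
                                   "prevalence band; data too sparse for NCT")
            continue
        _, wa = _estimate_raw(va, config)
        _, wb = _estimate_raw(vb, config)
        diff = np.abs(wa - wb)
        if diff.max() >= m_obs:
            count_m += 1
        if abs(np.abs(wa).sum() - np.abs(wb).sum()) / 2.0 >= s_obs:
            count_s += 1
        count_edge += diff >= obs_edge_diff
        count_strength += (np.abs(np.abs(wa).sum(axis=1)
                                  - np.abs(wb).sum(axis=1))
                           >= obs_strength_diff)
        b += 1

    denom = 1.0 + n_permutations
    return NCTResult(
        m_statistic=m_obs,
        p_m=(1.0 + count_m) / denom,
        s_statistic=s_obs,
        p_s=(1.0 + count_s) / denom,
        global_strengths=(gs_a, gs_b),
        edge_p=(1.0 + count_edge) / denom,
        strength_p=(1.0 + count_strength) / denom,
        n_permutations=n_permutations,
        seed=seed,
        network_a=net_a,
        network_b=net_b,
        labels=labels,
        n_redrawn=n_redrawn,
    )


def balanced_subsample_nct(xa: BinarySymptomTable, xb: BinarySymptomTable,
                           repeats: int = 5,
                           config: EstimationConfig = EstimationConfig(),
                           seed: int = 0, n_permutations: int = 2000,
                           labels: tuple[str, str] = ("A", "B"),
                           average: str = "mean") -> NCTResult:
    """NCT for unequal groups: subsample the larger group down, average.

    The larger group is subsampled without replacement to the smaller size,
    independently per repeat; a full NCT runs per repeat; reported p-values
    and statistics are the arithmetic means (medians with
    ``average='median'``) across repeats, with the per-repeat results kept.
    Equal group sizes delegate to a single plain :func:`nct`.
    """
    _check_compatible(xa, xb)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if average not in ("mean", "median"):
        raise ValueError("average must be 'mean' or 'median'")
    if xa.n == xb.n:
        return nct(xa, xb, config, seed, n_permutations, labels)

    a_larger = xa.n > xb.n
    big, small = (xa, xb) if a_larger else (xb, xa)
    ss = np.random.SeedSequence([int(seed), 0xA5])
    results = []
    for r, child in enumerate(ss.spawn(repeats)):
        states = child.generate_state(2)
        sub_rng = np.random.default_rng(int(states[0]))
        idx = sub_rng.choice(big.n, size=small.n, replace=False)
        big_sub = big.subset_rows(np.sort(idx))
        pair = (big_sub, small) if a_larger else (small, big_sub)
        results.append(nct(pair[0], pair[1], config,
                           int(states[1] % (2 ** 31)), n_permutations, labels))

    agg = np.mean if average == "mean" else np.median
    full_a = estimate_ising(xa, config)
    full_b = estimate_ising(xb, config)
    return NCTResult(
        m_statistic=float(agg([r.m_statistic for r in results])),
        p_m=float(agg([r.p_m for r in results])),
        s_statistic=float(agg([r.s_statistic for r in results])),
        p_s=float(agg([r.p_s for r in results])),
        global_strengths=(
            float(agg([r.global_strengths[0] for r in results])),
            float(agg([r.global_strengths[1] for r in results])),
        ),
        edge_p=agg([r.edge_p for r in results], axis=0),
        strength_p=agg([r.strength_p for r in results], axis=0),
        n_permutations=n_permutations,
        seed=seed,
        network_a=full_a,
        network_b=full_b,
        labels=labels,
        subsample_repeats=repeats,
        per_repeat=tuple(results),
        n_redrawn=sum(r.n_redrawn for r in results),
    )


def local_correlation_report(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                             nct_result: NCTResult, alpha: float = 0.05,
                             sort_by: str | None = None) -> pd.DataFrame:
    """Symptom-by-symptom comparison table: node strengths and all edges.

    One row per node (strengths in both networks, difference, local
    permutation p) and one per unordered node pair (edge weights likewise);
    significance flags at ``alpha`` are unadjusted for multiplicity.
    """
    if list(metrics_a.index) != list(metrics_b.index):
        raise ValueError("the two metric tables must list the same nodes in "
                         "the same order")
    names = list(metrics_a.index)
    p = len(names)
    if p != nct_result.network_a.p:
        raise ValueError("metric tables and NCT result disagree on node count")

    rows = []
    sa = metrics_a["strength"].to_numpy()
    sb = metrics_b["strength"].to_numpy()
    for i, name in enumerate(names):
        pval = float(nct_result.strength_p[i])
        rows.append({"item": name, "kind": "strength",
                     "value_a": float(sa[i]), "value_b": float(sb[i]),
                     "difference": float(sa[i] - sb[i]),
                     "p_value": pval, "significant": pval < alpha})
    wa = nct_result.network_a.weights
    wb = nct_result.network_b.weights
    for i in range(p):
        for j in range(i + 1, p):
            pval = float(nct_result.edge_p[i, j])
            rows.append({"item": f"{names[i]}--{names[j]}", "kind": "edge",
                         "value_a": float(wa[i, j]), "value_b": float(wb[i, j]),
                         "difference": float(wa[i, j] - wb[i, j]),
                         "p_value": pval, "significant": pval < alpha})
    out = pd.DataFrame(rows)
    if sort_by is not None:
        out = out.sort_values(sort_by, kind="stable").reset_index(drop=True)
    return out
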