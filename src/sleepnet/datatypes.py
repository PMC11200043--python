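"""Shared data containers for symptom-network analysis.

The pipeline operates on binary (0/1) questionnaire responses and pairwise
Markov random fields over them (Ising models): ``P(x) ∝ exp(Σ_i τ_i x_i +
Σ_{i<j} ω_ij x_i x_j)``, with node thresholds ``τ`` on the log-odds scale and
a symmetric zero-diagonal edge-weight matrix ``Ω``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BinarySymptomTable",
    "IsingModel",
    "EstimationConfig",
    "NetworkArtifact",
    "potential_edge_count",
]


def potential_edge_count(p: int) -> int:
    """Number of unordered node pairs in a p-node network: p(p-1)/2."""
    return p * (p - 1) // 2


@dataclass(frozen=True)
class BinarySymptomTable:
    """Respondents × binary symptoms, with block and (optional) group labels.

    Parameters
    ----------
    values
        ``(n, p)`` array with entries in {0, 1}; missingness must be resolved
        (rows dropped or recoded) before construction.
    variable_names
        ``p`` unique column labels.
    block_labels
        ``p`` thematic block labels (e.g. the 8 clinical groupings used for
        sleep questionnaires); defaults to a single block.
    group_labels
        Optional mapping of grouping-factor name -> length-``n`` label array
        (e.g. ``{"sex": [...], "age_group": [...]}``).
    """

    values: np.ndarray
    variable_names: tuple[str, ...]
    block_labels: tuple[str, ...] = ()
    group_labels: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D respondents × symptoms array")
        n, p = values.shape
        if n < 1 or p < 2:
            raise ValueError(f"need n >= 1 and p >= 2, got n={n}, p={p}")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("values must contain only 0 and 1 (resolve missing data first)")
        object.__setattr__(self, "values", values)
        names = tuple(str(v) for v in self.variable_names)
        if len(names) != p:
            raise ValueError(f"expected {p} variable names, got {len(names)}")
        if len(set(names)) != p:
            raise ValueError("variable_names must be unique")
        object.__setattr__(self, "variable_names", names)
        blocks = tuple(str(b) for b in self.block_labels) or ("all",) * p
        if len(blocks) != p:
            raise ValueError(f"expected {p} block labels, got {len(blocks)}")
        object.__setattr__(self, "block_labels", blocks)
        groups = {}
        for key, labels in dict(self.group_labels).items():
            arr = np.asarray(labels)
            if arr.shape != (n,):
                raise ValueError(f"group factor {key!r} must have length n={n}")
            groups[key] = arr
        object.__setattr__(self, "group_labels", groups)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def group_levels(self, factor: str) -> tuple:
        """Sorted distinct levels of a grouping factor."""
        return tuple(sorted(np.unique(self.group_labels[factor]).tolist()))

    def subset_rows(self, index: np.ndarray) -> "BinarySymptomTable":
        """Row subset (boolean mask or integer index), groups carried along."""
        groups = {k: v[index] for k, v in self.group_labels.items()}
        return BinarySymptomTable(self.values[index], self.variable_names,
                                  self.block_labels, groups)

    def group_subset(self, factor: str, level) -> "BinarySymptomTable":
        return self.subset_rows(self.group_labels[factor] == level)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(np.int64), columns=list(self.variable_names))
        for key, labels in self.group_labels.items():
            df[key] = labels
        return df

    def canonical_row_order(self) -> np.ndarray:
        """Deterministic row permutation: lexicographic in (values, group labels).

        Sorting pooled data canonically before drawing permutations makes
        permutation p-values invariant to the input row order.
        """
        keys = [self.values[:, j] for j in range(self.p - 1, -1, -1)]
        for key in sorted(self.group_labels):
            keys.insert(0, np.asarray(self.group_labels[key], dtype=str))
        return np.lexsort(keys)


@dataclass(frozen=True)
class IsingModel:
    """Node thresholds τ (log-odds) and symmetric edge weights Ω."""

    thresholds: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.thresholds, dtype=np.float64).ravel()
        omega = np.asarray(self.weights, dtype=np.float64)
        p = tau.shape[0]
        if omega.shape != (p, p):
            raise ValueError(f"weights must be {p}×{p} to match thresholds, got {omega.shape}")
        if not np.allclose(omega, omega.T, atol=1e-12):
            raise ValueError("weights matrix must be symmetric")
        if not np.allclose(np.diag(omega), 0.0, atol=1e-12):
            raise ValueError("weights matrix must have zero diagonal")
        omega = (omega + omega.T) / 2.0
        np.fill_diagonal(omega, 0.0)
        object.__setattr__(self, "thresholds", tau)
        object.__setattr__(self, "weights", omega)

    @property
    def p(self) -> int:
        return self.thresholds.shape[0]

    @property
    def n_potential_edges(self) -> int:
        return potential_edge_count(self.p)

    @property
    def n_edges(self) -> int:
        """Count of nonzero unordered pairs."""
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Nonzero unordered edges as (i, j, weight) with i < j."""
        iu, ju = np.triu_indices(self.p, k=1)
        w = self.weights[iu, ju]
        keep = w != 0.0
        return [(int(i), int(j), float(v)) for i, j, v in zip(iu[keep], ju[keep], w[keep])]


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for nodewise L1-penalized pseudo-likelihood estimation (eLasso).

    ``ebic_gamma`` is the EBIC sparsity hyperparameter γ (0 recovers BIC;
    0.25 is the established default for Ising networks). The λ path has
    ``lambda_count`` log-spaced values from the per-node λ_max down to
    ``λ_max · lambda_min_ratio``. ``symmetrization_rule`` is "AND" (edge kept
    only if both directed coefficients are nonzero) or "OR".
    """

    ebic_gamma: float = 0.25
    lambda_count: int = 100
    lambda_min_ratio: float = 0.01
    symmetrization_rule: str = "AND"
    max_iterations: int = 1000
    convergence_tolerance: float = 1e-7
    min_prevalence: float = 0.005

    def __post_init__(self) -> None:
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")
        if self.lambda_count < 2:
            raise ValueError("lambda_count must be >= 2")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.symmetrization_rule not in ("AND", "OR"):
            raise ValueError("symmetrization_rule must be 'AND' or 'OR'")

    def with_(self, **kwargs) -> "EstimationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NetworkArtifact:
    """An estimated (or planted) network with its provenance."""

    model: IsingModel
    group_id: str = "all"
    n_used: int = 0
    config: EstimationConfig | None = None
    variable_names: tuple[str, ...] = ()
    block_labels: tuple[str, ...] = ()
    layout: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = self.model.p
        names = tuple(self.variable_names) or tuple(f"V{i + 1}" for i in range(p))
        if len(names) != p:
            raise ValueError("one variable name per node required")
        object.__setattr__(self, "variable_names", names)
        blocks = tuple(self.block_labels) or ("all",) * p
        if len(blocks) != p:
            raise ValueError("one block label per node required")
        object.__setattr__(self, "block_labels", blocks)
        if self.layout is not None:
            layout = np.asarray(self.layout, dtype=np.float64)
            if layout.shape != (p, 2):
                raise ValueError("layout must provide one (x, y) pair per node")
            object.__setattr__(self, "layout", layout)
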