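"""Synthetic binary questionnaire data from planted Ising models.

Provides the generative counterpart of the estimation pipeline: sparse
positive-dominant pairwise networks over thematic blocks of symptoms,
threshold calibration to marginal-prevalence targets, exact enumeration of
the state distribution on small graphs (the oracle used throughout the test
suite), exact and Gibbs sampling, and grouped scenarios that mimic a cohort
split into unequal groups (e.g. a 69.7% / 30.3% sex split) drawn from
identical or perturbed networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logit, softmax

from ._solver import gibbs_sample
from .datatypes import BinarySymptomTable, IsingModel

logger = logging.getLogger(__name__)

__all__ = [
    "GraphSpec",
    "GroupSpec",
    "Perturbation",
    "ScenarioSpec",
    "ExactDistribution",
    "exact_distribution",
    "plant_model",
    "sample_ising",
    "make_group_scenario",
    "perturb_model",
    "default_scenario",
]

_MAX_EXACT_P = 12


@dataclass(frozen=True)
class GraphSpec:
    """Edge-density and weight-distribution parameters for a planted network.

    ``density`` is the probability a between-block pair receives an edge;
    within-block pairs use ``density × within_block_multiplier`` (clipped to
    1), mimicking thematically clustered symptom networks. Nonzero weights
    have magnitude uniform on ``weight_range`` and are positive with
    probability ``positive_fraction`` (default 70% positive / 30% negative,
    matching sparse, predominantly positive symptom networks).
    """

    density: float = 0.2
    positive_fraction: float = 0.7
    weight_range: tuple[float, float] = (0.2, 1.0)
    within_block_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        lo, hi = self.weight_range
        if not 0.0 <= lo <= hi:
            raise ValueError("weight_range must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class Perturbation:
    """How a group's network differs from the base model.

    ``scale`` multiplies edge weights (all edges, or only ``edge_subset``);
    ``rewire_fraction`` moves that share of existing edges to currently empty
    pairs, keeping the edge count fixed.
    """

    scale: float = 1.0
    edge_subset: tuple[tuple[int, int], ...] | None = None
    rewire_fraction: float = 0.0


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    perturbation: Perturbation = field(default_factory=Perturbation)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete synthetic-cohort recipe: network, prevalences, groups."""

    p: int
    graph_spec: GraphSpec = field(default_factory=GraphSpec)
    prevalence_targets: tuple[float, ...] = ()
    block_structure: tuple[str, ...] = ()
    groups: tuple[GroupSpec, ...] = ()
    seed: int = 0
    sampler: str = "gibbs"

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("need p >= 2")
        targets = tuple(float(t) for t in self.prevalence_targets)
        if not targets:
            targets = _default_prevalences(self.p, self.seed)
        if len(targets) != self.p:
            raise ValueError("one prevalence target per node required")
        if any(not 0.0 < t < 1.0 for t in targets):
            raise ValueError("prevalence targets must lie strictly inside (0, 1)")
        object.__setattr__(self, "prevalence_targets", targets)
        blocks = tuple(self.block_structure) or _default_blocks(self.p)
        if len(blocks) != self.p:
            raise ValueError("one block label per node required")
        object.__setattr__(self, "block_structure", blocks)
        groups = tuple(self.groups) or (GroupSpec("all", 1000),)
        object.__setattr__(self, "groups", groups)


def _default_prevalences(p: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E37]))
    return tuple(rng.uniform(0.15, 0.5, size=p).round(4).tolist())


def _default_blocks(p: int, n_blocks: int = 8) -> tuple[str, ...]:
    """Round-robin-free contiguous assignment into up to 8 thematic blocks."""
    n_blocks = min(n_blocks, p)
    sizes = np.full(n_blocks, p // n_blocks)
    sizes[: p % n_blocks] += 1
    labels: list[str] = []
    for b, size in enumerate(sizes):
        labels.extend([f"block{b + 1}"] * int(size))
    return tuple(labels)


@dataclass(frozen=True)
class ExactDistribution:
    """Exhaustive state table for a small Ising model (p <= 12)."""

    states: np.ndarray          # (2^p, p) in {0,1}
    probabilities: np.ndarray   # (2^p,), sums to 1
    marginals: np.ndarray       # (p,)  E[x_i]
    pairwise: np.ndarray        # (p,p) E[x_i x_j]


def _all_states(p: int) -> np.ndarray:
    codes = np.arange(2 ** p, dtype=np.int64)
    return ((codes[:, None] >> np.arange(p)) & 1).astype(np.float64)


def exact_distribution(model: IsingModel) -> ExactDistribution:
    """Enumerate P(x) ∝ exp(τ'x + ½ x'Ωx) over all 2^p binary states.

    Refuses p > 12 (4096-state guard); use :func:`sample_ising` with the
    Gibbs method for larger graphs.
    """
    p = model.p
    if p > _MAX_EXACT_P:
        raise ValueError(
            f"exact enumeration limited to p <= {_MAX_EXACT_P} (got p={p}); "
            "use sample_ising(..., method='gibbs') instead"
        )
    states = _all_states(p)
    energy = states @ model.thresholds + 0.5 * np.einsum(
        "si,ij,sj->s", states, model.weights, states
    )
    probs = softmax(energy)
    marginals = probs @ states
    pairwise = states.T @ (states * probs[:, None])
    return ExactDistribution(states, probs, marginals, pairwise)


def _exact_marginals(model: IsingModel) -> np.ndarray:
    return exact_distribution(model).marginals


def _gibbs_marginals(model: IsingModel, n: int, seed: int) -> np.ndarray:
    draws = gibbs_sample(model.thresholds, model.weights, n, 500, 2, seed)
    return draws.mean(axis=0)


def _random_weights(p: int, blocks: Sequence[str], spec: GraphSpec,
                    rng: np.random.Generator) -> np.ndarray:
    omega = np.zeros((p, p))
    lo, hi = spec.weight_range
    for i in range(p):
        for j in range(i + 1, p):
            dens = spec.density
            if blocks[i] == blocks[j]:
                dens = min(1.0, dens * spec.within_block_multiplier)
            if rng.random() < dens:
                mag = rng.uniform(lo, hi)
                sign = 1.0 if rng.random() < spec.positive_fraction else -1.0
                omega[i, j] = omega[j, i] = sign * mag
    return omega


def plant_model(graph_spec: GraphSpec, prevalence_targets: Sequence[float],
                seed: int, block_structure: Sequence[str] | None = None,
                tolerance: float = 0.02, max_iterations: int = 200,
                damping: float = 0.6) -> IsingModel:
    """Draw a sparse symmetric network and calibrate thresholds to prevalences.

    Thresholds start at logit of the targets and are adjusted by damped
    fixed-point updates ``τ ← τ + damping·(logit(target) − logit(marginal))``
    until every realized marginal is within ``tolerance`` of its target.
    Marginals are exact (enumeration) for p <= 12 and Gibbs estimates above.

    Raises ``RuntimeError`` naming the worst node if calibration fails within
    ``max_iterations``.
    """
    targets = np.asarray(prevalence_targets, dtype=np.float64)
    if np.any(targets <= 0.0) or np.any(targets >= 1.0):
        raise ValueError("prevalence targets must lie strictly inside (0, 1)")
    p = targets.shape[0]
    blocks = tuple(block_structure) if block_structure is not None else ("all",) * p
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51A7]))
    omega = _random_weights(p, blocks, graph_spec, rng)

    tau = logit(targets)
    target_logit = logit(targets)
    exact = p <= _MAX_EXACT_P
    cal_n = 4000
    worst = np.inf
    for it in range(max_iterations):
        model = IsingModel(tau, omega)
        if exact:
            marg = _exact_marginals(model)
        else:
            marg = _gibbs_marginals(model, cal_n, int(rng.integers(2 ** 31)))
        err = np.abs(marg - targets)
        worst = float(err.max())
        if worst < tolerance:
            logger.debug("threshold calibration converged in %d iterations "
                         "(worst error %.4f)", it, worst)
            return model
        marg_c = np.clip(marg, 1e-6, 1 - 1e-6)
        tau = tau + damping * (target_logit - logit(marg_c))
    worst_node = int(np.argmax(np.abs(
        (_exact_marginals(IsingModel(tau, omega)) if exact
         else _gibbs_marginals(IsingModel(tau, omega), cal_n, int(rng.integers(2 ** 31))))
        - targets)))
    raise RuntimeError(
        f"threshold calibration did not reach tolerance {tolerance} in "
        f"{max_iterations} iterations; worst node index {worst_node}"
    )


def sample_ising(model: IsingModel, n: int, seed: int, method: str = "exact",
                 burn_in: int = 1000, thinning: int = 10,
                 variable_names: Sequence[str] | None = None,
                 block_labels: Sequence[str] | None = None) -> BinarySymptomTable:
    """Draw ``n`` respondents from an Ising model.

    ``method='exact'`` samples i.i.d. from the enumerated distribution
    (p <= 12 only); ``method='gibbs'`` runs a single-site Gibbs chain with
    ``burn_in`` discard sweeps and one retained draw every ``thinning``
    sweeps (conservative defaults for p <= 50).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if method == "exact":
        dist = exact_distribution(model)
        rng = np.random.default_rng(seed)
        idx = rng.choice(dist.states.shape[0], size=n, p=dist.probabilities)
        values = dist.states[idx]
    elif method == "gibbs":
        values = gibbs_sample(model.thresholds, model.weights, n, burn_in,
                              thinning, int(seed) % (2 ** 32))
    else:
        raise ValueError("method must be 'exact' or 'gibbs'")
    names = tuple(variable_names) if variable_names is not None else tuple(
        f"V{i + 1}" for i in range(model.p))
    blocks = tuple(block_labels) if block_labels is not None else ()
    return BinarySymptomTable(values, names, blocks)


def perturb_model(model: IsingModel, perturbation: Perturbation,
                  seed: int = 0) -> IsingModel:
    """Apply a group perturbation (rescale and/or rewire) to a base model."""
    omega = model.weights.copy()
    if perturbation.edge_subset is not None:
        for i, j in perturbation.edge_subset:
            if omega[i, j] == 0.0:
                raise ValueError(f"perturbation addresses nonexistent edge ({i}, {j})")
            omega[i, j] *= perturbation.scale
            omega[j, i] = omega[i, j]
    elif perturbation.scale != 1.0:
        omega *= perturbation.scale
    if perturbation.rewire_fraction > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E]))
        iu, ju = np.triu_indices(model.p, k=1)
        present = np.flatnonzero(omega[iu, ju] != 0.0)
        absent = np.flatnonzero(omega[iu, ju] == 0.0)
        k = int(round(perturbation.rewire_fraction * present.size))
        k = min(k, absent.size)
        move = rng.choice(present, size=k, replace=False)
        dest = rng.choice(absent, size=k, replace=False)
        for src, dst in zip(move, dest):
            w = omega[iu[src], ju[src]]
            omega[iu[src], ju[src]] = omega[ju[src], iu[src]] = 0.0
            omega[iu[dst], ju[dst]] = omega[ju[dst], iu[dst]] = w
    return IsingModel(model.thresholds, omega)


def make_group_scenario(spec: ScenarioSpec) -> tuple[BinarySymptomTable, list[IsingModel]]:
    """Generate a grouped cohort and return it with the per-group truths.

    The base network is planted once from ``spec``; each group's model is the
    base model under that group's perturbation; groups are sampled
    independently (seeds derived from ``spec.seed``) and concatenated with a
    ``group`` factor.
    """
    base = plant_model(spec.graph_spec, spec.prevalence_targets, spec.seed,
                       block_structure=spec.block_structure)
    method = spec.sampler if spec.p > _MAX_EXACT_P or spec.sampler == "gibbs" else "exact"
    if spec.p > _MAX_EXACT_P:
        method = "gibbs"
    ss = np.random.SeedSequence([spec.seed, 0xC0])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(spec.groups))]
    names = tuple(f"V{i + 1}" for i in range(spec.p))
    tables = []
    labels = []
    truths = []
    for gspec, gseed in zip(spec.groups, child_seeds):
        gmodel = perturb_model(base, gspec.perturbation, seed=gseed)
        truths.append(gmodel)
        tbl = sample_ising(gmodel, gspec.n, gseed, method=method,
                           variable_names=names, block_labels=spec.block_structure)
        tables.append(tbl.values)
        labels.extend([gspec.label] * gspec.n)
    values = np.vstack(tables)
    table = BinarySymptomTable(values, names, spec.block_structure,
                               {"group": np.asarray(labels)})
    return table, truths


def default_scenario(seed: int = 0, p: int = 20, n_total: int = 3000,
                     larger_fraction: float = 0.697) -> ScenarioSpec:
    """Desk-scale mimic of the study cohort: p=20 symptoms in 8 blocks, two
    groups of unequal size (69.7% / 30.3%) drawn from one common network."""
    n_a = int(round(n_total * larger_fraction))
    return ScenarioSpec(
        p=p,
        graph_spec=GraphSpec(density=0.15, within_block_multiplier=2.5),
        groups=(GroupSpec("women", n_a), GroupSpec("men", n_total - n_a)),
        seed=seed,
    )
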