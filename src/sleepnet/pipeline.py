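"""End-to-end orchestration: data (or scenario) → networks → inference →
comparison → robustness → machine-readable summary.

A single config (dict, YAML or JSON) names the input data or a simulation
scenario, the grouping factor, and the estimation/comparison/bootstrap
settings; given the same config and seed the pipeline output is
deterministic (byte-identical summary JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import (BinarySymptomTable, EstimationConfig, IsingModel,
                        NetworkArtifact)
from .estimation import estimate_ising
from .io import VariableSpec, read_symptom_csv, write_network
from .metrics import (centrality_table, fr_layout, global_strength,
                      predictability, standardize)
from .nct import NCTResult, balanced_subsample_nct, local_correlation_report
from .robustness import (DEFAULT_DROP_GRID, StabilityResult,
                         case_dropping_bootstrap)
from .simulate import (GraphSpec, GroupSpec, Perturbation, ScenarioSpec,
                       make_group_scenario)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus the JSON-ready summary."""

    table: BinarySymptomTable
    artifacts: dict[str, NetworkArtifact]
    centralities: dict[str, pd.DataFrame]
    predictabilities: dict[str, pd.DataFrame]
    nct_results: dict[tuple[str, str], NCTResult]
    stability_results: dict[str, StabilityResult]
    true_models: list[IsingModel] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def summary_json(self) -> str:
        return json.dumps(self.summary, indent=1, sort_keys=True)


def load_config(source) -> dict:
    """Accept a dict, or a path to a YAML/JSON config file."""
    if isinstance(source, Mapping):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text)


def _scenario_from_config(cfg: Mapping, seed: int) -> ScenarioSpec:
    groups = tuple(
        GroupSpec(str(g["label"]), int(g["n"]),
                  Perturbation(scale=float(g.get("scale", 1.0)),
                               rewire_fraction=float(g.get("rewire_fraction", 0.0))))
        for g in cfg.get("groups", [{"label": "all", "n": 1000}])
    )
    graph = GraphSpec(
        density=float(cfg.get("density", 0.2)),
        positive_fraction=float(cfg.get("positive_fraction", 0.7)),
        weight_range=tuple(cfg.get("weight_range", (0.2, 1.0))),
        within_block_multiplier=float(cfg.get("within_block_multiplier", 1.0)),
    )
    return ScenarioSpec(
        p=int(cfg["p"]),
        graph_spec=graph,
        prevalence_targets=tuple(cfg.get("prevalence_targets", ())),
        block_structure=tuple(cfg.get("block_structure", ())),
        groups=groups,
        seed=int(cfg.get("seed", seed)),
        sampler=str(cfg.get("sampler", "gibbs")),
    )


def _load_table(config: Mapping, seed: int) -> tuple[BinarySymptomTable, list[IsingModel], str]:
    if "scenario" in config:
        spec = _scenario_from_config(config["scenario"], seed)
        table, truths = make_group_scenario(spec)
        return table, truths, "group"
    if "data" not in config:
        raise ValueError("config must contain either 'scenario' or 'data'")
    data_cfg = config["data"]
    spec = VariableSpec.from_dict(data_cfg)
    group_column = config.get("group_column")
    group_cols = [group_column] if group_column else []
    table = read_symptom_csv(data_cfg["path"], spec, group_cols)
    return table, [], group_column or ""


def _derived_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config, output_dir=None) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Steps: load/simulate the grouped table; estimate one network per group
    level (lexicographic order); compute centrality (raw and z-standardized),
    predictability and layout per group; compare every group pair with the
    (subsampled, averaged) NCT; run the case-dropping bootstrap per group;
    assemble a deterministic summary. Files are written under ``output_dir``
    (or ``config['output_dir']``) when given.

    Refuses to estimate any group with fewer rows than ``min_group_n``.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    est_cfg = EstimationConfig(**config.get("estimation", {}))
    min_group_n = int(config.get("min_group_n", 100))
    pred_method = str(config.get("predictability_method", "r2"))

    table, truths, group_column = _load_table(config, seed)

    if group_column and group_column in table.group_labels:
        raw_levels = table.group_levels(group_column)
        levels = [str(lv) for lv in raw_levels]
        subsets = {str(lv): table.group_subset(group_column, lv)
                   for lv in raw_levels}
    else:
        levels = ["all"]
        subsets = {"all": table}

    for lv in levels:
        if subsets[lv].n < min_group_n:
            raise ValueError(
                f"group {lv!r} has only {subsets[lv].n} rows, below the "
                f"configured minimum of {min_group_n}; refusing to estimate")

    out = Path(output_dir or config.get("output_dir", "")) if (
        output_dir or config.get("output_dir")) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    artifacts: dict[str, NetworkArtifact] = {}
    centralities: dict[str, pd.DataFrame] = {}
    predictabilities: dict[str, pd.DataFrame] = {}
    for gi, lv in enumerate(levels):
        sub = subsets[lv]
        model = estimate_ising(sub, est_cfg)
        layout = fr_layout(model, seed=_derived_seed(seed, 1, gi))
        artifact = NetworkArtifact(model, lv, sub.n, est_cfg,
                                   sub.variable_names, sub.block_labels, layout)
        artifacts[lv] = artifact
        cent = centrality_table(model, sub.variable_names)
        cent_z = standardize(cent).add_suffix("_z")
        centralities[lv] = pd.concat([cent, cent_z], axis=1)
        predictabilities[lv] = predictability(sub, model, pred_method)
        if out is not None:
            write_network(artifact, out / f"network_{lv}.json", "json")
            centralities[lv].to_csv(out / f"centrality_{lv}.csv")
            predictabilities[lv].to_csv(out / f"predictability_{lv}.csv")

    cmp_cfg = dict(config.get("comparison", {}))
    nct_results: dict[tuple[str, str], NCTResult] = {}
    if cmp_cfg.get("enabled", True) and len(levels) > 1:
        for pi, (a, b) in enumerate(combinations(levels, 2)):
            res = balanced_subsample_nct(
                subsets[a], subsets[b],
                repeats=int(cmp_cfg.get("subsample_repeats", 5)),
                config=est_cfg,
                seed=_derived_seed(seed, 2, pi),
                n_permutations=int(cmp_cfg.get("n_permutations", 2000)),
                labels=(a, b))
            nct_results[(a, b)] = res
            if out is not None:
                (out / f"nct_{a}_vs_{b}.json").write_text(
                    json.dumps(res.to_dict(), indent=1, sort_keys=True))
                report = local_correlation_report(
                    centralities[a][["strength"]],
                    centralities[b][["strength"]], res,
                    alpha=float(cmp_cfg.get("alpha", 0.05)))
                report.to_csv(out / f"local_{a}_vs_{b}.csv", index=False)

    rob_cfg = dict(config.get("robustness", {}))
    stability_results: dict[str, StabilityResult] = {}
    if rob_cfg.get("enabled", True):
        grid = tuple(rob_cfg.get("drop_proportions", DEFAULT_DROP_GRID))
        for gi, lv in enumerate(levels):
            res = case_dropping_bootstrap(
                subsets[lv], est_cfg, drop_proportions=grid,
                n_boot=int(rob_cfg.get("n_boot", 50)),
                seed=_derived_seed(seed, 3, gi))
            stability_results[lv] = res
            if out is not None:
                (out / f"stability_{lv}.json").write_text(
                    json.dumps(res.to_dict(), indent=1, sort_keys=True))

    summary = _build_summary(seed, est_cfg, levels, subsets, artifacts,
                             centralities, predictabilities, nct_results,
                             stability_results)
    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))

    return PipelineResult(table, artifacts, centralities, predictabilities,
                          nct_results, stability_results, truths, summary)


def _build_summary(seed, est_cfg, levels, subsets, artifacts, centralities,
                   predictabilities, nct_results, stability_results) -> dict:
    groups = {}
    for lv in levels:
        model = artifacts[lv].model
        cent = centralities[lv]
        top = cent["strength"].sort_values(ascending=False, kind="stable")
        groups[lv] = {
            "n": subsets[lv].n,
            "p": model.p,
            "n_potential_edges": model.n_potential_edges,
            "n_edges": model.n_edges,
            "global_strength": global_strength(model),
            "mean_abs_weight": float(np.abs(model.weights[
                np.triu_indices(model.p, k=1)]).mean()),
            "top_strength_nodes": list(top.index[:5]),
            "mean_predictability": float(
                predictabilities[lv]["predictability"].mean()),
        }
    comparisons = {
        f"{a}_vs_{b}": {
            "m_statistic": res.m_statistic, "p_m": res.p_m,
            "s_statistic": res.s_statistic, "p_s": res.p_s,
            "global_strengths": list(res.global_strengths),
            "subsample_repeats": res.subsample_repeats,
            "n_permutations": res.n_permutations,
        }
        for (a, b), res in nct_results.items()
    }
    stability = {
        lv: {"cs_coefficient": res.cs_coefficient,
             "n_boot": res.n_boot,
             "drop_proportions": list(res.drop_proportions)}
        for lv, res in stability_results.items()
    }
    return {
        "seed": seed,
        "estimation": dataclasses.asdict(est_cfg),
        "groups": groups,
        "comparisons": comparisons,
        "stability": stability,
    }
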