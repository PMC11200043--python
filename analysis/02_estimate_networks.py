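#!/usr/bin/env python
"""Estimate one symptom network per group from the simulated cohort.

Runs the nodewise eLasso (L1-penalized logistic pseudo-likelihood, EBIC
selection with γ=0.25, AND-rule symmetrization) separately on each group of
the cohort written by 01_simulate_cohort.py, and reports edge counts and
recovery against the planted truth.
"""

from pathlib import Path

import numpy as np

from sleepnet import (EstimationConfig, NetworkArtifact, VariableSpec,
                      estimate_ising, fr_layout, read_network,
                      read_symptom_csv, write_network)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = ROOT / "scratch" / "cohort.csv"
CONFIG = EstimationConfig(lambda_count=50)


def main() -> None:
    table = read_symptom_csv(
        COHORT,
        VariableSpec(tuple(f"V{i + 1}" for i in range(20))), ["group"])
    for level in table.group_levels("group"):
        sub = table.group_subset("group", level)
        model = estimate_ising(sub, CONFIG)
        layout = fr_layout(model, seed=1)
        artifact = NetworkArtifact(model, str(level), sub.n, CONFIG,
                                   sub.variable_names, sub.block_labels,
                                   layout)
        out = RESULTS / f"network_{level}.json"
        write_network(artifact, out, "json")
        truth = read_network(RESULTS / f"truth_{level}.json").model
        iu = np.triu_indices(model.p, 1)
        te, ee = truth.weights[iu] != 0, model.weights[iu] != 0
        sens = (te & ee).sum() / max(te.sum(), 1)
        spec = (~te & ~ee).sum() / max((~te).sum(), 1)
        print(f"group {level} (n={sub.n}): {model.n_edges} of "
              f"{model.n_potential_edges} potential edges; recovery "
              f"sensitivity {sens:.2f}, specificity {spec:.2f} -> {out.name}")


if __name__ == "__main__":
    main()
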