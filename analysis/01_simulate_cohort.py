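#!/usr/bin/env python
"""Simulate the desk-scale study cohort.

Plants one sparse, predominantly positive symptom network (p=20 binary
symptoms in 8 thematic blocks), calibrates thresholds so every symptom has a
realistic marginal prevalence, and draws two groups of unequal size
(69.7% / 30.3% of n=3000, mimicking a women/men split) from the *same*
network — the null configuration against which the comparison machinery is
exercised. Writes the cohort CSV and the ground-truth networks.
"""

from pathlib import Path

import numpy as np

from sleepnet import NetworkArtifact, default_scenario, make_group_scenario, write_network

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 20260926


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = default_scenario(seed=SEED)
    table, truths = make_group_scenario(spec)
    SCRATCH.mkdir(exist_ok=True)
    csv_path = SCRATCH / "cohort.csv"
    table.to_frame().to_csv(csv_path, index=False)
    labels, counts = np.unique(table.group_labels["group"], return_counts=True)
    print(f"cohort: {table.n} respondents × {table.p} symptoms "
          f"({dict(zip(labels.tolist(), counts.tolist()))})")
    for gspec, model in zip(spec.groups, truths):
        artifact = NetworkArtifact(model, gspec.label, gspec.n,
                                   variable_names=table.variable_names,
                                   block_labels=table.block_labels)
        out = RESULTS / f"truth_{gspec.label}.json"
        write_network(artifact, out, "json")
        print(f"ground truth for {gspec.label}: {model.n_edges} of "
              f"{model.n_potential_edges} potential edges -> {out.name}")
    print(f"wrote {csv_path}")


if __name__ == "__main__":
    main()
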