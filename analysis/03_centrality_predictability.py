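#!/usr/bin/env python
"""Node-level inference: centrality and predictability per group.

For each estimated group network: strength, closeness, betweenness and
expected influence (raw and z-standardized), plus nodewise predictability
(Brier-based R², i.e. how well each symptom is predicted by its estimated
neighbors). Prints the top symptoms by standardized strength — the quantity
used to rank symptom importance.
"""

from pathlib import Path

from sleepnet import (VariableSpec, centrality_table, predictability,
                      read_network, read_symptom_csv, standardize)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = ROOT / "scratch" / "cohort.csv"


def main() -> None:
    table = read_symptom_csv(
        COHORT,
        VariableSpec(tuple(f"V{i + 1}" for i in range(20))), ["group"])
    for level in table.group_levels("group"):
        artifact = read_network(RESULTS / f"network_{level}.json")
        sub = table.group_subset("group", level)
        cent = centrality_table(artifact.model, artifact.variable_names)
        full = cent.join(standardize(cent).add_suffix("_z"))
        full.to_csv(RESULTS / f"centrality_{level}.csv")
        pred = predictability(sub, artifact.model)
        pred.to_csv(RESULTS / f"predictability_{level}.csv")
        top = full["strength_z"].sort_values(ascending=False).head(3)
        print(f"group {level}: top symptoms by standardized strength:")
        for name, z in top.items():
            print(f"  {name}: strength z={z:+.2f}, "
                  f"predictability={pred.loc[name, 'predictability']:.2f}")


if __name__ == "__main__":
    main()
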