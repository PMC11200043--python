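# sleepnet

Network analysis of binary symptom data, built for clinical questionnaire
studies (the motivating case: sleep-health questionnaires with dozens of
yes/no symptom items and grouping factors such as sex and age band). The
package estimates a sparse Ising network over symptoms, ranks symptoms by
centrality and predictability, compares two groups' networks with a
permutation test, and quantifies robustness by bootstrap — and ships a
synthetic-cohort generator with an exact small-graph oracle, so every part
of the pipeline is testable against a known ground truth.

## The model and the pipeline

Symptoms x ∈ {0,1}^p follow a pairwise Markov random field (Ising model)

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} ω_ij x_i x_j ),

estimated by the eLasso recipe: nodewise L1-penalized logistic regression
(logit P(x_i|x_−i) = τ_i + Σ_j ω_ij x_j), per-node penalty selected by the
extended Bayesian information criterion EBIC = −2ℓ + k log n +
2γ k log(p−1) with γ = 0.25, AND-rule symmetrization. On top of the fitted
network:

* **centrality** — strength Σ|ω|, expected influence Σω, closeness and
  betweenness on edge lengths 1/|ω| (raw and z-standardized);
* **predictability** — per node, a Brier-score R² of the unpenalized
  logistic refit on its estimated neighbors, in [0, 1];
* **comparison (NCT)** — permutation test of the structure statistic
  M = max|ω^A − ω^B| and the global-strength statistic S = |GS_A − GS_B|,
  with local per-edge/per-node p-values; unequal groups are handled by
  subsampling the larger group 5× and averaging;
* **robustness** — nonparametric edge bootstrap and the case-dropping CS
  coefficient (largest drop proportion keeping, with 95% probability, a
  correlation ≥ 0.70 with full-sample strengths; ≥ 0.25 recommended).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run a complete desk-scale study on a
simulated cohort (p = 20 symptoms in 8 thematic blocks, two groups —
"women" n = 2091, "men" n = 909 — drawn from one common planted network),
writing tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_estimate_networks.py
python analysis/03_centrality_predictability.py
python analysis/04_compare_networks.py
python analysis/05_robustness.py
```

Output of steps 2, 4 and 5 (abridged):

```
group men (n=909): 11 of 190 potential edges; recovery sensitivity 0.42, specificity 1.00
group women (n=2091): 22 of 190 potential edges; recovery sensitivity 0.85, specificity 1.00
...
global strength: women 4.86, men 4.57
S test: 0.829 (P=0.628); M test: 0.589 (P=0.563) [5 subsample repeats × 200 permutations]
local tests flagged at α=.05 (unadjusted): 0 of 210 rows
...
group men (n=909): CS(strength) = 0.10 (too low; floor 0.25)
group women (n=2091): CS(strength) = 0.40 (acceptable; floor 0.25)
women's network edge bootstrap (200 draws): 8 of 22 estimated edges have
95% intervals excluding zero
```

Read: with more respondents the women's network recovers more of the 26
planted edges (the AND rule plus EBIC is conservative, so specificity stays
at 1.00 and the missing edges are the weak ones); both groups were drawn
from the same network, and the comparison correctly finds no significant
difference in structure (M), global strength (S) or any of the 210 local
tests. The robustness step then earns its keep: at n = 909 the strength
ordering is *not* stable (CS 0.10 < 0.25), so centrality conclusions should
only be drawn for the larger group — exactly the situation the CS
coefficient exists to flag.

The same pipeline is available programmatically (`sleepnet.run_pipeline`)
and as a CLI (`sleepnet simulate|estimate|metrics|compare|bootstrap|report`)
for CSV questionnaire data with a header row of symptom columns; see
`sleepnet <cmd> --help`.

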