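# Methods

`sleepnet` implements a complete symptom-network analysis pipeline for
binary questionnaire data: estimation of a pairwise Markov random field
(Ising model) over symptoms, node-level inference (centrality and
predictability), permutation-based comparison of two groups' networks, and
bootstrap robustness. Because the motivating application domain (clinical
sleep questionnaires) rarely comes with public raw data, the package also
contains a first-class synthetic-cohort generator with an exact small-graph
oracle; every statistical guarantee the test suite asserts is a statement
about this generator's planted ground truth.

## Model

The joint law of p binary symptoms x ∈ {0,1}^p is

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} ω_ij x_i x_j ),

with node thresholds τ_i (log-odds scale) and a symmetric, zero-diagonal
weight matrix Ω. The full conditional of each node is logistic:
logit P(x_i = 1 | x_−i) = τ_i + Σ_j ω_ij x_j, which is what makes nodewise
(pseudo-likelihood) estimation consistent and cheap.

## Estimation (eLasso)

Each node is regressed on all remaining nodes by L1-penalized logistic
regression with an unpenalized intercept. Per node we solve

    min −ℓ(b0, β)/n + λ‖β‖₁

along a decreasing grid of `lambda_count` (default 100) log-spaced values
from just above λ_max (the smallest penalty producing the empty model —
starting strictly above it guarantees the k = 0 model is on the path) down
to `λ_max · lambda_min_ratio` (default 0.01). The per-λ model is scored by
the extended Bayesian information criterion

    EBIC = −2ℓ + k·log n + 2γ·k·log(p − 1),

with k the number of nonzero neighbor coefficients and γ = 0.25 by default
(γ = 0 recovers the BIC; 0.25 is the established default for binary symptom
networks). Directed coefficients are symmetrized by the AND rule (edge kept
only when both directions are nonzero; value = mean of the two; OR rule
available by config). Thresholds are the selected intercepts.

The solver is a proximal-Newton coordinate descent written for this package
(numba-compiled): an outer IRLS loop refreshes logistic weights
w_i = p_i(1−p_i) (floored at 1e-5 to stay conditioned under separation) and
builds the weighted Gram matrix — cheap for binary predictors via per-row
nonzero lists — and an inner coordinate-descent loop solves the L1
quadratic subproblem in coefficient space with soft thresholding, so zeros
are exact. Solutions are warm-started along the path. Convergence is
declared when no coefficient moves more than `convergence_tolerance`
(default 1e-7) over a Newton step; `max_iterations` (default 1000) caps the
outer loop. The unit suite cross-checks coefficients against scikit-learn's
saga solver to ~1e-8. A hand-rolled solver was chosen because the
comparison and bootstrap machinery re-estimates networks inside every
permutation/draw — general-purpose fitters are orders of magnitude too slow
for that loop at the per-fit level.

Columns with prevalence outside [0.005, 0.995] are rejected with guidance
(pseudo-likelihood is ill-conditioned there); missing data are handled
complete-case at CSV ingestion, with the dropped-row count logged.

## Centrality, predictability, layout

* strength_i = Σ_j |ω_ij|; global strength = Σ_{i<j} |ω_ij|.
* expected influence_i = Σ_j ω_ij (negative edges keep their sign).
* closeness and betweenness use edge lengths 1/|ω_ij| (absolute value:
  field convention for signed networks). Closeness is computed within a
  node's connected component and scaled by (reachable − 1)/(p − 1) so the
  measure stays comparable across disconnected graphs; isolates score 0.
  Betweenness counts fractional shares of shortest paths (unnormalized).
  Both are validated against an exhaustive path-enumeration oracle on small
  graphs.
* Centralities are reported raw and z-standardized (the scale on which
  symptom-importance plots are usually read).
* Predictability refits each node by unpenalized logistic regression on its
  *estimated* neighborhood and reports, by default, a Brier-score R²:
  1 − Brier(model)/Brier(intercept-only), clipped to [0, 1]. A normalized
  accuracy variant — (acc − acc₀)/(1 − acc₀) against the marginal
  classifier — is provided because the literature on mixed graphical models
  uses it for categorical nodes; the choice between the two is genuinely
  ambiguous for binary symptom data, so both are exposed and the default
  honors the R² reading. Empty neighborhoods score 0.
* Layout is Fruchterman–Reingold (networkx) with |ω| as attraction weight,
  deterministic given a seed, min-max scaled to the unit box.

## Two-network comparison (NCT)

Observed statistics from networks estimated per group with a shared
estimation config:

* M = max_{ij} |ω_ij^A − ω_ij^B| (structure statistic). The name "M test"
  is used loosely in parts of the applied literature; the maximum absolute
  edge difference is the standard structure-invariance statistic and is the
  definition adopted here.
* S = |GS_A − GS_B| (global-strength statistic).

The null distribution is built by pooling respondents, reassigning group
labels uniformly at random preserving (n_A, n_B), and re-estimating both
networks per permutation — the full estimation config, EBIC selection
included, runs inside the loop (a shared-λ fast mode is deliberately not
the default). p-values use the add-one estimator
(1 + #{perm ≥ obs})/(1 + B), so they are never 0. The same permutation
draws provide local per-edge and per-node-strength two-sided p-values,
reported unadjusted. Pooled rows are put in canonical lexicographic order
before permuting, which makes p-values invariant to input row order at a
fixed seed. Permuted splits violating the prevalence band are redrawn and
counted.

Unequal groups: the larger group is subsampled without replacement to the
smaller size `repeats` times (default 5, matching the common practice for
markedly unbalanced cohorts); a full NCT runs per repeat (subsample once,
then permute — the repeat-level subsample is held fixed inside the
permutation loop); reported statistics and p-values are arithmetic means
across repeats (medians by flag), with per-repeat results retained. The
default permutation count is 2000; simulation-heavy tests run 25–200.

## Robustness

* Nonparametric edge bootstrap: rows resampled with replacement, network
  re-estimated per draw (default 2000), percentile 95% intervals per edge.
* Case-dropping subset bootstrap: for each drop proportion q in
  {0.1, …, 0.7}, `n_boot` subsets of round((1−q)n) rows are drawn without
  replacement; the Spearman correlation between subset-sample and
  full-sample node strengths is recorded (Pearson by flag; Spearman is the
  rank-retention reading of stability). Exactly identical strength vectors
  score 1 (covers degenerate, perfectly stable estimation including empty
  networks); a constant vector on one side only scores 0.
* CS coefficient: the largest q such that for every grid point q' ≤ q at
  least 95% of draws have correlation ≥ 0.70 (contiguity from the smallest
  q prevents non-monotone flukes from promoting a large q); 0 if the first
  grid point fails; 0.25 is the conventional interpretability floor.
  Stability is computed for strength by default — the index robustness
  analyses conventionally target.

## Synthetic cohorts

`plant_model` draws a sparse symmetric Ω — edge probability `density`
between blocks, `density × within_block_multiplier` within a thematic block
(up to 8 blocks by default, mirroring how sleep questionnaires cluster into
hypersomnia/insomnia/respiratory/motor/psychiatric/disturbance/behavior/
comorbidity themes); nonzero magnitudes uniform on [0.2, 1.0], 70% positive
— matching the sparse, predominantly positive texture of published symptom
networks. Thresholds are calibrated to marginal-prevalence targets
(default uniform on [0.15, 0.5]) by damped fixed-point updates
τ ← τ + 0.6·(logit(target) − logit(marginal)), tolerance 0.02, max 200
iterations; marginals are exact (full enumeration) for p ≤ 12 and Gibbs
estimates above. `exact_distribution` enumerates all 2^p states (guarded at
p ≤ 12) and is the oracle for every sampler and calibration test. Sampling
is i.i.d. from the enumerated law (p ≤ 12) or by a systematic-sweep Gibbs
chain (burn-in 1000 sweeps, thinning 10 — conservative for p ≤ 50).
Grouped scenarios draw each group from the planted model under an optional
perturbation (global or per-edge rescaling, degree-preserving rewiring) and
return the per-group ground truths. The default desk-scale scenario is
p = 20 symptoms, two groups of 69.7%/30.3% of n = 3000 — a scaled-down
mimic of a large two-group questionnaire cohort.

What the generator does *not* emulate: item wording, scale-derived
composite indicators, realistic epidemiological prevalences of specific
disorders, missingness mechanisms, or residual dependence beyond pairwise
interactions. Passing tests therefore demonstrate correctness of the
machinery under the stated generative assumptions, not clinical validity on
real questionnaires.

## Validation scales and numerical choices

The statistical acceptance tests run at deliberately modest, fixed sizes
chosen so the whole suite completes on one CPU in well under half an hour;
the pass bars were fixed before the simulations were run:

* sampler-vs-oracle agreement: p = 8, 50,000 Gibbs draws, every univariate
  and pairwise moment within 0.01;
* specificity: 10-node independent model, n = 5000, ≥ 18/20 seeds yield an
  empty network;
* recovery: p = 15, density 0.2, n = 10,000 — sensitivity and specificity
  ≥ 0.9, Spearman ≥ 0.8 on true-edge weights;
* type-I error: 100 runs × 100 permutations (p = 10, n = 500 + 500, one
  common planted model), S- and M-test rejection counts at α = .05 inside
  the exact binomial 95% interval;
* power: group B = 1.5 × group A weights, n = 1000 + 1000, 50 runs × 60
  permutations, S-test rejection in ≥ 80% of runs;
* stability: p = 10, |ω| ∈ [0.5, 1], n = 4000, n_boot = 30 — CS ≥ 0.25 in
  ≥ 9/10 seeds.

Simulation-heavy paths use a 25-value λ grid and a 1e-5 coefficient
tolerance (config `EstimationConfig(lambda_count=25,
convergence_tolerance=1e-5)`); final reported networks use the 100-value
default. Degenerate inputs: constant columns are refused; ties in EBIC
resolve to the larger λ (sparser model); equal-length shortest paths share
betweenness fractionally; EBIC-vs-BIC identity at γ = 0 is exact.

## Known limitations

* Pseudo-likelihood, not joint maximum likelihood; weights are comparable
  across groups only under a shared estimation config.
* The AND rule biases very weak edges toward exclusion (conservative).
* Predictability is computed on the same data used to select neighborhoods
  (no sample splitting), so it is mildly optimistic — consistent with
  common practice for descriptive network analyses.
* The balanced-subsampling NCT averages p-values across repeats; averaged
  p-values are valid descriptively but are not exact p-values.
* Gibbs sampling accuracy for p > 12 is checked only indirectly (via
  small-p agreement with enumeration); very strong couplings (|ω| ≫ 1)
  would need longer chains than the defaults.
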