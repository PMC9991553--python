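# Methods

This note documents the statistical machinery in `stuntmsm`: the data
model, the estimators, the synthetic cohort and its calibration, the
numerical choices, and what the simulation study does and does not
demonstrate.

## Data model

One row per child per wave, in a fixed long-format CSV dialect
(`stuntmsm.simulate.PERSON_WAVE_COLUMNS`). Waves 1–4 are exposure waves
carrying the height-for-age z-score (HAZ), the binary stunting indicator
`A_t = 1{HAZ_t < −2}`, and six time-varying household covariates `L_t`;
wave 5 carries the highest completed school grade and the binary
grade-completion outcome `Y = 1{grade ≥ 3}` (the threshold is a config
parameter; some published accounts of this design use grade 5). Baseline
covariates `V` — gender, population group, birth weight, parental
education — repeat on every row. Children enter at 24–36 months and age
24 months per wave.

HAZ values outside (−6, +6) are coded missing before classification,
mirroring WHO flag limits; the stunting cutoff is strict (`−2.00` itself
is not stunted).

## Estimators

**Stabilized IPT weights.** Denominator: pooled logistic regression of
`A_t` on wave indicators, `A_{t−1}`, `L_t` and `V`; numerator: the same
without `L_t`. Exposure history enters as the first-order lag only — a
deliberate parsimony choice at wave-level prevalences below 10 %. The
per-wave stabilized ratio uses the probability of the exposure value
actually observed, and the weight carried into the outcome model is the
within-child running product. Probabilities exactly 0/1 raise a
positivity error; values below 1e−10 are floored with a warning.
Truncation is available (`weight_diagnostics(..., truncation_percentiles=(1, 99))`)
but off by default, matching a design whose weights are well behaved.
Per-wave (unpooled) exposure models are available via
`WeightModelSpec(pooling="per_wave")`; covariates constant within a wave
(the lag at wave 1) are dropped there.

**Pooled MSM.** Weighted logistic regression of the broadcast outcome on
wave-indicator intercepts plus *current* stunting status — a single
pooled coefficient, the design's headline estimand shape — with CR0
cluster-robust (child-level) sandwich standard errors, Wald intervals on
the log-odds scale, and a normal reference for p-values. Wave dummies
rather than a continuous time term give each wave its own intercept.
CR1 (`g/(g−1)`) is available via config; with ~2 600 clusters the
difference is negligible. Unweighted comparators: the crude model
(intercepts + stunting) and a baseline-adjusted model (+ `V`), both
cluster-robust, quantify the time-dependent confounding the weights
remove.

**Multiple imputation.** Chained equations on the child-level wide
layout, so an attrited wave borrows from the child's other waves, the
baseline covariates and the outcome. Binary variables (including the
stunting indicator itself — the analysis exposure) are imputed by
Bernoulli draws from a ridge-stabilized logistic model whose coefficients
are perturbed by a posterior draw; continuous variables by Bayesian
normal-linear draws (predictive-mean matching optional). The z-score is
kept out of the chain: it is deterministically linked to the indicator,
and letting the two impute each other collapses the exposure imputation
into a thresholded linear draw with appreciable attenuation. After the
chain, missing HAZ values are back-filled from the wave's observed
within-group distribution on the side of the cutoff the imputed indicator
dictates, purely so completed tables carry no missing fields. Defaults:
m = 5 imputations, 10 cycles, visit order of increasing missingness.
Per-imputation MSM log-odds ratios and squared robust SEs are combined by
Rubin's rules (`T = W + (1 + 1/m)B`) with Barnard–Rubin small-sample
degrees of freedom and a t reference. Pooling is done on the log-OR
scale, where the estimator is closest to normal.

**Complete-case path.** Drops any child with a missing analysis variable
at the scenario's exposure waves or a missing outcome, then reruns the
full weighting + MSM pipeline on the survivors.

## Synthetic cohort and calibration

The generator emulates the causal structure that motivates the MSM:

* `V` drawn from the published baseline profile (50.5 % male, 83.8 %
  African, birth weight 3.1 ± 0.6 kg, parental education 10.3 ± 2.8 y).
* `L_t` evolves with persistence; log per-capita income drifts upward
  (7.7 → 8.4 log-Rand over four waves) and, like illness, loads on the
  *lagged stunting indicator* — the confounder–mediator feedback.
* Stunting follows a first-order logistic process in `A_{t−1}` (logit
  coefficient 5.0 — see below), current `L_t` and `V`. HAZ is
  reconstructed from the same latent logistic draw through a monotone,
  wave-specific piecewise-linear map, so `HAZ < −2 ⟺ A_t = 1` exactly
  and the weight-model family is correctly specified by construction.
  The wave intercepts are calibrated by root-finding on a large forward
  pass so marginal prevalence tracks 28.2 % → 19 % → 13 % → 8.6 % (the
  two interior values interpolate the published endpoints).
* `Y` is drawn once per child from a structural logit carrying the
  stunting effect through an "ever stunted within the effect window"
  indicator plus loadings on income, illness, co-residence and household
  size. Baseline covariates get zero direct outcome loadings by default:
  with `V` in the weight numerator and a `V`-free MSM — the design being
  mirrored — direct `V → Y` effects would sit outside what the weights
  adjust. `V` still drives exposure, reproducing the published baseline
  contrasts (stunted children more often male, lighter at birth, poorer).

**The causal truth** of a configuration is *defined* by Monte-Carlo
g-computation: simulate large cohorts under the static regimes "stunted
at every window wave" and "never stunted" (covariate feedback and the
waves outside the window evolving naturally) and take the ratio of
marginal outcome odds. This is a total effect: mediated paths through
`L` are part of it, so a zero structural coefficient with active feedback
is *not* a null configuration. `calibrate_effect` bisects the structural
coefficient against this oracle; the shipped defaults hit OR 0.78
(all-waves window) and 0.71 (early-only window) to within ±0.005.

**Estimand alignment.** A pooled current-status MSM estimates, at each
wave, the marginal contrast between currently-stunted and
currently-not-stunted regimes; this coincides with the always-vs-never
contrast only to the extent that current status determines window
exposure. Two generator properties close the gap: high persistence
(onset after the entry wave is rare — consistent with stunting onset
peaking by age 2–3 in cohorts recruited at 24–36 months) makes
`A_t = 1` nearly imply "ever stunted", and the entry wave, where the
correspondence is exact, carries the largest exposure variance and hence
the most weight in the pooled fit. A residual gap of about +0.013 on the
log-OR (toward the null, ~0.01 on the OR scale; measured by fitting one
150 000-child cohort) remains — it is inherent to summarizing a
window-length effect with a single current-status coefficient, not an
implementation artefact. The 200-replicate recovery runs land within
0.02 of the calibrated ORs with 94–95 % CI coverage.

**Missingness.** Wave-level attrition at the published per-wave rates
(67/454/374/366/438 of 2 629), with probabilities tilted by observed
quantities only — baseline income, urban residence, birth weight and the
previous wave's stunting status where observed — so the mechanism is MAR
by construction. Item-level rates (2–4 %) knock out individual fields,
tilted by observed income. Attrition blanks all of a wave's measured
variables but keeps `V` (recorded once at entry).

## Problem sizes

Recovery experiments use 200 replicates of n = 2 618 children (the
analysis sample size of the cohort being emulated) with oracle runs of
4–6 × 10⁵ children; generator-calibration checks average 50 replicates;
the MI-vs-complete-case study uses 100 replicates with m = 5 and 10
cycles. One full cohort generates and fits in well under a second; a
complete MI replicate takes a few seconds.

## Numerical choices

* IRLS with step-halving (monotone deviance), convergence at relative
  deviance change < 1e−8, cap 50 iterations. Plain Newton diverges from
  the null start when coefficients are large (the persistence term), so
  the damping is load-bearing.
* Separation: constant outcomes are rejected up front; a saturated
  likelihood (deviance ≈ 0 on a binary outcome) or coefficients beyond
  1e3 raise `SeparationError`. Fractional outcomes (used when refitting
  on fitted probabilities, and in imputation models) are exempt from the
  saturation check.
* Rank deficiency is reported with the offending columns via pivoted QR.
* Imputation models add an L2 penalty of 1e−4 and stop at step norm
  1e−4 with warm starts across cycles — their precision is dominated by
  the posterior-draw noise that proper imputation requires.
* The cluster sandwich is CR0: `B⁻¹ (Σ_c s_c s_cᵀ) B⁻¹` with `B` the
  observed information at the weighted MLE; it equals HC0 under
  singleton clusters and matches the reference implementation to 1e−8.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in the configs; identical config + seed reproduces tables byte for
  byte.

## What the simulations do and do not show

The generator reproduces the published *marginals* (prevalence decline,
baseline covariate profile, attrition pattern) and the *causal
structure* (time-varying confounding with feedback), and the weight
model is correctly specified by construction. Passing recovery therefore
demonstrates that the estimator chain is implemented correctly and
behaves as MSM theory predicts under its assumptions — it does not
validate those assumptions for any real cohort. Real survey data add
survey design (stratification, clustering, panel weights), measurement
error in anthropometry, possibly MNAR attrition, and unmeasured
confounding, none of which are modelled here. The complete-case
comparison shows the qualitative pattern expected under covariate-driven
MAR (pooled-MI estimates track the full-data analysis; complete-case
intervals are markedly wider); magnitudes depend on the assumed MAR
loadings, which the published record does not pin down.

Other known limitations: exposure history is summarized by a first-order
lag; the MSM carries a single pooled exposure coefficient by default (a
cumulative-dose parameterization is available via
`MarginalStructuralModel(..., exposure="cumulative")` but is not what the
calibration targets); bootstrap confidence intervals and
censoring/attrition weights (IPCW) are not implemented — missingness is
handled by imputation, matching the design being emulated.
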