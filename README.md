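# stuntmsm

Marginal structural models (MSM) for the effect of **time-varying childhood
stunting** on **primary-school grade completion**, with a calibrated
longitudinal cohort simulator and a g-computation causal oracle.

## The problem

Stunting (height-for-age z-score below −2) both shapes and is shaped by a
child's household circumstances: low income and illness make stunting more
likely, and prior stunting in turn depresses income trajectories and raises
illness risk. Covariates like these are simultaneously *confounders* of
later stunting and *mediators* of earlier stunting, so a conventional
regression that adjusts for them is biased either way. The standard remedy
is a marginal structural model estimated with stabilized
inverse-probability-of-treatment (IPT) weights:

1. at every person-wave, fit a logistic model for current stunting
   `A_t` given the previous status `A_{t−1}`, the current time-varying
   covariates `L_t` (household income, illness, co-residence, household
   size, urban residence, grant receipt) and baseline covariates `V`
   (gender, population group, birth weight, parental education); the
   stabilized weight is

   `SW_i = ∏_t  P(A_t = a_it | A_{t−1}, V) / P(A_t = a_it | A_{t−1}, L_t, V)`

2. fit a **weighted pooled logistic regression** of the terminal
   grade-completion outcome `Y` on wave intercepts and current stunting,
   with standard errors clustered on the child. `exp(β_stunting)` is the
   marginal odds ratio comparing the always-stunted with the never-stunted
   regime.

The cohort this design targets (≈2 600 South African children followed
from age 2–3 across five biennial survey waves) is access-restricted, so
the package ships a **synthetic cohort generator** calibrated to the
published marginals — stunting prevalence declining from 28.2 % at wave 1
to 8.6 % at wave 4, mean birth weight 3.1 kg, 50.5 % male, 83.8 % African,
per-wave attrition of 67/454/374/366/438 children out of 2 629 — together
with a brute-force Monte-Carlo **g-computation oracle** that computes the
true marginal causal odds ratio implied by any generator configuration.
The default configurations are calibrated so that truth equals the two
headline scenarios: OR 0.78 for a stunting effect acting across all
exposure waves ("Model A") and OR 0.71 for an effect confined to early
childhood ("Model B").

Also included: MAR item missingness and wave attrition, multiple
imputation by chained equations with Rubin's-rules pooling, a
complete-case sensitivity path, covariate-balance / positivity / weight
diagnostics, and a CLI.

## Worked example

```python
from stuntmsm import default_config, generate_cohort, build_analysis_table
from stuntmsm.pipeline import fit_scenario

cfg = default_config().replace(seed=1)          # calibrated Model-A truth
table, truth = generate_cohort(cfg)             # 2618 children x 5 waves
print(truth.true_marginal_or)                   # 0.781  (g-computation)

analysis = build_analysis_table(table)          # long table, lag + outcome
res = fit_scenario(analysis, "all_waves")       # weights + three models
print(res["weight_diagnostics"])
print(res["msm"].summary())
print(res["adjusted"].summary())
```

prints (numbers from the run above):

```
truth OR 0.781, wave prevalences [0.285, 0.198, 0.132, 0.088]
weights: mean 0.9973 sd 0.2363 min 0.152 max 4.335
MSM (IPT-weighted) pooled logistic, scenario=all_waves
OR = 0.796 (95% CI 0.642, 0.987), p = 0.0375  [cluster-robust]
unweighted, adjusted pooled logistic, scenario=all_waves
OR = 0.620 (95% CI 0.504, 0.763), p = 0.0000  [cluster-robust]
```

Read it as: the stabilized weights average ≈1 (no positivity or
specification alarm); the weighted MSM estimate (0.80) sits close to the
simulated causal truth (0.78), while the conventional covariate-adjusted
regression (0.62) overstates the harm because it conditions on mediators —
exactly the time-dependent-confounding phenomenon the MSM exists to fix.

The same pipeline is scriptable from the shell:

```bash
stuntmsm simulate --seed 1 --out cohort.csv           # + cohort.truth.json
stuntmsm derive   --in cohort.csv --scenario all_waves --out analysis.csv
stuntmsm weights  --in analysis.csv --out weighted.csv
stuntmsm fit      --in weighted.csv --scenario all_waves --out results.json
stuntmsm report   --seed 1 --out run/                 # full grid, manifest
stuntmsm recover  --replicates 200 --scenario all_waves   # bias/coverage
stuntmsm impute-fit --in incomplete.csv --m 5 --seed 1    # MICE + pooling
```

## Layout

| module | contents |
| --- | --- |
| `stuntmsm.simulate` | generator config, cohort simulation, g-computation oracle, effect/prevalence calibration, MAR missingness |
| `stuntmsm.derive` | HAZ cleaning, stunting classification, outcome derivation, scenario analysis table |
| `stuntmsm.weights` | exposure models, stabilized weights, diagnostics, positivity, balance |
| `stuntmsm.estimation` | IRLS weighted logistic core, cluster-robust sandwich, `MarginalStructuralModel` / `MSMResult` |
| `stuntmsm.missing` | chained-equation imputation, Rubin pooling, complete-case filter |
| `stuntmsm.pipeline` | orchestration, descriptive tables, replicate recovery experiments |
| `stuntmsm.cli` | `stuntmsm` command-line entry points |

See `docs/methods.md` for the model, the calibration procedure, the
estimand discussion and known limitations.
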