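"""Synthetic longitudinal cohort generator with a g-computation causal oracle.

Emulates a panel of South African children followed over four biennial
exposure waves plus a terminal schooling wave: time-invariant baseline
covariates ``V`` (gender, population group, birth weight, parental
education), time-varying household covariates ``L_t`` (co-residence with
both parents, household size, illness, urban residence, log per-capita
income, child-support-grant receipt), a binary stunting exposure ``A_t``
derived from a height-for-age z-score (HAZ < -2), and a binary
grade-completion outcome ``Y`` observed once at the final wave.

The causal structure is the one that motivates marginal structural
modelling: each ``L_t`` both predicts subsequent stunting and is itself
affected by prior stunting (confounder-mediator duality), so conventional
regression adjustment for ``L`` is biased while inverse-probability-of-
treatment weighting is not.

Two design choices matter for interpretation:

* Stunting status follows a first-order logistic process in the lagged
  stunting indicator, the current time-varying covariates and the baseline
  covariates.  The HAZ value is reconstructed from the same latent logistic
  draw through a monotone, wave-specific piecewise-linear map, so
  ``haz < -2`` holds exactly when the child is stunted and the exposure
  model used for the stabilized weights is correctly specified by
  construction.
* The outcome's structural logit carries the stunting effect through an
  "ever stunted within the effect window" indicator.  Persistence of
  stunting is high (onset after the baseline wave is rare), mirroring
  cohorts recruited at ages 2-3 where stunting incidence has already
  peaked; this also makes the pooled current-status MSM estimand coincide
  with the always-versus-never g-computation contrast.

The marginal causal odds ratio implied by a configuration is *defined* by
Monte-Carlo g-computation over the two static regimes "stunted at every
window wave" and "never stunted" (:func:`true_marginal_or`), and
:func:`calibrate_effect` tunes the structural effect so that this marginal
odds ratio matches a requested target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ALL_WAVES",
    "EARLY_ONLY",
    "ConfigError",
    "BaselineParams",
    "StuntingProcess",
    "ConfounderProcess",
    "OutcomeParams",
    "MissingnessConfig",
    "GeneratorConfig",
    "SimulationTruth",
    "generate_cohort",
    "true_marginal_or",
    "calibrate_effect",
    "calibrate_prevalence",
    "apply_missingness",
    "default_config",
]

ALL_WAVES = "all_waves"
EARLY_ONLY = "early_only"

#: fixed column order of the long-format person-wave CSV contract
PERSON_WAVE_COLUMNS = [
    "child_id",
    "wave",
    "age_months",
    "haz",
    "stunted",
    "male",
    "african",
    "birthweight_kg",
    "parental_edu_years",
    "lives_with_both_parents",
    "household_size",
    "any_illness",
    "urban",
    "log_pc_income",
    "grant_receipt",
    "highest_grade_completed",
    "grade_outcome",
]

#: time-varying covariate columns (the L block)
TIME_VARYING_COLUMNS = [
    "lives_with_both_parents",
    "household_size",
    "any_illness",
    "urban",
    "log_pc_income",
    "grant_receipt",
]

#: baseline covariate columns (the V block)
BASELINE_COLUMNS = ["male", "african", "birthweight_kg", "parental_edu_years"]


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class BaselineParams:
    """Distribution of the time-invariant baseline covariates.

    Defaults reproduce the cohort's printed baseline profile: 50.5% male,
    83.8% African, birth weight 3.1 (0.6) kg, parental education 10.3
    (2.8) years.
    """

    prob_male: float = 0.505
    prob_african: float = 0.838
    birthweight_mean_kg: float = 3.1
    birthweight_sd_kg: float = 0.6
    parental_edu_mean_years: float = 10.3
    parental_edu_sd_years: float = 2.8

    def validate(self) -> None:
        for name in ("prob_male", "prob_african"):
            _require(0.0 <= getattr(self, name) <= 1.0, f"baseline_params.{name}",
                     "probability must be in [0, 1]")
        for name in ("birthweight_sd_kg", "parental_edu_sd_years"):
            _require(getattr(self, name) > 0, f"baseline_params.{name}",
                     "standard deviation must be > 0")


@dataclass(frozen=True)
class StuntingProcess:
    """Stunting exposure process and HAZ reconstruction.

    The per-wave stunting probability is ``expit(wave_intercepts[t] +
    persistence * A_{t-1} + loadings . (L_t, V))``.  ``wave_intercepts``
    defaults are calibrated so the marginal prevalence declines from 28.2%
    at wave 1 to 8.6% at wave 4.  ``haz_scale_stunted`` and
    ``haz_scales_recovered`` set the spread of the reconstructed HAZ on
    either side of the -2 threshold; they are cosmetic (only the side of
    the threshold enters the analysis) but keep the HAZ marginals at
    plausible levels for this population.
    """

    wave_intercepts: tuple[float, ...] = (-1.1788, -4.6547, -4.6781, -4.8431)
    persistence: float = 5.0
    loading_log_pc_income: float = -0.55
    loading_any_illness: float = 0.55
    loading_household_size: float = 0.03
    loading_birthweight: float = -0.55
    loading_parental_edu: float = -0.05
    loading_male: float = 0.20
    haz_scale_stunted: float = 0.50
    haz_scales_recovered: tuple[float, ...] = (0.70, 0.45, 0.35, 0.30)

    def validate(self, n_waves: int) -> None:
        _require(len(self.wave_intercepts) == n_waves,
                 "haz_process.wave_intercepts",
                 f"needs one intercept per exposure wave ({n_waves})")
        _require(len(self.haz_scales_recovered) == n_waves,
                 "haz_process.haz_scales_recovered",
                 f"needs one scale per exposure wave ({n_waves})")
        _require(self.haz_scale_stunted > 0, "haz_process.haz_scale_stunted",
                 "must be > 0")
        _require(all(s > 0 for s in self.haz_scales_recovered),
                 "haz_process.haz_scales_recovered", "must be > 0")


@dataclass(frozen=True)
class ConfounderProcess:
    """Evolution of the time-varying covariates.

    Every covariate depends on its own lag, and income and illness load on
    the *lagged stunting indicator* — the feedback that gives the
    covariates their dual confounder/mediator role.  Income drifts upward
    by ``income_drift`` per wave (log Rand), reproducing the printed rise
    from 7.7 at baseline to 8.4 at wave 4.
    """

    income_baseline_mean: float = 7.7
    income_baseline_sd: float = 0.75
    income_loading_urban: float = 0.35
    income_loading_parental_edu: float = 0.06
    income_drift: float = 0.233
    income_step_sd: float = 0.35
    income_on_prior_stunting: float = -0.05
    illness_baseline_rate: float = 0.08
    illness_base_logit: float = -2.586
    illness_on_prior_stunting: float = 0.40
    urban_baseline_rate: float = 0.35
    urban_loading_nonafrican: float = 0.25
    urban_switch_prob: float = 0.04
    parents_baseline_logit: float = -0.60
    parents_loading_income: float = 0.25
    parents_step_logit: float = -0.70
    parents_persistence: float = 2.2
    household_size_mean: float = 6.0
    household_size_sd: float = 2.2
    household_size_drift: float = -0.1
    household_size_step_sd: float = 0.7
    grant_base_logit: float = 1.0
    grant_loading_income: float = -0.5

    def validate(self) -> None:
        for name in ("illness_baseline_rate", "urban_baseline_rate",
                     "urban_switch_prob"):
            _require(0.0 <= getattr(self, name) <= 1.0,
                     f"confounder_process.{name}", "rate must be in [0, 1]")
        for name in ("income_baseline_sd", "income_step_sd",
                     "household_size_sd", "household_size_step_sd"):
            _require(getattr(self, name) > 0, f"confounder_process.{name}",
                     "standard deviation must be > 0")


@dataclass(frozen=True)
class OutcomeParams:
    """Structural model for the terminal grade-completion outcome.

    ``logit P(Y=1) = intercept + exposure_effect_logit * ever_stunted(window)
    + loadings . (V, summaries of L)``.  ``effect_window`` selects whether
    the window covers all exposure waves or only the first two (early
    childhood).  The default ``exposure_effect_logit`` values are the ones
    produced by :func:`calibrate_effect` against the marginal odds-ratio
    targets 0.78 (all waves) and 0.71 (early only); regenerate them with
    ``scripts/`` tooling if the process parameters change.
    """

    intercept: float = 1.5
    exposure_effect_logit: float = -0.1875
    effect_window: str = ALL_WAVES
    loading_income_mean: float = 0.45
    loading_any_illness_ever: float = -0.45
    loading_both_parents_baseline: float = 0.25
    loading_household_size_mean: float = -0.04
    loading_male: float = 0.0
    loading_african: float = 0.0
    loading_birthweight: float = 0.0
    loading_parental_edu: float = 0.0
    grade_threshold: int = 3

    def validate(self) -> None:
        _require(self.effect_window in (ALL_WAVES, EARLY_ONLY),
                 "outcome_params.effect_window",
                 f"must be '{ALL_WAVES}' or '{EARLY_ONLY}'")
        _require(self.grade_threshold >= 0, "outcome_params.grade_threshold",
                 "must be >= 0")


@dataclass(frozen=True)
class MissingnessConfig:
    """Item-level MAR missingness and whole-wave attrition.

    ``wave_attrition_rates`` defaults are the study's per-wave losses
    (67, 454, 374, 366, 438 of 2629 children for waves 1-5).  Attrition
    probability is tilted by *observed* quantities only — baseline
    covariates and the previous wave's stunting status where observed —
    keeping the mechanism missing-at-random.
    """

    item_rates: Mapping[str, float] = field(default_factory=lambda: {
        "haz": 0.03,
        "log_pc_income": 0.04,
        "any_illness": 0.02,
        "lives_with_both_parents": 0.02,
    })
    wave_attrition_rates: tuple[float, ...] = (
        67 / 2629, 454 / 2629, 374 / 2629, 366 / 2629, 438 / 2629)
    mar_on_prior_stunting: float = 0.5
    mar_on_income: float = -0.3
    mar_on_urban: float = -0.2
    mar_on_birthweight: float = -0.1
    item_mar_on_income: float = -0.2

    def validate(self) -> None:
        for k, v in self.item_rates.items():
            _require(0.0 <= v <= 1.0, f"missingness.item_rates[{k}]",
                     "rate must be in [0, 1]")
        _require(all(0.0 <= r <= 1.0 for r in self.wave_attrition_rates),
                 "missingness.wave_attrition_rates", "rates must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic cohort generator."""

    n_children: int = 2618
    n_exposure_waves: int = 4
    seed: int = 0
    baseline_params: BaselineParams = field(default_factory=BaselineParams)
    haz_process: StuntingProcess = field(default_factory=StuntingProcess)
    confounder_process: ConfounderProcess = field(default_factory=ConfounderProcess)
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)

    def validate(self) -> None:
        _require(self.n_children >= 1, "n_children", "must be >= 1")
        _require(self.n_exposure_waves >= 1, "n_exposure_waves", "must be >= 1")
        if self.outcome_params.effect_window == EARLY_ONLY:
            _require(self.n_exposure_waves >= 2, "n_exposure_waves",
                     "early_only window needs at least 2 exposure waves")
        self.baseline_params.validate()
        self.haz_process.validate(self.n_exposure_waves)
        self.confounder_process.validate()
        self.outcome_params.validate()
        self.missingness.validate()

    @property
    def window_length(self) -> int:
        if self.outcome_params.effect_window == EARLY_ONLY:
            return 2
        return self.n_exposure_waves

    def replace(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with top-level fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationTruth:
    """Ledger of the causal truth implied by a configuration.

    ``true_marginal_or`` is the Monte-Carlo g-computation estimate of the
    marginal odds ratio comparing "always stunted in the effect window"
    with "never stunted"; ``true_conditional_logit_effect`` is the
    structural (conditional) log-odds coefficient, which differs from the
    log marginal odds ratio because the odds ratio is non-collapsible.
    """

    true_marginal_or: float
    true_conditional_logit_effect: float
    exposure_prevalence_by_wave: tuple[float, ...]

    def __post_init__(self):
        if not self.true_marginal_or > 0:
            raise ValueError("true_marginal_or must be > 0")
        if not all(0.0 <= p <= 1.0 for p in self.exposure_prevalence_by_wave):
            raise ValueError("exposure prevalences must be in [0, 1]")


def default_config(scenario: str = ALL_WAVES, **kwargs) -> GeneratorConfig:
    """Default calibrated configuration for one of the two scenarios.

    ``all_waves`` targets a marginal causal OR of 0.78 (stunting effect
    from early to late childhood); ``early_only`` targets 0.71 (effect
    confined to the first two waves).
    """
    if scenario == ALL_WAVES:
        out = OutcomeParams()
    elif scenario == EARLY_ONLY:
        out = OutcomeParams(exposure_effect_logit=-0.2930,
                            effect_window=EARLY_ONLY)
    else:
        raise ConfigError(f"effect_window: unknown scenario '{scenario}'")
    return GeneratorConfig(outcome_params=out, **kwargs)


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _simulate(config: GeneratorConfig, n: int, rng: np.random.Generator,
              regime: int | None = None) -> dict[str, np.ndarray]:
    """Simulate n children; returns arrays keyed by variable.

    Time-varying arrays have shape (n, T).  ``regime`` fixes the exposure
    at every *window* wave to 0 or 1 (static intervention for the
    g-computation oracle); waves outside the window evolve naturally.
    """
    bp = config.baseline_params
    sp = config.haz_process
    cp = config.confounder_process
    op = config.outcome_params
    T = config.n_exposure_waves
    window = config.window_length

    male = (rng.random(n) < bp.prob_male).astype(float)
    african = (rng.random(n) < bp.prob_african).astype(float)
    bw = rng.normal(bp.birthweight_mean_kg, bp.birthweight_sd_kg, n)
    pedu = rng.normal(bp.parental_edu_mean_years, bp.parental_edu_sd_years, n)
    age1 = rng.integers(24, 37, n).astype(float)

    inc = np.empty((n, T)); ill = np.empty((n, T)); urb = np.empty((n, T))
    par = np.empty((n, T)); hs = np.empty((n, T)); grant = np.empty((n, T))
    haz = np.empty((n, T)); A = np.empty((n, T))

    for t in range(T):
        a_prev = A[:, t - 1] if t > 0 else np.zeros(n)
        if t == 0:
            p_urb = np.clip(cp.urban_baseline_rate
                            + cp.urban_loading_nonafrican * (1 - african), 0, 1)
            urb[:, 0] = (rng.random(n) < p_urb).astype(float)
            inc[:, 0] = (cp.income_baseline_mean
                         + cp.income_loading_urban * (urb[:, 0] - 0.5)
                         + cp.income_loading_parental_edu
                         * (pedu - bp.parental_edu_mean_years)
                         + rng.normal(0, cp.income_baseline_sd, n))
            ill[:, 0] = (rng.random(n) < cp.illness_baseline_rate).astype(float)
            par[:, 0] = (rng.random(n) < expit(
                cp.parents_baseline_logit + cp.parents_loading_income
                * (inc[:, 0] - cp.income_baseline_mean))).astype(float)
            hs[:, 0] = np.clip(np.round(rng.normal(
                cp.household_size_mean, cp.household_size_sd, n)), 2, 15)
        else:
            switch = rng.random(n) < cp.urban_switch_prob
            urb[:, t] = np.where(switch, 1.0, urb[:, t - 1])
            inc[:, t] = (inc[:, t - 1] + cp.income_drift
                         + cp.income_on_prior_stunting * a_prev
                         + rng.normal(0, cp.income_step_sd, n))
            ill[:, t] = (rng.random(n) < expit(
                cp.illness_base_logit
                + cp.illness_on_prior_stunting * a_prev)).astype(float)
            par[:, t] = (rng.random(n) < expit(
                cp.parents_step_logit
                + cp.parents_loading_income * (inc[:, t] - cp.income_baseline_mean)
                + cp.parents_persistence * par[:, t - 1])).astype(float)
            hs[:, t] = np.clip(hs[:, t - 1] + np.round(rng.normal(
                cp.household_size_drift, cp.household_size_step_sd, n)), 2, 15)
        grant[:, t] = (rng.random(n) < expit(
            cp.grant_base_logit + cp.grant_loading_income
            * (inc[:, t] - cp.income_baseline_mean))).astype(float)

        lp = (sp.wave_intercepts[t]
              + sp.persistence * a_prev
              + sp.loading_log_pc_income * (inc[:, t] - cp.income_baseline_mean)
              + sp.loading_any_illness * ill[:, t]
              + sp.loading_household_size * (hs[:, t] - cp.household_size_mean)
              + sp.loading_birthweight * (bw - bp.birthweight_mean_kg)
              + sp.loading_parental_edu * (pedu - bp.parental_edu_mean_years)
              + sp.loading_male * male)
        eps = rng.logistic(0.0, 1.0, n)
        A[:, t] = (eps < lp).astype(float)
        # HAZ shares the latent draw: haz < -2 exactly when stunted; the
        # clip keeps rare logistic tails inside the biological flag limits
        latent = lp - eps
        scale = np.where(latent > 0, sp.haz_scale_stunted,
                         sp.haz_scales_recovered[t])
        haz[:, t] = np.clip(-2.0 - scale * latent, -5.95, 5.95)
        if regime is not None and t < window:
            A[:, t] = float(regime)

    ever = A[:, :window].max(axis=1)
    lin = (op.intercept
           + op.exposure_effect_logit * ever
           + op.loading_income_mean * (inc.mean(axis=1) - cp.income_baseline_mean)
           + op.loading_any_illness_ever * ill.max(axis=1)
           + op.loading_both_parents_baseline * par[:, 0]
           + op.loading_household_size_mean * (hs.mean(axis=1) - cp.household_size_mean)
           + op.loading_male * male
           + op.loading_african * african
           + op.loading_birthweight * (bw - bp.birthweight_mean_kg)
           + op.loading_parental_edu * (pedu - bp.parental_edu_mean_years))
    Y = (rng.random(n) < expit(lin)).astype(float)

    # integer highest grade consistent with the binary outcome
    g = op.grade_threshold
    extra = rng.binomial(5, 0.26, n).astype(float)
    below = rng.binomial(max(g - 1, 0), 0.55, n).astype(float) if g > 0 else np.zeros(n)
    grade = np.where(Y == 1, g + extra, below)

    return dict(male=male, african=african, birthweight_kg=bw,
                parental_edu_years=pedu, age1=age1,
                log_pc_income=inc, any_illness=ill, urban=urb,
                lives_with_both_parents=par, household_size=hs,
                grant_receipt=grant, haz=haz, stunted=A,
                highest_grade_completed=grade, grade_outcome=Y)


def _to_long(d: dict[str, np.ndarray], T: int) -> pd.DataFrame:
    """Assemble the fixed-column-order long-format person-wave table."""
    n = len(d["grade_outcome"])
    frames = []
    for t in range(1, T + 2):  # waves 1..T are exposure waves, T+1 is outcome
        row = {
            "child_id": np.arange(n),
            "wave": np.full(n, t),
            "age_months": d["age1"] + 24.0 * (t - 1),
        }
        if t <= T:
            row["haz"] = d["haz"][:, t - 1]
            row["stunted"] = d["stunted"][:, t - 1]
        else:
            row["haz"] = np.full(n, np.nan)
            row["stunted"] = np.full(n, np.nan)
        for c in BASELINE_COLUMNS:
            row[c] = d[c]
        for c in TIME_VARYING_COLUMNS:
            row[c] = d[c][:, t - 1] if t <= T else np.full(n, np.nan)
        if t == T + 1:
            row["highest_grade_completed"] = d["highest_grade_completed"]
            row["grade_outcome"] = d["grade_outcome"]
        else:
            row["highest_grade_completed"] = np.full(n, np.nan)
            row["grade_outcome"] = np.full(n, np.nan)
        frames.append(pd.DataFrame(row))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["child_id", "wave"], kind="mergesort").reset_index(drop=True)
    return out[PERSON_WAVE_COLUMNS]


def generate_cohort(config: GeneratorConfig,
                    compute_truth: bool = True,
                    truth_n_mc: int = 200_000,
                    truth: SimulationTruth | None = None,
                    ) -> tuple[pd.DataFrame, SimulationTruth | None]:
    """Generate a complete (no-missingness) long-format cohort.

    Returns the person-wave table and the :class:`SimulationTruth` ledger.
    The truth ledger's marginal odds ratio is filled by the g-computation
    oracle (an extra Monte-Carlo run of ``truth_n_mc`` children under each
    static regime); pass ``compute_truth=False`` or a precomputed ``truth``
    to skip that cost in replicate studies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = _simulate(config, config.n_children, rng)
    table = _to_long(d, config.n_exposure_waves)
    prev = tuple(float(p) for p in d["stunted"].mean(axis=0))
    if truth is None and compute_truth:
        or_hat = true_marginal_or(config, n_mc=truth_n_mc,
                                  seed=config.seed + 1_000_003)
        truth = SimulationTruth(
            true_marginal_or=or_hat,
            true_conditional_logit_effect=config.outcome_params.exposure_effect_logit,
            exposure_prevalence_by_wave=prev,
        )
    return table, truth


def true_marginal_or(config: GeneratorConfig, n_mc: int = 200_000,
                     seed: int = 0) -> float:
    """Monte-Carlo g-computation estimate of the true marginal causal OR.

    Simulates ``n_mc`` children under the static regime "stunted at every
    wave of the effect window" and, with common random numbers, under
    "never stunted", and returns the ratio of the marginal outcome odds.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    config.validate()
    rng1 = np.random.default_rng(seed)
    p1 = _simulate(config, n_mc, rng1, regime=1)["grade_outcome"].mean()
    rng0 = np.random.default_rng(seed)
    p0 = _simulate(config, n_mc, rng0, regime=0)["grade_outcome"].mean()
    if p0 in (0.0, 1.0) or p1 in (0.0, 1.0):
        raise ValueError("degenerate outcome distribution in g-computation")
    return float((p1 / (1 - p1)) / (p0 / (1 - p0)))


def calibrate_effect(config: GeneratorConfig, target_or: float,
                     tol: float = 0.01, n_mc: int = 300_000, seed: int = 0,
                     max_iter: int = 40) -> GeneratorConfig:
    """Tune ``exposure_effect_logit`` so the g-computation OR hits a target.

    Bisection on the structural coefficient against the Monte-Carlo
    oracle; the marginal OR is monotone in the conditional effect.
    Raises ``RuntimeError`` with the final bracket if the target is not
    reached within ``max_iter`` iterations.
    """
    if not target_or > 0:
        raise ValueError("target_or must be > 0")
    config.validate()

    def oracle(theta: float) -> float:
        cfg = config.replace(outcome_params=dataclasses.replace(
            config.outcome_params, exposure_effect_logit=theta))
        return true_marginal_or(cfg, n_mc=n_mc, seed=seed)

    lo, hi = -3.0, 3.0
    f_lo, f_hi = oracle(lo), oracle(hi)
    if not (f_lo < target_or < f_hi):
        raise RuntimeError(
            f"calibration bracket [{lo}, {hi}] -> OR [{f_lo:.4f}, {f_hi:.4f}] "
            f"does not contain target {target_or}")
    theta = 0.0
    for _ in range(max_iter):
        theta = 0.5 * (lo + hi)
        val = oracle(theta)
        if abs(val - target_or) <= 0.5 * tol:
            break
        if val > target_or:
            hi = theta
        else:
            lo = theta
    cfg = config.replace(outcome_params=dataclasses.replace(
        config.outcome_params, exposure_effect_logit=theta))
    achieved = true_marginal_or(cfg, n_mc=2 * n_mc, seed=seed + 1)
    if abs(achieved - target_or) > tol:
        raise RuntimeError(
            f"calibration did not converge: bracket [{lo:.4f}, {hi:.4f}], "
            f"achieved OR {achieved:.4f}, target {target_or}")
    return cfg


def calibrate_prevalence(config: GeneratorConfig,
                         targets: tuple[float, ...],
                         n: int = 400_000, seed: int = 12345,
                         ) -> GeneratorConfig:
    """Calibrate the per-wave exposure intercepts to marginal prevalences.

    Runs one large forward pass; at each wave the intercept is solved by
    root-finding so the simulated marginal stunting prevalence matches the
    target before the wave's exposure is drawn.  Used to produce the
    frozen defaults; sampling error at the default ``n`` is a small
    fraction of a percentage point.
    """
    config.validate()
    T = config.n_exposure_waves
    if len(targets) != T:
        raise ConfigError("haz_process.wave_intercepts: "
                          f"need {T} prevalence targets, got {len(targets)}")
    rng = np.random.default_rng(seed)
    bp, sp, cp = (config.baseline_params, config.haz_process,
                  config.confounder_process)
    # forward pass mirroring _simulate, solving each intercept in turn
    male = (rng.random(n) < bp.prob_male).astype(float)
    african = (rng.random(n) < bp.prob_african).astype(float)
    bw = rng.normal(bp.birthweight_mean_kg, bp.birthweight_sd_kg, n)
    pedu = rng.normal(bp.parental_edu_mean_years, bp.parental_edu_sd_years, n)
    inc = np.zeros(n); ill = np.zeros(n); urb = np.zeros(n)
    par = np.zeros(n); hs = np.zeros(n)
    a_prev = np.zeros(n)
    intercepts = []
    for t in range(T):
        if t == 0:
            p_urb = np.clip(cp.urban_baseline_rate
                            + cp.urban_loading_nonafrican * (1 - african), 0, 1)
            urb = (rng.random(n) < p_urb).astype(float)
            inc = (cp.income_baseline_mean
                   + cp.income_loading_urban * (urb - 0.5)
                   + cp.income_loading_parental_edu * (pedu - bp.parental_edu_mean_years)
                   + rng.normal(0, cp.income_baseline_sd, n))
            ill = (rng.random(n) < cp.illness_baseline_rate).astype(float)
            par = (rng.random(n) < expit(
                cp.parents_baseline_logit
                + cp.parents_loading_income * (inc - cp.income_baseline_mean))).astype(float)
            hs = np.clip(np.round(rng.normal(cp.household_size_mean,
                                             cp.household_size_sd, n)), 2, 15)
        else:
            switch = rng.random(n) < cp.urban_switch_prob
            urb = np.where(switch, 1.0, urb)
            inc = (inc + cp.income_drift + cp.income_on_prior_stunting * a_prev
                   + rng.normal(0, cp.income_step_sd, n))
            ill = (rng.random(n) < expit(
                cp.illness_base_logit
                + cp.illness_on_prior_stunting * a_prev)).astype(float)
            par = (rng.random(n) < expit(
                cp.parents_step_logit
                + cp.parents_loading_income * (inc - cp.income_baseline_mean)
                + cp.parents_persistence * par)).astype(float)
            hs = np.clip(hs + np.round(rng.normal(
                cp.household_size_drift, cp.household_size_step_sd, n)), 2, 15)
        core = (sp.persistence * a_prev
                + sp.loading_log_pc_income * (inc - cp.income_baseline_mean)
                + sp.loading_any_illness * ill
                + sp.loading_household_size * (hs - cp.household_size_mean)
                + sp.loading_birthweight * (bw - bp.birthweight_mean_kg)
                + sp.loading_parental_edu * (pedu - bp.parental_edu_mean_years)
                + sp.loading_male * male)
        alpha = brentq(lambda a: expit(a + core).mean() - targets[t], -20, 10)
        intercepts.append(float(alpha))
        eps = rng.logistic(0.0, 1.0, n)
        a_prev = (eps < alpha + core).astype(float)
    new_sp = dataclasses.replace(sp, wave_intercepts=tuple(intercepts))
    return config.replace(haz_process=new_sp)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def _tilted_probs(rate: float, score: np.ndarray) -> np.ndarray:
    """Per-unit missingness probabilities with marginal rate ``rate``,
    tilted multiplicatively by exp(score) and clipped to [0, 1]."""
    if rate <= 0.0:
        return np.zeros(len(score))
    if rate >= 1.0:
        return np.ones(len(score))
    w = np.exp(score - score.max())
    p = rate * w / w.mean()
    return np.clip(p, 0.0, 1.0)


def apply_missingness(table: pd.DataFrame, config: GeneratorConfig,
                      seed: int) -> pd.DataFrame:
    """Apply MAR item missingness and whole-wave attrition to a cohort.

    Attrition at wave *w* blanks every measured variable of that wave
    (baseline covariates, treated as recorded once, are kept).  Item rates
    then knock out individual fields, with probabilities tilted by the
    observed household income.  The input table is not modified.
    """
    mc = config.missingness
    mc.validate()
    rng = np.random.default_rng(seed)
    out = table.copy()
    T = config.n_exposure_waves
    n = out["child_id"].nunique()
    wide_income = out.pivot(index="child_id", columns="wave",
                            values="log_pc_income")
    wide_stunted = out.pivot(index="child_id", columns="wave", values="stunted")
    base = out[out["wave"] == 1].set_index("child_id")
    inc0 = (base["log_pc_income"]
            - config.confounder_process.income_baseline_mean).to_numpy()
    urb0 = base["urban"].to_numpy()
    bw0 = (base["birthweight_kg"]
           - config.baseline_params.birthweight_mean_kg).to_numpy()

    measured = ["haz", "stunted"] + TIME_VARYING_COLUMNS
    stunt_obs = wide_stunted.copy()  # blanked as waves attrite, so the MAR
    # score only ever uses values that remain observed
    for t, rate in enumerate(mc.wave_attrition_rates[:T + 1], start=1):
        prior_stunt = (stunt_obs[t - 1].fillna(0).to_numpy()
                       if t > 1 and (t - 1) in stunt_obs else np.zeros(n))
        score = (mc.mar_on_prior_stunting * prior_stunt
                 + mc.mar_on_income * inc0
                 + mc.mar_on_urban * urb0
                 + mc.mar_on_birthweight * bw0)
        gone = rng.random(n) < _tilted_probs(float(rate), score)
        gone_ids = base.index.to_numpy()[gone]
        mask = out["wave"].eq(t) & out["child_id"].isin(gone_ids)
        if t <= T:
            out.loc[mask, measured] = np.nan
            if t in stunt_obs:
                stunt_obs.loc[gone_ids, t] = np.nan
        else:
            out.loc[mask, ["highest_grade_completed", "grade_outcome"]] = np.nan

    for col, rate in mc.item_rates.items():
        if col not in out.columns:
            raise ConfigError(f"missingness.item_rates[{col}]: unknown column")
        rows = out["wave"] <= T
        inc_obs = out.loc[rows, "log_pc_income"].fillna(
            config.confounder_process.income_baseline_mean).to_numpy()
        score = mc.item_mar_on_income * (
            inc_obs - config.confounder_process.income_baseline_mean)
        hit = rng.random(rows.sum()) < _tilted_probs(float(rate), score)
        idx = out.index[rows][hit]
        out.loc[idx, col] = np.nan
        if col == "haz":
            out.loc[idx, "stunted"] = np.nan
    return out
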