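"""End-to-end orchestration: simulate -> derive -> (impute) -> weights ->
fit, plus descriptive tables and replicate recovery experiments."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .derive import DEFAULT_GRADE_THRESHOLD, build_analysis_table
from .estimation import MSMResult, fit_msm, fit_unweighted
from .missing import (complete_case_filter, mice_impute, pool_rubin)
from .simulate import (ALL_WAVES, EARLY_ONLY, BASELINE_COLUMNS,
                       TIME_VARYING_COLUMNS, GeneratorConfig, SimulationTruth,
                       apply_missingness, default_config, generate_cohort,
                       true_marginal_or)
from .weights import (WeightModelSpec, compute_stabilized_weights,
                      covariate_balance, fit_exposure_models,
                      positivity_check, weight_diagnostics)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "descriptives",
    "wave_summaries",
    "fit_scenario",
    "fit_scenario_multiply_imputed",
    "replicate_recovery",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``missing_data`` selects how missingness is handled once it has been
    applied: ``'none'`` (analyse the complete table), ``'mi'`` (chained
    equations + Rubin pooling) or ``'complete_case'``.
    """

    n_children: int = 2618
    seed: int = 0
    scenarios: tuple[str, ...] = (ALL_WAVES, EARLY_ONLY)
    outcome_threshold: int = DEFAULT_GRADE_THRESHOLD
    apply_missingness: bool = False
    missing_data: str = "none"
    m_imputations: int = 5
    mice_cycles: int = 10
    recovery_replicates: int = 200
    out_dir: str | None = None

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["scenarios"] = tuple(raw.get("scenarios", cls.scenarios))
        return cls(**raw)

    def validate(self) -> None:
        for s in self.scenarios:
            if s not in (ALL_WAVES, EARLY_ONLY):
                raise ValueError(f"unknown scenario '{s}'")
        if self.missing_data not in ("none", "mi", "complete_case"):
            raise ValueError("missing_data must be none|mi|complete_case")


def _msm_row(res: MSMResult, model_label: str) -> dict:
    return {"model": model_label, "scenario": res.scenario,
            "or": res.or_estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p_value}


def fit_scenario(analysis_table: pd.DataFrame, scenario: str,
                 spec: WeightModelSpec | None = None) -> dict:
    """Weights + the three pooled models for one scenario, on complete data.

    Returns weight diagnostics and MSM / unadjusted / adjusted results.
    """
    fits = fit_exposure_models(analysis_table, spec)
    wset = compute_stabilized_weights(fits, analysis_table)
    return {
        "weights": wset,
        "weight_diagnostics": weight_diagnostics(wset),
        "msm": fit_msm(analysis_table, wset, scenario=scenario),
        "unadjusted": fit_unweighted(analysis_table, "none", scenario),
        "adjusted": fit_unweighted(analysis_table, "baseline", scenario),
    }


def fit_scenario_multiply_imputed(person_table: pd.DataFrame, scenario: str,
                                  m: int = 5, cycles: int = 10, seed: int = 0,
                                  outcome_threshold: int = DEFAULT_GRADE_THRESHOLD,
                                  spec: WeightModelSpec | None = None) -> dict:
    """Impute, refit the full weighting + MSM pipeline per imputation, pool.

    Every completed dataset gets its own exposure models, weights and
    pooled logistic fits; the per-imputation log-ORs and squared robust
    SEs are combined by Rubin's rules for each of the three models.
    """
    stack = mice_impute(person_table, m=m, cycles=cycles, seed=seed,
                        grade_threshold=outcome_threshold)
    per_model: dict[str, list[tuple[float, float]]] = {
        "msm": [], "unadjusted": [], "adjusted": []}
    n_records = None
    for completed in stack.completed_tables:
        tab = build_analysis_table(completed, scenario=scenario,
                                   outcome_threshold=outcome_threshold)
        n_records = len(tab)
        res = fit_scenario(tab, scenario, spec)
        for key in per_model:
            r: MSMResult = res[key]
            per_model[key].append((r.log_or, r.log_or_se ** 2))
    k = 6  # wave dummies + stunting + intercept, order of magnitude only
    out = {"imputation_stack": stack}
    for key, pairs in per_model.items():
        est = [p[0] for p in pairs]
        var = [p[1] for p in pairs]
        out[key] = pool_rubin(est, var, df_com=(n_records - k))
    return out


def descriptives(table: pd.DataFrame, group_by: str = "stunted",
                 wave: int = 1) -> pd.DataFrame:
    """Baseline-covariate comparison by stunting status (Table-2 shape).

    Binary covariates are summarised as n (%) with a Pearson chi-square
    test, continuous ones as mean (sd) with a Welch t test.  Constant
    covariates are reported with a note instead of a test.
    """
    base = table[table["wave"] == wave]
    g = base[group_by]
    if g.dropna().nunique() < 2:
        raise ValueError(f"grouping column '{group_by}' has fewer than two "
                         "levels at the baseline wave")
    rows = []
    for c in BASELINE_COLUMNS + TIME_VARYING_COLUMNS:
        sub = base[[c, group_by]].dropna()
        x1 = sub.loc[sub[group_by] == 1, c].to_numpy(dtype=float)
        x0 = sub.loc[sub[group_by] == 0, c].to_numpy(dtype=float)
        if len(x0) == 0 or len(x1) == 0:
            raise ValueError(f"empty exposure group for covariate '{c}'")
        binary = set(np.unique(sub[c])) <= {0.0, 1.0}
        if sub[c].nunique() < 2:
            rows.append({"covariate": c, "type": "constant",
                         "group0": float(x0.mean()), "group1": float(x1.mean()),
                         "p_value": np.nan, "note": "constant; test skipped"})
            continue
        if binary:
            tab = pd.crosstab(sub[group_by], sub[c])
            chi2 = stats.chi2_contingency(tab.to_numpy())
            rows.append({"covariate": c, "type": "n (%)",
                         "group0": 100.0 * x0.mean(),
                         "group1": 100.0 * x1.mean(),
                         "p_value": float(chi2.pvalue), "note": ""})
        else:
            t = stats.ttest_ind(x1, x0, equal_var=False)
            rows.append({"covariate": c, "type": "mean (sd)",
                         "group0": float(x0.mean()), "group1": float(x1.mean()),
                         "p_value": float(t.pvalue), "note": ""})
    return pd.DataFrame(rows)


def wave_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-wave sample characteristics (Table-1 shape).

    Binary covariates as percentages, continuous ones as mean (sd), plus
    the stunting prevalence, for each exposure wave; computed over the
    non-missing records of each wave.
    """
    waves = sorted(w for w in table["wave"].unique()
                   if table.loc[table["wave"] == w, "stunted"].notna().any())
    rows = []
    for c in ["stunted"] + BASELINE_COLUMNS + TIME_VARYING_COLUMNS:
        row = {"covariate": c}
        for w in waves:
            x = table.loc[table["wave"] == w, c].dropna()
            if len(x) == 0:
                row[f"wave_{w}"] = ""
                continue
            if set(np.unique(x)) <= {0.0, 1.0}:
                row[f"wave_{w}"] = f"{100 * x.mean():.1f}%"
            else:
                row[f"wave_{w}"] = f"{x.mean():.2f} ({x.std():.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(pcfg: PipelineConfig,
                 gen_config: GeneratorConfig | None = None) -> dict:
    """Run simulate -> derive -> (missingness handling) -> weights -> fit.

    Returns a results bundle: the generated cohort and its truth ledger,
    descriptive tables, per-scenario weight diagnostics, positivity
    report and the six Table-3-shaped estimates.  Deterministic given the
    seeds; writes JSON/CSV artefacts plus a manifest when ``out_dir`` is
    set.
    """
    pcfg.validate()
    results_rows = []
    bundle: dict = {"config": pcfg, "scenarios": {}}
    truths: dict[str, SimulationTruth] = {}
    for scenario in pcfg.scenarios:
        cfg = (gen_config if gen_config is not None
               else default_config(scenario)).replace(
            n_children=pcfg.n_children, seed=pcfg.seed)
        if gen_config is not None:
            cfg = cfg.replace(outcome_params=dataclasses.replace(
                cfg.outcome_params,
                effect_window=scenario))
        table, truth = generate_cohort(cfg)
        truths[scenario] = truth
        if pcfg.apply_missingness:
            table = apply_missingness(table, cfg, seed=pcfg.seed + 17)
        sc: dict = {"truth": truth}
        if pcfg.missing_data == "mi" and pcfg.apply_missingness:
            mi = fit_scenario_multiply_imputed(
                table, scenario, m=pcfg.m_imputations, cycles=pcfg.mice_cycles,
                seed=pcfg.seed + 29, outcome_threshold=pcfg.outcome_threshold)
            sc["pooled"] = {k: mi[k] for k in ("msm", "unadjusted", "adjusted")}
            for key in ("msm", "unadjusted", "adjusted"):
                p = mi[key]
                results_rows.append({"model": key, "scenario": scenario,
                                     "or": p.or_estimate, "ci_low": p.ci_low,
                                     "ci_high": p.ci_high, "p": p.p_value})
        else:
            work = table
            if pcfg.missing_data == "complete_case" and pcfg.apply_missingness:
                work, cc_report = complete_case_filter(table, scenario)
                sc["complete_case_report"] = cc_report
            analysis = build_analysis_table(
                work, scenario=scenario,
                outcome_threshold=pcfg.outcome_threshold)
            fitres = fit_scenario(analysis, scenario)
            sc.update(fitres)
            sc["positivity"] = positivity_check(analysis, ["male", "urban"])
            sc["balance_unweighted"] = covariate_balance(analysis)
            sc["balance_weighted"] = covariate_balance(analysis, fitres["weights"])
            sc["descriptives"] = descriptives(work)
            sc["wave_summaries"] = wave_summaries(work)
            for key in ("msm", "unadjusted", "adjusted"):
                results_rows.append(_msm_row(sc[key], key))
        bundle["scenarios"][scenario] = sc
    bundle["results_table"] = pd.DataFrame(results_rows)
    if pcfg.out_dir is not None:
        _write_bundle(bundle, pcfg, truths)
    return bundle


def _write_bundle(bundle: dict, pcfg: PipelineConfig,
                  truths: dict[str, SimulationTruth]) -> None:
    out = Path(pcfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["results_table"].to_csv(out / "results_table.csv", index=False)
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(pcfg),
        "truth": {s: dataclasses.asdict(t) for s, t in truths.items()},
    }
    for scenario, sc in bundle["scenarios"].items():
        if "weight_diagnostics" in sc:
            manifest[f"weight_diagnostics_{scenario}"] = {
                k: v for k, v in sc["weight_diagnostics"].items()
                if isinstance(v, (int, float))}
        if "descriptives" in sc:
            sc["descriptives"].to_csv(
                out / f"descriptives_{scenario}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# replicate recovery experiments
# ---------------------------------------------------------------------------

def replicate_recovery(scenario: str = ALL_WAVES, n_replicates: int = 200,
                       n_children: int = 2618, seed: int = 0,
                       gen_config: GeneratorConfig | None = None,
                       truth: float | None = None,
                       truth_n_mc: int = 400_000) -> dict:
    """Repeatedly simulate and refit to measure bias and CI coverage.

    Each replicate draws a fresh cohort from the calibrated generator,
    rebuilds the analysis table, re-estimates the weights and fits the
    MSM and both unweighted comparators.  Returns per-replicate estimates
    and a summary against the g-computation truth.
    """
    cfg = gen_config if gen_config is not None else default_config(scenario)
    cfg = cfg.replace(n_children=n_children)
    if truth is None:
        truth = true_marginal_or(cfg, n_mc=truth_n_mc, seed=seed + 999_983)
    rows = []
    for r in range(n_replicates):
        rcfg = cfg.replace(seed=seed + 7919 * r)
        table, _ = generate_cohort(rcfg, compute_truth=False)
        analysis = build_analysis_table(table, scenario=scenario)
        res = fit_scenario(analysis, scenario)
        msm: MSMResult = res["msm"]
        rows.append({
            "replicate": r,
            "or_msm": msm.or_estimate,
            "ci_low": msm.ci_low, "ci_high": msm.ci_high,
            "covered": msm.ci_low <= truth <= msm.ci_high,
            "or_unadjusted": res["unadjusted"].or_estimate,
            "or_adjusted": res["adjusted"].or_estimate,
            "weight_mean": res["weight_diagnostics"]["mean"],
        })
    df = pd.DataFrame(rows)
    log_truth = np.log(truth)
    summary = {
        "scenario": scenario,
        "n_replicates": n_replicates,
        "truth_or": float(truth),
        "mean_or_msm": float(df["or_msm"].mean()),
        "mean_or_unadjusted": float(df["or_unadjusted"].mean()),
        "mean_or_adjusted": float(df["or_adjusted"].mean()),
        "coverage": float(df["covered"].mean()),
        "abs_bias_log_msm": float(
            abs(np.log(df["or_msm"]).mean() - log_truth)),
        "abs_bias_log_unadjusted": float(
            abs(np.log(df["or_unadjusted"]).mean() - log_truth)),
        "abs_bias_log_adjusted": float(
            abs(np.log(df["or_adjusted"]).mean() - log_truth)),
        "mc_se_or_msm": float(df["or_msm"].std(ddof=1)
                              / np.sqrt(n_replicates)),
        "mean_weight_mean": float(df["weight_mean"].mean()),
    }
    return {"replicates": df, "summary": summary}
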