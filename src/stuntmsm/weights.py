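"""Stabilized inverse-probability-of-treatment weights and diagnostics.

The denominator model is a pooled logistic regression of current stunting
on the previous wave's status, the current time-varying covariates, the
baseline covariates and wave indicators; the numerator model drops the
time-varying covariates.  The stabilized weight at wave *t* is the ratio
of the probabilities each model assigns to the exposure value actually
observed, and the weight carried into the outcome model is the running
product of those ratios within child.  Under correct specification the
stabilized weights average close to 1; large deviations or extreme
weights indicate positivity or specification problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import WeightedLogitResults, fit_weighted_logistic
from .simulate import BASELINE_COLUMNS, TIME_VARYING_COLUMNS

__all__ = [
    "PositivityError",
    "WeightModelSpec",
    "WeightSet",
    "fit_exposure_models",
    "compute_stabilized_weights",
    "weight_diagnostics",
    "positivity_check",
    "covariate_balance",
    "plot_weight_histogram",
]

_PROB_FLOOR = 1e-10


class PositivityError(RuntimeError):
    """An exposure model assigned probability 0 or 1 to an observed value."""


@dataclass(frozen=True)
class WeightModelSpec:
    """Covariate lists for the two exposure models.

    ``denominator_covariates`` must contain the numerator covariates, and
    both must contain the lagged exposure; wave indicators are always
    included.  ``pooling='per_wave'`` fits a separate model per wave
    instead of one pooled model with wave indicators.
    """

    denominator_covariates: tuple[str, ...] = tuple(
        ["stunted_lag"] + BASELINE_COLUMNS + TIME_VARYING_COLUMNS)
    numerator_covariates: tuple[str, ...] = tuple(
        ["stunted_lag"] + BASELINE_COLUMNS)
    pooling: str = "pooled_over_waves"

    def __post_init__(self):
        if "stunted_lag" not in self.numerator_covariates or \
                "stunted_lag" not in self.denominator_covariates:
            raise ValueError("both exposure models must include stunted_lag")
        extra = set(self.numerator_covariates) - set(self.denominator_covariates)
        if extra:
            raise ValueError(
                f"numerator covariates not in denominator model: {sorted(extra)}")
        if self.pooling not in ("pooled_over_waves", "per_wave"):
            raise ValueError("pooling must be 'pooled_over_waves' or 'per_wave'")


@dataclass
class ExposureModelFit:
    """One exposure model: a pooled fit, or one fit per wave.

    In per-wave mode each wave keeps its own covariate list, because a
    covariate can be constant within a single wave (the lagged exposure is
    identically zero at the first wave) and is then dropped there.
    """

    covariates: tuple[str, ...]
    pooling: str
    fits: dict[int | None, tuple[tuple[str, ...], WeightedLogitResults]]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Probability of being stunted for each person-wave record."""
        from .estimation import build_design
        if self.pooling == "pooled_over_waves":
            covs, res = self.fits[None]
            X, _ = build_design(table, list(covs), include_exposure=False)
            return res.predict(X)
        p = np.empty(len(table))
        for w, (covs, res) in self.fits.items():
            m = (table["wave"] == w).to_numpy()
            sub = table[m]
            X = np.column_stack(
                [np.ones(m.sum())]
                + [sub[c].to_numpy(dtype=float) for c in covs])
            p[m] = res.predict(X)
        return p


def _fit_one(table: pd.DataFrame, covariates: tuple[str, ...],
             pooling: str, label: str) -> ExposureModelFit:
    from .estimation import build_design, SeparationError, RankDeficientError
    cols = ["stunted"] + list(covariates)
    if table[cols].isna().any().any():
        bad = [c for c in cols if table[c].isna().any()]
        raise ValueError(
            f"{label} model columns contain missing values: {bad}; "
            "impute or filter to complete cases first")
    try:
        if pooling == "pooled_over_waves":
            X, names = build_design(table, list(covariates),
                                    include_exposure=False)
            res = fit_weighted_logistic(
                X, table["stunted"].to_numpy(dtype=float), exog_names=names)
            return ExposureModelFit(covariates, pooling,
                                    {None: (covariates, res)})
        fits = {}
        for w in sorted(table["wave"].unique()):
            sub = table[table["wave"] == w]
            covs = tuple(c for c in covariates if sub[c].nunique() > 1)
            X = np.column_stack(
                [np.ones(len(sub))]
                + [sub[c].to_numpy(dtype=float) for c in covs])
            res = fit_weighted_logistic(
                X, sub["stunted"].to_numpy(dtype=float),
                exog_names=["intercept"] + list(covs))
            fits[int(w)] = (covs, res)
        return ExposureModelFit(covariates, pooling, fits)
    except (SeparationError, RankDeficientError) as e:
        raise type(e)(f"{label} exposure model: {e}") from e


def fit_exposure_models(analysis_table: pd.DataFrame,
                        spec: WeightModelSpec | None = None,
                        ) -> tuple[ExposureModelFit, ExposureModelFit]:
    """Fit the numerator and denominator stunting models.

    Returns ``(numerator_fit, denominator_fit)``.  Requires a complete
    analysis table (run after imputation or the complete-case filter).
    """
    spec = spec or WeightModelSpec()
    num = _fit_one(analysis_table, spec.numerator_covariates, spec.pooling,
                   "numerator")
    den = _fit_one(analysis_table, spec.denominator_covariates, spec.pooling,
                   "denominator")
    return num, den


@dataclass
class WeightSet:
    """Per person-wave stabilized weights with their building blocks.

    ``frame`` has columns child_id, wave, p_num, p_den (probabilities of
    the observed exposure value under each model), sw_t (their ratio) and
    sw_cum (running product within child); it is aligned row-for-row with
    the analysis table the weights were computed from.
    """

    frame: pd.DataFrame = field(repr=False)

    @property
    def sw_t(self) -> np.ndarray:
        return self.frame["sw_t"].to_numpy()

    @property
    def sw_cum(self) -> np.ndarray:
        return self.frame["sw_cum"].to_numpy()

    def diagnostics(self, truncation_percentiles=None) -> dict:
        return weight_diagnostics(self, truncation_percentiles)


def compute_stabilized_weights(fits, analysis_table: pd.DataFrame) -> WeightSet:
    """Stabilized weights from fitted numerator/denominator models.

    For each record the models' stunting probabilities are converted to
    the probability of the exposure value actually observed (``p`` when
    stunted, ``1 - p`` otherwise); the stabilized weight is their ratio
    and the cumulative weight the within-child running product over waves.
    """
    num_fit, den_fit = fits
    tab = analysis_table
    a = tab["stunted"].to_numpy(dtype=float)
    out = {}
    for label, fit in (("num", num_fit), ("den", den_fit)):
        p1 = fit.predict(tab)
        if np.any(p1 <= 0.0) or np.any(p1 >= 1.0):
            raise PositivityError(
                f"{label} model assigns probability 0 or 1; positivity is "
                "violated for some covariate pattern")
        p_obs = np.where(a == 1, p1, 1.0 - p1)
        if np.any(p_obs < _PROB_FLOOR):
            warnings.warn(
                f"{label} model probabilities below {_PROB_FLOOR}; flooring "
                "before division (possible practical positivity violation)",
                RuntimeWarning, stacklevel=2)
            p_obs = np.clip(p_obs, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
        out[label] = p_obs
    sw_t = out["num"] / out["den"]
    frame = pd.DataFrame({
        "child_id": tab["child_id"].to_numpy(),
        "wave": tab["wave"].to_numpy(),
        "p_num": out["num"], "p_den": out["den"], "sw_t": sw_t,
    }, index=tab.index)
    order = frame.sort_values(["child_id", "wave"], kind="mergesort").index
    cum = frame.loc[order].groupby("child_id")["sw_t"].cumprod()
    frame["sw_cum"] = cum.reindex(frame.index)
    return WeightSet(frame)


def weight_diagnostics(weight_set: WeightSet,
                       truncation_percentiles: tuple[float, float] | None = None,
                       ) -> dict:
    """Summary statistics of the cumulative stabilized weights.

    With ``truncation_percentiles`` (e.g. ``(1, 99)``) also reports the
    share of weights outside those percentiles and returns a truncated
    copy under the ``'truncated'`` key (weights clamped to the bounds).
    """
    w = weight_set.sw_cum
    if len(w) == 0:
        raise ValueError("empty weight set")
    diag = {
        "n": int(len(w)),
        "mean": float(np.mean(w)),
        "sd": float(np.std(w, ddof=1)) if len(w) > 1 else 0.0,
        "min": float(np.min(w)),
        "max": float(np.max(w)),
    }
    if truncation_percentiles is not None:
        lo_p, hi_p = truncation_percentiles
        lo, hi = np.percentile(w, [lo_p, hi_p])
        diag["truncation_percentiles"] = (float(lo_p), float(hi_p))
        diag["truncation_bounds"] = (float(lo), float(hi))
        diag["n_outside_truncation"] = int(np.sum((w < lo) | (w > hi)))
        tf = weight_set.frame.copy()
        tf["sw_cum"] = np.clip(w, lo, hi)
        diag["truncated"] = WeightSet(tf)
    return diag


def positivity_check(analysis_table: pd.DataFrame,
                     strata_columns: list[str]) -> pd.DataFrame:
    """Exposure counts per covariate stratum, flagging empty cells.

    Strata are the cross-classification of the given categorical columns;
    a stratum is flagged when it contains no exposed or no unexposed
    person-wave records (a positivity violation in the sample).
    Continuous columns must be binned by the caller first.
    """
    if not strata_columns:
        raise ValueError("need at least one stratification column")
    for c in strata_columns:
        vals = analysis_table[c].dropna()
        if vals.nunique() > 10 or not np.allclose(vals, np.round(vals)):
            raise ValueError(
                f"column '{c}' looks continuous; bin it before stratifying")
    tab = analysis_table.dropna(subset=strata_columns + ["stunted"])
    counts = (tab.groupby(strata_columns + ["stunted"], observed=True)
              .size().unstack("stunted", fill_value=0))
    counts.columns = [f"stunted_{int(c)}" for c in counts.columns]
    for col in ("stunted_0", "stunted_1"):
        if col not in counts.columns:
            counts[col] = 0
    counts["flagged"] = (counts["stunted_0"] == 0) | (counts["stunted_1"] == 0)
    return counts.reset_index()


def covariate_balance(analysis_table: pd.DataFrame, weight_set=None,
                      covariates: list[str] | None = None) -> pd.DataFrame:
    """Standardized mean differences of covariates across exposure groups.

    Weighted SMDs use the cumulative stabilized weights; comparing them
    with the unweighted SMDs shows how much confounding the weighting
    removed in the pseudo-population.
    """
    covs = covariates or TIME_VARYING_COLUMNS
    w = np.ones(len(analysis_table)) if weight_set is None else \
        np.asarray(getattr(weight_set, "sw_cum", weight_set), dtype=float)
    a = analysis_table["stunted"].to_numpy(dtype=float)
    rows = []
    for c in covs:
        x = analysis_table[c].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(a)
        x1, w1 = x[ok & (a == 1)], w[ok & (a == 1)]
        x0, w0 = x[ok & (a == 0)], w[ok & (a == 0)]
        m1, m0 = np.average(x1, weights=w1), np.average(x0, weights=w0)
        v1 = np.average((x1 - m1) ** 2, weights=w1)
        v0 = np.average((x0 - m0) ** 2, weights=w0)
        pooled = np.sqrt(0.5 * (v1 + v0))
        rows.append({"covariate": c,
                     "smd": (m1 - m0) / pooled if pooled > 0 else 0.0})
    return pd.DataFrame(rows)


def plot_weight_histogram(weight_set: WeightSet, path=None, bins: int = 60):
    """Histogram of cumulative stabilized weights (optional figure path)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(weight_set.sw_cum, bins=bins, color="#4477aa")
    ax.axvline(1.0, color="k", lw=1, ls="--")
    ax.set_xlabel("cumulative stabilized weight")
    ax.set_ylabel("person-wave records")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
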