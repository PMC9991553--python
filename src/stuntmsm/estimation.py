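"""Weighted logistic regression with cluster-robust inference, and the
marginal structural / comparator models built on top of it.

The core fitter is iteratively reweighted least squares (IRLS) for the
binomial logit model with optional prior observation weights, which enter
the score as frequency-type multipliers — exactly what inverse-probability
weighting requires.  Robust covariances are CR0 cluster sandwiches,
``B^{-1} (sum_c s_c s_c') B^{-1}`` with ``B`` the observed information and
``s_c`` the within-cluster sum of weighted scores; with singleton clusters
this reduces to the HC0 heteroskedasticity-robust estimator.

The marginal structural model itself is a weighted *pooled* logistic
regression: one record per child per exposure wave, the terminal
grade-completion outcome broadcast to each record, wave-indicator
intercepts plus the current stunting status, and standard errors clustered
on the child.  The unweighted comparators (crude, and adjusted for
baseline covariates) quantify how much time-dependent confounding the
weighting removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ALL_WAVES, EARLY_ONLY, BASELINE_COLUMNS

__all__ = [
    "RankDeficientError",
    "SeparationError",
    "WeightedLogit",
    "WeightedLogitResults",
    "cluster_robust_cov",
    "MarginalStructuralModel",
    "MSMResult",
    "fit_weighted_logistic",
    "fit_msm",
    "fit_unweighted",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not of full column rank."""


class SeparationError(RuntimeError):
    """The likelihood is monotone (perfect or quasi-perfect separation)."""


def _check_full_rank(exog: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(exog)
    if r < exog.shape[1]:
        # identify the offending columns via pivoted QR
        from scipy.linalg import qr
        _, rmat, piv = qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rmat))
        bad = [names[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-8 * diag[0]] or [names[p] for p in piv[r:]]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {r} < {exog.shape[1]}); "
            f"collinear columns: {bad}")


class WeightedLogit:
    """Binomial logit model with prior weights.

    Parameters
    ----------
    endog : array-like
        Outcome in [0, 1]; fractional values are allowed (they arise when
        refitting on fitted probabilities, and in imputation models).
    exog : array-like, 2-d
        Design matrix including any intercept column.
    weights : array-like, optional
        Positive prior weights multiplying each observation's score
        contribution (frequency-type).
    exog_names : list of str, optional
        Column names for error messages and summaries.
    """

    def __init__(self, endog, exog, weights=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog and exog have incompatible shapes")
        if np.any((self.endog < 0) | (self.endog > 1)):
            raise ValueError("endog values must lie in [0, 1]")
        if weights is None:
            self.weights = np.ones(len(self.endog))
        else:
            self.weights = np.asarray(weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("weights must be strictly positive")
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.exog.shape[1])])
        _check_full_rank(self.exog, self.exog_names)

    def fit(self, maxiter: int = 50, tol: float = 1e-8) -> "WeightedLogitResults":
        """IRLS to convergence (relative deviance change below ``tol``)."""
        y, X, w = self.endog, self.exog, self.weights
        ymean = np.average(y, weights=w)
        if ymean <= 0.0 or ymean >= 1.0:
            raise SeparationError("outcome is constant; logit MLE does not exist")
        n, k = X.shape
        beta = np.zeros(k)
        # start from the null model intercept if one is present
        eta = np.full(n, np.log(ymean / (1 - ymean)))
        dev = self._deviance(y, _expit(eta), w)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            p = _expit(eta)
            wls = w * p * (1 - p)
            if np.max(wls) < 1e-12:
                raise SeparationError("all fitted probabilities degenerate")
            z = eta + (y - p) / np.maximum(p * (1 - p), 1e-12)
            WX = X * wls[:, None]
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
            # step-halving keeps the deviance monotone (plain Newton can
            # overshoot when coefficients are large)
            dev_new = self._deviance(y, _expit(X @ beta_new), w)
            halvings = 0
            while (not np.isfinite(dev_new) or dev_new > dev + 1e-10) \
                    and halvings < 30:
                beta_new = 0.5 * (beta + beta_new)
                dev_new = self._deviance(y, _expit(X @ beta_new), w)
                halvings += 1
            if not np.isfinite(dev_new):
                raise SeparationError("divergent deviance during IRLS")
            rel = abs(dev - dev_new) / (abs(dev_new) + 0.1)
            beta, eta, dev = beta_new, X @ beta_new, dev_new
            if rel < tol:
                converged = True
                break
        binary = bool(np.all((y == 0.0) | (y == 1.0)))
        if np.max(np.abs(beta)) > 1e3 or (binary and dev < 1e-6):
            raise SeparationError(
                "coefficients diverged or the likelihood is saturated; "
                "data are (quasi-)separated")
        p = _expit(eta)
        info = X.T @ (X * (self.weights * p * (1 - p))[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise SeparationError(f"singular information matrix: {e}") from e
        return WeightedLogitResults(self, beta, cov, p, dev, converged, it)

    @staticmethod
    def _deviance(y, p, w):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        yc = np.clip(y, 1e-12, 1 - 1e-12)
        ll = y * np.log(p) + (1 - y) * np.log(1 - p)
        sat = y * np.log(yc) + (1 - y) * np.log(1 - yc)
        return float(-2.0 * np.sum(w * (ll - sat)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


@dataclass
class WeightedLogitResults:
    """MLE of a :class:`WeightedLogit` with model-based covariance."""

    model: WeightedLogit
    params: np.ndarray
    cov_params: np.ndarray
    fittedvalues: np.ndarray
    deviance: float
    converged: bool
    iterations: int

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def n_obs(self) -> int:
        return len(self.model.endog)

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return _expit(X @ self.params)

    def summary(self) -> str:
        lines = [f"{'':<26}{'coef':>10}{'se':>10}",
                 "-" * 46]
        for name, b, s in zip(self.model.exog_names, self.params, self.bse):
            lines.append(f"{name:<26}{b:>10.4f}{s:>10.4f}")
        lines.append(f"n_obs {self.n_obs}, deviance {self.deviance:.2f}, "
                     f"converged={self.converged} ({self.iterations} it)")
        return "\n".join(lines)


def fit_weighted_logistic(design_matrix, outcome_vector, weights=None,
                          exog_names=None, **fit_kwargs) -> WeightedLogitResults:
    """Functional façade over :class:`WeightedLogit`."""
    return WeightedLogit(outcome_vector, design_matrix, weights=weights,
                         exog_names=exog_names).fit(**fit_kwargs)


def cluster_robust_cov(fit: WeightedLogitResults, cluster_ids,
                       correction: str = "cr0") -> np.ndarray:
    """CR sandwich covariance with scores summed within clusters.

    ``correction='cr0'`` is the plain sandwich; ``'cr1'`` applies the
    ``g/(g-1)`` small-sample factor.  With one observation per cluster the
    CR0 estimate equals HC0.
    """
    ids = np.asarray(cluster_ids)
    if len(ids) != fit.n_obs:
        raise ValueError("cluster_ids must have one entry per observation")
    uniq, inv = np.unique(ids, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 clusters for a cluster-robust "
                         "covariance")
    if not fit.converged:
        raise ValueError("fit did not converge; refusing robust covariance")
    X = fit.model.exog
    resid = fit.model.weights * (fit.model.endog - fit.fittedvalues)
    scores = X * resid[:, None]
    S = np.zeros((g, X.shape[1]))
    np.add.at(S, inv, scores)
    meat = S.T @ S
    if correction == "cr1":
        meat = meat * (g / (g - 1.0))
    elif correction != "cr0":
        raise ValueError(f"unknown correction '{correction}'")
    B_inv = fit.cov_params  # inverse observed information
    return B_inv @ meat @ B_inv


# ---------------------------------------------------------------------------
# pooled MSM and comparators
# ---------------------------------------------------------------------------

@dataclass
class MSMResult:
    """Odds-ratio estimate for stunting from a pooled logistic model."""

    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    log_or: float
    log_or_se: float
    scenario: str
    weighted: bool
    adjusted: str
    fit: WeightedLogitResults
    robust_cov: np.ndarray

    def __post_init__(self):
        if not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")

    def summary(self) -> str:
        kind = "MSM (IPT-weighted)" if self.weighted else (
            "unweighted, adjusted" if self.adjusted == "baseline"
            else "unweighted, unadjusted")
        return (f"{kind} pooled logistic, scenario={self.scenario}\n"
                f"OR = {self.or_estimate:.3f} "
                f"(95% CI {self.ci_low:.3f}, {self.ci_high:.3f}), "
                f"p = {self.p_value:.4f}  [cluster-robust]")


def _scenario_waves(table: pd.DataFrame, scenario: str) -> list[int]:
    waves = sorted(int(w) for w in table["wave"].unique())
    if scenario == EARLY_ONLY:
        return waves[:2]
    if scenario == ALL_WAVES:
        return waves
    raise ValueError(f"unknown scenario '{scenario}'")


def build_design(table: pd.DataFrame, columns: list[str],
                 include_exposure: bool = True) -> tuple[np.ndarray, list[str]]:
    """Intercept + wave dummies (first wave as reference) + named columns."""
    waves = sorted(int(w) for w in table["wave"].unique())
    parts = [np.ones(len(table))]
    names = ["intercept"]
    for w in waves[1:]:
        parts.append((table["wave"] == w).to_numpy(dtype=float))
        names.append(f"wave_{w}")
    if include_exposure:
        parts.append(table["stunted"].to_numpy(dtype=float))
        names.append("stunted")
    for c in columns:
        parts.append(table[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(parts), names


class MarginalStructuralModel:
    """Pooled logistic model of grade completion on current stunting.

    Build from a scenario analysis table (see
    :func:`stuntmsm.derive.build_analysis_table`); pass the cumulative
    stabilized weights for the MSM, or no weights for the conventional
    comparators.  ``fit()`` returns an :class:`MSMResult` whose Wald
    confidence interval and p-value use the child-clustered sandwich
    covariance.
    """

    def __init__(self, analysis_table: pd.DataFrame, weights=None,
                 scenario: str = ALL_WAVES, adjusted: str = "none",
                 correction: str = "cr0", exposure: str = "current"):
        if adjusted not in ("none", "baseline"):
            raise ValueError("adjusted must be 'none' or 'baseline'")
        if exposure not in ("current", "cumulative"):
            raise ValueError("exposure must be 'current' or 'cumulative'")
        waves = _scenario_waves(analysis_table, scenario)
        tab = analysis_table[analysis_table["wave"].isin(waves)].copy()
        if exposure == "cumulative":
            # running count of stunted waves up to and including t
            order = tab.sort_values(["child_id", "wave"],
                                    kind="mergesort").index
            cum = tab.loc[order].groupby("child_id")["stunted"].cumsum()
            tab["stunted"] = cum.reindex(tab.index)
        self.exposure = exposure
        cols = ["stunted", "outcome"] + (
            BASELINE_COLUMNS if adjusted == "baseline" else [])
        missing = tab[cols].isna().any(axis=1)
        if missing.any():
            raise ValueError(
                f"{int(missing.sum())} person-wave records have missing "
                "analysis values; impute or apply the complete-case filter "
                "before fitting")
        self.table = tab
        self.scenario = scenario
        self.adjusted = adjusted
        self.correction = correction
        if weights is None:
            self.weights = None
        else:
            w = np.asarray(weights, dtype=float)
            if len(w) != len(analysis_table):
                raise ValueError("weights must align with the analysis table")
            self.weights = w[analysis_table["wave"].isin(waves).to_numpy()]

    def fit(self, **fit_kwargs) -> MSMResult:
        X, names = build_design(
            self.table,
            BASELINE_COLUMNS if self.adjusted == "baseline" else [])
        y = self.table["outcome"].to_numpy(dtype=float)
        res = fit_weighted_logistic(X, y, weights=self.weights,
                                    exog_names=names, **fit_kwargs)
        rcov = cluster_robust_cov(res, self.table["child_id"].to_numpy(),
                                  correction=self.correction)
        j = names.index("stunted")
        b = float(res.params[j])
        se = float(np.sqrt(rcov[j, j]))
        zcrit = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(b) / se)
        return MSMResult(
            or_estimate=float(np.exp(b)),
            ci_low=float(np.exp(b - zcrit * se)),
            ci_high=float(np.exp(b + zcrit * se)),
            p_value=float(p),
            log_or=b, log_or_se=se,
            scenario=self.scenario,
            weighted=self.weights is not None,
            adjusted=self.adjusted,
            fit=res, robust_cov=rcov)


def fit_msm(analysis_table: pd.DataFrame, weight_set,
            scenario: str = ALL_WAVES, **kwargs) -> MSMResult:
    """IPT-weighted pooled logistic MSM for one scenario.

    ``weight_set`` is a :class:`stuntmsm.weights.WeightSet` (its cumulative
    stabilized weights are used) or a bare array aligned with the table.
    """
    w = getattr(weight_set, "sw_cum", weight_set)
    w = np.asarray(w, dtype=float)
    return MarginalStructuralModel(analysis_table, weights=w,
                                   scenario=scenario, **kwargs).fit()


def fit_unweighted(analysis_table: pd.DataFrame, adjusted: str = "none",
                   scenario: str = ALL_WAVES, **kwargs) -> MSMResult:
    """Conventional (unweighted) pooled logistic comparator.

    ``adjusted='none'`` fits wave intercepts + stunting only;
    ``'baseline'`` adds the baseline covariates.  Shown for comparison
    with the MSM to gauge the magnitude of time-dependent confounding.
    """
    return MarginalStructuralModel(analysis_table, weights=None,
                                   scenario=scenario, adjusted=adjusted,
                                   **kwargs).fit()
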