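"""Multiple imputation by chained equations and Rubin's-rules pooling.

Imputation is run on the child-level *wide* layout (one row per child,
one column per variable-wave), so that a wave lost to attrition can be
filled in from the child's other waves, the baseline covariates and the
schooling outcome.  Each incomplete variable gets an iterative regression
imputation model — logistic for binary columns, normal-linear for
continuous ones — conditioning on all other analysis variables, with
coefficients perturbed by a posterior draw before each prediction so the
imputations propagate model uncertainty.  Predictive-mean matching is
available as an alternative draw mechanism.

Pooling follows Rubin's rules on the log-odds-ratio scale: pooled point
``Q̄``, within-imputation variance ``W``, between-imputation variance
``B``, total ``T = W + (1 + 1/m) B``, with Barnard-Rubin small-sample
degrees of freedom when a complete-data df is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .derive import STUNTING_CUTOFF
from .simulate import (ALL_WAVES, EARLY_ONLY, BASELINE_COLUMNS,
                       TIME_VARYING_COLUMNS)

__all__ = [
    "ImputationStack",
    "PooledEstimate",
    "mice_impute",
    "pool_rubin",
    "complete_case_filter",
]

_RIDGE = 1e-4


@dataclass
class ImputationStack:
    """m completed person-wave tables plus the settings that made them."""

    completed_tables: list[pd.DataFrame] = field(repr=False)
    m: int = 5
    cycles: int = 10
    seed: int = 0
    variable_models: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.completed_tables) != self.m:
            raise ValueError("need exactly m completed tables")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-pooled log-odds-ratio with its odds-ratio presentation."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self):
        if self.within_var < 0 or self.between_var < 0:
            raise ValueError("variance components must be non-negative")
        if self.total_var < self.within_var - 1e-12:
            raise ValueError("total variance cannot be below within variance")
        if not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")

    def summary(self) -> str:
        return (f"pooled over m={self.m} imputations: "
                f"OR = {self.or_estimate:.3f} "
                f"(95% CI {self.ci_low:.3f}, {self.ci_high:.3f}), "
                f"p = {self.p_value:.4f}, df = {self.df:.1f}")


# ---------------------------------------------------------------------------
# chained equations
# ---------------------------------------------------------------------------

def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _ridge_logit(X, y, lam=_RIDGE, maxiter=8, start=None):
    """Ridge-stabilized logistic fit; returns (beta, covariance).

    Damped Newton with step-halving.  ``start`` warm-starts later MICE
    cycles, which then converge in a step or two; the stopping rule is
    deliberately loose — imputation models need far less precision than
    the posterior-draw noise they feed.
    """
    n, k = X.shape
    beta = np.zeros(k) if start is None else np.asarray(start, float).copy()
    lam_eye = lam * np.eye(k)

    def penloss(b):
        eta = X @ b
        # -loglik + ridge, computed stably
        return (float(np.sum(np.logaddexp(0.0, eta) - y * eta))
                + 0.5 * lam * float(b @ b))

    loss = penloss(beta)
    for _ in range(maxiter):
        p = _expit(X @ beta)
        w = np.maximum(p * (1 - p), 1e-8)
        H = X.T @ (X * w[:, None]) + lam_eye
        g = X.T @ (y - p) - lam * beta
        step = np.linalg.solve(H, g)
        if np.max(np.abs(step)) < 1e-4:
            break
        new = beta + step
        new_loss = penloss(new)
        halvings = 0
        while (not np.isfinite(new_loss) or new_loss > loss + 1e-10) \
                and halvings < 20:
            new = 0.5 * (beta + new)
            new_loss = penloss(new)
            halvings += 1
        beta, loss = new, new_loss
    p = _expit(X @ beta)
    w = np.maximum(p * (1 - p), 1e-8)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + lam_eye)
    return beta, cov


def _impute_logistic(X_obs, y_obs, X_mis, rng, start=None):
    beta, cov = _ridge_logit(X_obs, y_obs, start=start)
    draw = rng.multivariate_normal(beta, cov, method="cholesky")
    p = _expit(X_mis @ draw)
    return (rng.random(len(p)) < p).astype(float), beta


def _impute_linear(X_obs, y_obs, X_mis, rng, pmm_k: int = 0):
    n, k = X_obs.shape
    A = X_obs.T @ X_obs + _RIDGE * np.eye(k)
    beta = np.linalg.solve(A, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(A)
    draw = rng.multivariate_normal(beta, cov, method="cholesky")
    mu_mis = X_mis @ draw
    if pmm_k > 0:
        mu_obs = X_obs @ draw
        order = np.argsort(mu_obs)
        pos = np.searchsorted(mu_obs[order], mu_mis)
        out = np.empty(len(mu_mis))
        for i, p0 in enumerate(pos):
            lo = max(p0 - pmm_k, 0)
            hi = min(p0 + pmm_k, n)
            donors = order[lo:hi]
            out[i] = y_obs[donors[rng.integers(0, len(donors))]]
        return out
    return mu_mis + rng.normal(0.0, np.sqrt(sigma2), len(mu_mis))


def _wide_layout(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Child-level wide frame of analysis variables; returns (wide, T)."""
    waves = sorted(table["wave"].unique())
    T = len(waves) - 1
    base = table[table["wave"] == waves[0]].set_index("child_id")
    wide = base[BASELINE_COLUMNS].copy()
    # the z-score is deliberately left out of the chain: it is collinear
    # with the indicator it defines, and letting the two impute each other
    # degrades the exposure imputation into a thresholded linear draw
    for t in waves[:-1]:
        sub = table[table["wave"] == t].set_index("child_id")
        for c in ["stunted"] + TIME_VARYING_COLUMNS:
            wide[f"{c}_w{t}"] = sub[c]
    last = table[table["wave"] == waves[-1]].set_index("child_id")
    wide["grade_outcome"] = last["grade_outcome"]
    return wide, T


def mice_impute(table: pd.DataFrame, m: int = 5, cycles: int = 10,
                seed: int = 0, variable_models: dict[str, str] | None = None,
                method: str = "posterior", grade_threshold: int = 3,
                ) -> ImputationStack:
    """Multiply impute an incomplete person-wave table.

    Returns ``m`` completed long tables.  Binary columns — including the
    stunting indicator itself, which is the exposure the analysis model
    uses — are imputed by Bernoulli draws from a posterior-perturbed
    logistic model; continuous columns by a Bayesian normal-linear draw
    (or predictive-mean matching with ``method='pmm'``).  The imputed HAZ
    is reconciled with the imputed indicator, and an imputed outcome is
    written back as a consistent highest-grade value.  Variables are
    visited in order of increasing missingness; a column that is entirely
    missing is rejected.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if method not in ("posterior", "pmm"):
        raise ValueError("method must be 'posterior' or 'pmm'")
    wide, T = _wide_layout(table)
    frac = wide.isna().mean()
    if (frac >= 1.0).any():
        bad = list(frac.index[frac >= 1.0])
        raise ValueError(f"columns entirely missing, cannot impute: {bad}")
    targets = [c for c in wide.columns if frac[c] > 0]
    targets.sort(key=lambda c: frac[c])
    binary = {c: set(wide[c].dropna().unique()) <= {0.0, 1.0}
              for c in wide.columns}
    models = dict(variable_models or {})
    for c in targets:
        models.setdefault(c, "logistic" if binary[c] else "linear")

    rng = np.random.default_rng(seed)
    cols = list(wide.columns)
    jof = {c: j for j, c in enumerate(cols)}
    base_mat = wide.to_numpy(dtype=float)
    nrow = base_mat.shape[0]
    miss = {c: np.isnan(base_mat[:, jof[c]]) for c in targets}
    completed = []
    for _ in range(m):
        mat = base_mat.copy()
        for c in targets:  # initial fill: resample observed values
            obs = base_mat[~miss[c], jof[c]]
            mat[miss[c], jof[c]] = rng.choice(obs, size=int(miss[c].sum()))
        X = np.empty((nrow, len(cols)))  # intercept + all predictors
        X[:, 0] = 1.0
        warm: dict[str, np.ndarray] = {}
        for _cycle in range(cycles):
            for c in targets:
                j = jof[c]
                others = [jj for jj in range(len(cols)) if jj != j]
                X[:, 1:] = mat[:, others]
                y = mat[:, j]
                mis = miss[c]
                if models[c] == "logistic":
                    imp, beta = _impute_logistic(X[~mis], y[~mis], X[mis],
                                                 rng, start=warm.get(c))
                    warm[c] = beta
                else:
                    imp = _impute_linear(X[~mis], y[~mis], X[mis], rng,
                                         pmm_k=5 if method == "pmm" else 0)
                mat[mis, j] = imp
        work = pd.DataFrame(mat, index=wide.index, columns=cols)
        completed.append(_wide_to_long(table, work, T, grade_threshold, rng))
    return ImputationStack(completed_tables=completed, m=m, cycles=cycles,
                           seed=seed, variable_models=models)


def _wide_to_long(template: pd.DataFrame, wide: pd.DataFrame, T: int,
                  grade_threshold: int, rng: np.random.Generator,
                  ) -> pd.DataFrame:
    """Write imputed wide values back into a copy of the long table.

    The binary stunting indicator is the imputed analysis variable; a
    missing z-score is back-filled from the wave's observed within-group
    HAZ distribution on the side of the cutoff the indicator dictates,
    purely so completed tables carry no missing fields.
    """
    out = template.copy()
    waves = sorted(out["wave"].unique())
    for t in waves[:-1]:
        m = out["wave"] == t
        ids = out.loc[m, "child_id"].to_numpy()
        for c in ["stunted"] + TIME_VARYING_COLUMNS:
            col = f"{c}_w{t}"
            if col in wide.columns:
                out.loc[m, c] = wide.loc[ids, col].to_numpy()
        haz = out.loc[m, "haz"].to_numpy(dtype=float)
        stunted = out.loc[m, "stunted"].to_numpy(dtype=float)
        need = np.isnan(haz)
        if need.any():
            fill = np.empty(int(need.sum()))
            grp = stunted[need]
            for g in (0.0, 1.0):
                side = grp == g
                if not side.any():
                    continue
                obs = haz[(~np.isnan(haz)) & (stunted == g)]
                if len(obs) >= 2:
                    mu, sd = float(obs.mean()), float(obs.std())
                else:  # degenerate wave: fall back to cutoff-adjacent mass
                    mu, sd = (STUNTING_CUTOFF - 0.5 if g == 1.0
                              else STUNTING_CUTOFF + 0.5), 0.25
                draw = rng.normal(mu, max(sd, 1e-6), int(side.sum()))
                wrong = (draw < STUNTING_CUTOFF) != (g == 1.0)
                draw[wrong] = 2.0 * STUNTING_CUTOFF - draw[wrong]
                fill[side] = draw
            haz[need] = fill
            out.loc[m, "haz"] = haz
    m = out["wave"] == waves[-1]
    ids = out.loc[m, "child_id"].to_numpy()
    y = wide.loc[ids, "grade_outcome"].to_numpy()
    out.loc[m, "grade_outcome"] = y
    grade = out.loc[m, "highest_grade_completed"].to_numpy()
    filled = np.where(np.isnan(grade),
                      np.where(y == 1, float(grade_threshold),
                               max(grade_threshold - 1.0, 0.0)),
                      grade)
    out.loc[m, "highest_grade_completed"] = filled
    return out


# ---------------------------------------------------------------------------
# pooling and complete cases
# ---------------------------------------------------------------------------

def pool_rubin(estimates, variances, df_com: float | None = None,
               ) -> PooledEstimate:
    """Combine m log-odds-ratio estimates by Rubin's rules.

    ``estimates`` are per-imputation log-ORs and ``variances`` their
    squared standard errors.  Confidence limits use a t reference with
    the (Barnard-Rubin, when ``df_com`` is given) degrees of freedom, and
    are exponentiated to the odds-ratio scale.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    if np.any(u <= 0):
        raise ValueError("variances must be > 0")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0:
        lam = (1.0 + 1.0 / m) * b / t
        df = (m - 1) / lam ** 2
        if df_com is not None:
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
    else:
        df = float("inf") if df_com is None else float(df_com)
    se = np.sqrt(t)
    tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
    p = (2.0 * stats.t.sf(abs(qbar) / se, df) if np.isfinite(df)
         else 2.0 * stats.norm.sf(abs(qbar) / se))
    return PooledEstimate(
        point=qbar, within_var=w, between_var=b, total_var=t, df=float(df),
        m=m, or_estimate=float(np.exp(qbar)),
        ci_low=float(np.exp(qbar - tcrit * se)),
        ci_high=float(np.exp(qbar + tcrit * se)), p_value=float(p))


def complete_case_filter(table: pd.DataFrame, scenario: str = ALL_WAVES,
                         ) -> tuple[pd.DataFrame, dict]:
    """Drop children with any missing analysis variable in the scenario.

    A child is retained only if every analysis variable (exposure,
    time-varying and baseline covariates) is observed at each of the
    scenario's exposure waves *and* the outcome is observed at the final
    wave.  Returns the filtered table (all waves, retained children) and a
    retention report.
    """
    if scenario not in (ALL_WAVES, EARLY_ONLY):
        raise ValueError(f"unknown scenario '{scenario}'")
    waves = sorted(table["wave"].unique())
    exposure_waves = waves[:-1]
    if scenario == EARLY_ONLY:
        exposure_waves = exposure_waves[:2]
    cols = ["stunted"] + TIME_VARYING_COLUMNS + BASELINE_COLUMNS
    expo = table[table["wave"].isin(exposure_waves)]
    bad_expo = expo.loc[expo[cols].isna().any(axis=1), "child_id"].unique()
    last = table[table["wave"] == waves[-1]]
    bad_out = last.loc[last["grade_outcome"].isna(), "child_id"].unique()
    bad = set(bad_expo) | set(bad_out)
    keep = table[~table["child_id"].isin(bad)].copy()
    n_in = table["child_id"].nunique()
    n_keep = keep["child_id"].nunique()
    if n_keep == 0:
        raise ValueError("no complete cases remain")
    report = {"n_children_in": int(n_in), "n_children_retained": int(n_keep),
              "n_children_dropped": int(n_in - n_keep),
              "scenario": scenario}
    return keep.reset_index(drop=True), report
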