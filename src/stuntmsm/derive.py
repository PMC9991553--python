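"""Analysis-variable derivation: stunting from HAZ, the grade-completion
outcome, and the scenario analysis table with exposure-history columns."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ALL_WAVES, EARLY_ONLY

__all__ = [
    "CleaningReport",
    "clean_haz",
    "classify_stunting",
    "derive_outcome",
    "build_analysis_table",
    "DEFAULT_HAZ_BOUNDS",
    "DEFAULT_GRADE_THRESHOLD",
]

#: WHO-style biological plausibility flag limits for height-for-age z-scores
DEFAULT_HAZ_BOUNDS = (-6.0, 6.0)

#: completed Grade 3 or higher counts as on-track grade completion
DEFAULT_GRADE_THRESHOLD = 3

#: z-score threshold below which a child is classified as stunted
STUNTING_CUTOFF = -2.0


@dataclass(frozen=True)
class CleaningReport:
    """Outcome of HAZ plausibility screening."""

    n_implausible_haz: int
    n_missing_haz: int
    plausibility_bounds: tuple[float, float]

    def __post_init__(self):
        if self.n_implausible_haz < 0 or self.n_missing_haz < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.plausibility_bounds
        if not lo < hi:
            raise ValueError("plausibility bounds must satisfy low < high")


def _as_float_array(values, what: str) -> tuple[np.ndarray, bool]:
    scalar = np.isscalar(values)
    try:
        arr = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as e:
        raise TypeError(f"{what} must be numeric or missing: {e}") from e
    return np.atleast_1d(arr), scalar


def clean_haz(haz, bounds: tuple[float, float] = DEFAULT_HAZ_BOUNDS,
              report: bool = False):
    """Code biologically implausible HAZ values as missing.

    Values strictly outside ``bounds`` become NaN; in-range values pass
    through unchanged and missing values stay missing.  With
    ``report=True`` also returns a :class:`CleaningReport`.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy low < high")
    arr, scalar = _as_float_array(haz, "haz")
    implausible = (~np.isnan(arr)) & ((arr < lo) | (arr > hi))
    cleaned = np.where(implausible, np.nan, arr)
    if isinstance(haz, pd.Series):
        cleaned = pd.Series(cleaned, index=haz.index, name=haz.name)
    elif scalar:
        cleaned = float(cleaned[0])
    if report:
        rep = CleaningReport(
            n_implausible_haz=int(implausible.sum()),
            n_missing_haz=int(np.isnan(arr).sum()),
            plausibility_bounds=(float(lo), float(hi)))
        return cleaned, rep
    return cleaned


def classify_stunting(haz):
    """Binary stunting indicator: 1 iff HAZ < -2 (strict); NaN propagates."""
    arr, scalar = _as_float_array(haz, "haz")
    out = np.where(np.isnan(arr), np.nan,
                   (arr < STUNTING_CUTOFF).astype(float))
    if isinstance(haz, pd.Series):
        return pd.Series(out, index=haz.index, name="stunted")
    return float(out[0]) if scalar else out


def derive_outcome(highest_grade, threshold_grade: int = DEFAULT_GRADE_THRESHOLD):
    """Binary grade-completion outcome: 1 iff grade >= threshold.

    The default threshold is completion of Grade 3 or higher, the grade an
    on-time child entering school at age 7 has completed by the terminal
    wave.  NaN propagates; negative grades are rejected.
    """
    if threshold_grade < 0:
        raise ValueError("threshold_grade must be >= 0")
    arr, scalar = _as_float_array(highest_grade, "highest_grade")
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("highest_grade contains negative values")
    out = np.where(np.isnan(arr), np.nan,
                   (arr >= threshold_grade).astype(float))
    if isinstance(highest_grade, pd.Series):
        return pd.Series(out, index=highest_grade.index, name="grade_outcome")
    return float(out[0]) if scalar else out


def build_analysis_table(person_waves: pd.DataFrame,
                         scenario: str = ALL_WAVES,
                         outcome_threshold: int = DEFAULT_GRADE_THRESHOLD,
                         haz_bounds: tuple[float, float] = DEFAULT_HAZ_BOUNDS,
                         ) -> pd.DataFrame:
    """Turn a long person-wave table into a scenario analysis table.

    Cleans HAZ, derives the stunting exposure where absent, derives the
    binary outcome from the terminal wave's highest completed grade,
    broadcasts it to every exposure-wave row of the child, and adds the
    lagged exposure column ``stunted_lag`` (0 at the first wave, the
    previous wave's status otherwise, missing if that status is missing).
    ``scenario='early_only'`` keeps only the first two exposure waves.

    Raises on duplicated (child, wave) rows and on an outcome recorded at
    a non-terminal wave.
    """
    if scenario not in (ALL_WAVES, EARLY_ONLY):
        raise ValueError(f"unknown scenario '{scenario}'")
    df = person_waves.copy()
    if df.duplicated(subset=["child_id", "wave"]).any():
        dupes = df.loc[df.duplicated(subset=["child_id", "wave"]),
                       ["child_id", "wave"]].head()
        raise ValueError(f"duplicated (child_id, wave) rows, e.g.\n{dupes}")
    df = df.sort_values(["child_id", "wave"], kind="mergesort")
    waves = sorted(df["wave"].unique())
    final_wave = waves[-1]
    if "highest_grade_completed" in df.columns:
        early_outcome = df["highest_grade_completed"].notna() & (df["wave"] != final_wave)
        if early_outcome.any():
            raise ValueError(
                "highest_grade_completed present at a non-final wave "
                f"(waves {sorted(df.loc[early_outcome, 'wave'].unique())})")

    haz_recorded = df["haz"].notna()
    df["haz"] = clean_haz(df["haz"], bounds=haz_bounds)
    derived = classify_stunting(df["haz"])
    if "stunted" in df.columns:
        # a recorded z-score always wins (so an implausible one voids the
        # stale label); only where HAZ was never measured do we trust a
        # recorded status (e.g. an imputed indicator)
        df["stunted"] = derived.where(haz_recorded, df["stunted"])
    else:
        df["stunted"] = derived

    last = df[df["wave"] == final_wave].set_index("child_id")
    outcome = derive_outcome(last["highest_grade_completed"],
                             threshold_grade=outcome_threshold)
    exposure_waves = [w for w in waves if w != final_wave]
    if scenario == EARLY_ONLY:
        exposure_waves = exposure_waves[:2]
    out = df[df["wave"].isin(exposure_waves)].copy()
    out["stunted_lag"] = out.groupby("child_id")["stunted"].shift(1)
    out.loc[out["wave"] == exposure_waves[0], "stunted_lag"] = 0.0
    out["outcome"] = out["child_id"].map(outcome)
    return out.reset_index(drop=True)
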