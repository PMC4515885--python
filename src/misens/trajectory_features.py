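"""Summarize irregular longitudinal histories into a fixed covariate set.

Subjects are monitored on a varying number of occasions, so the repeated
measurements cannot enter a wide-format imputation model as one column per
time point.  Instead each subject's process history on every scale is
compressed into (a) an ordinary-least-squares intercept and slope of the
score against the session number and (b) the values of the two last process
measurements.  Together with the pre-assessment value and the subject-level
covariates these form one wide row per subject.

Subjects with fewer than two observed process measurements of the outcome
scale cannot be imputed under this scheme and are reported separately
("not imputable").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, MisensError, NotImputableError
from .synthetic_cohort import (
    HAQ_SUBSCALES,
    OUTCOME_VAR,
    ROLE_POST,
    ROLE_PRE,
    ROLE_PROCESS,
    LongCohort,
)

#: scales summarized per subject (outcome first, then alliance subscales)
PROCESS_SCALES = (OUTCOME_VAR,) + HAQ_SUBSCALES

#: fixed column order of the serialized wide table
WIDE_ID_COLUMNS = ("subject_id",)
WIDE_OUTCOME_COLUMNS = ("pre_oq", "post_oq", "M")


@dataclass(frozen=True)
class TrendSummary:
    """OLS line through a subject's process measurements of one scale."""

    intercept: float
    slope: float
    n_points: int


def fit_subject_trend(sessions: Sequence[float], scores: Sequence[float]) -> TrendSummary:
    """Ordinary least squares of score on session number.

    Requires at least two points on at least two distinct sessions; the
    caller excludes pre-assessment values (only process measurements carry
    trend information about the treatment phase).
    """
    s = np.asarray(sessions, dtype=float)
    y = np.asarray(scores, dtype=float)
    if s.size != y.size:
        raise ValueError("sessions and scores must have equal length")
    if s.size < 2:
        raise InsufficientDataError("a trend needs at least two measurements")
    if np.unique(s).size < 2:
        raise InsufficientDataError("a trend needs at least two distinct session numbers")
    s_mean, y_mean = s.mean(), y.mean()
    slope = float(((s - s_mean) * (y - y_mean)).sum() / ((s - s_mean) ** 2).sum())
    intercept = float(y_mean - slope * s_mean)
    return TrendSummary(intercept=intercept, slope=slope, n_points=int(s.size))


def extract_last_two(process_rows: pd.DataFrame) -> tuple[float, float]:
    """Values at the two highest observed process sessions: (penultimate, last).

    Ties in session number are broken by occasion index (later occasion wins).
    """
    obs = process_rows[process_rows["observed"]]
    if len(obs) < 2:
        raise NotImputableError("fewer than two observed process measurements")
    ordered = obs.sort_values(["session_number", "occasion_index"], kind="mergesort")
    last_two = ordered.tail(2)["value"].to_numpy(dtype=float)
    return float(last_two[0]), float(last_two[1])


def _scale_columns(scale: str) -> list[str]:
    return [f"{scale}_int", f"{scale}_slope", f"{scale}_penult", f"{scale}_last"]


def wide_columns(covariates: Sequence[str]) -> list[str]:
    """Documented, fixed column order of the wide one-row-per-subject table."""
    cols = list(WIDE_ID_COLUMNS) + list(covariates) + ["pre_oq"]
    for scale in PROCESS_SCALES:
        cols += _scale_columns(scale)
    cols += ["post_oq", "M"]
    return cols


@dataclass
class WideTable:
    """One-row-per-subject feature table plus the not-imputable remainder."""

    cases: pd.DataFrame
    not_imputable: pd.DataFrame


def _scale_summary(obs_pm: pd.DataFrame, scale: str, index: pd.Index) -> pd.DataFrame:
    """Vectorized per-subject trend + last-two summary of one scale."""
    ci, cs, cp, cl = _scale_columns(scale)
    out = pd.DataFrame(index=index, columns=[ci, cs, cp, cl], dtype=float)
    pm = obs_pm[obs_pm["variable"] == scale]
    if pm.empty:
        return out
    pm = pm.sort_values(["subject_id", "session_number", "occasion_index"], kind="mergesort")
    g = pm.groupby("subject_id")
    n = g.size()
    s = pm["session_number"].astype(float)
    y = pm["value"].astype(float)
    agg = pd.DataFrame(
        {
            "n": n,
            "s": g["session_number"].sum(),
            "y": g["value"].sum(),
            "ss": s.pow(2).groupby(pm["subject_id"]).sum(),
            "sy": (s * y).groupby(pm["subject_id"]).sum(),
            "ndistinct": g["session_number"].nunique(),
        }
    )
    ok = agg.index[(agg["n"] >= 2) & (agg["ndistinct"] >= 2)]
    a = agg.loc[ok]
    sxx = a["ss"] - a["s"] ** 2 / a["n"]
    sxy = a["sy"] - a["s"] * a["y"] / a["n"]
    slope = sxy / sxx
    intercept = a["y"] / a["n"] - slope * a["s"] / a["n"]
    out.loc[ok, cs] = slope
    out.loc[ok, ci] = intercept
    last = g.nth(-1).set_index(pm.loc[g.nth(-1).index, "subject_id"])["value"]
    penult = g.nth(-2).set_index(pm.loc[g.nth(-2).index, "subject_id"])["value"]
    out.loc[ok, cl] = last.reindex(ok)
    out.loc[ok, cp] = penult.reindex(ok)
    return out


def assemble_wide(cohort: LongCohort, covariate_table: pd.DataFrame | None = None) -> WideTable:
    """Build the wide table used by the imputation models.

    Subjects need at least two observed process measurements of the outcome
    scale; others land in ``not_imputable``.  The missingness indicator ``M``
    is 1 exactly when the post value is absent (no post row, or post row not
    observed).  Alliance trend/last-two columns are left missing (NaN) for
    subjects with fewer than two observed measurements of that subscale.
    """
    if covariate_table is None:
        covariate_table = cohort.subjects
    if covariate_table["subject_id"].duplicated().any():
        raise MisensError("duplicate subject ids in the covariate table")
    m = cohort.measurements
    cov_cols = [c for c in covariate_table.columns if c != "subject_id"]

    all_subjects = pd.Index(m["subject_id"].unique(), name="subject_id")
    obs = m[m["observed"]]
    oq = obs[obs["variable"] == OUTCOME_VAR]

    n_obs_pm = (
        oq[oq["role"] == ROLE_PROCESS].groupby("subject_id").size().reindex(all_subjects, fill_value=0)
    )
    keep = n_obs_pm.index[n_obs_pm >= 2]
    dropped = n_obs_pm.index[n_obs_pm < 2]

    base = pd.DataFrame(index=pd.Index(keep, name="subject_id"))
    pre = oq[oq["role"] == ROLE_PRE].set_index("subject_id")["value"]
    base["pre_oq"] = pre.reindex(keep)

    obs_pm = obs[obs["role"] == ROLE_PROCESS]
    for scale in PROCESS_SCALES:
        base = base.join(_scale_summary(obs_pm, scale, base.index))

    post = oq[oq["role"] == ROLE_POST].set_index("subject_id")["value"]
    base["post_oq"] = post.reindex(keep)
    base["M"] = base["post_oq"].isna().astype(int)

    cases = (
        covariate_table.set_index("subject_id")
        .reindex(keep)
        .join(base)
        .reset_index()
    )
    cases = cases[wide_columns(cov_cols)]
    not_imputable = pd.DataFrame(
        {
            "subject_id": dropped,
            "n_process_observed": n_obs_pm.loc[dropped].to_numpy(),
            "reason": "fewer than two process measurements",
        },
        columns=["subject_id", "n_process_observed", "reason"],
    )
    return WideTable(cases=cases, not_imputable=not_imputable.reset_index(drop=True))


def write_wide(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_wide(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
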