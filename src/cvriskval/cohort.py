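"""Cohort data model: eligibility, matching, censoring, crude incidence.

The in-memory cohort container is a pandas DataFrame, one row per subject
(column dictionary in :data:`COHORT_COLUMNS`); small typed records
(:class:`FollowUp`, :class:`MatchedSet`) carry per-subject follow-up and
matching structure.  Follow-up runs from cohort entry to the earliest of
the outcome-family event, death from a non-CVD cause, ten years, or the
administrative end of study.  Cause-specific semantics: an event from a
*different* CVD family does not terminate follow-up for the family under
analysis, preserving each family's person-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataIntegrityError, InvalidInputError

__all__ = [
    "COHORT_COLUMNS",
    "HORIZON_YEARS",
    "OUTCOME_FAMILIES",
    "FollowUp",
    "MatchedSet",
    "screen_eligibility",
    "match_controls",
    "resolve_followup",
    "incidence_rate",
    "person_years",
    "read_cohort_csv",
    "write_cohort_csv",
    "missingness_summary",
]

HORIZON_YEARS = 10.0
DAYS_PER_YEAR = 365.25

#: Terminal-event codes and the outcome families each one counts toward.
#: Fatal CVD events carry a cause tag so they route to the right composite.
EVENT_FAMILIES: Mapping[str, frozenset] = {
    "ami": frozenset({"ascvd", "overall_cvd"}),
    "stroke": frozenset({"ascvd", "overall_cvd"}),
    "heart_failure": frozenset({"heart_failure", "overall_cvd"}),
    "cvd_death_atherosclerotic": frozenset({"ascvd", "overall_cvd"}),
    "cvd_death_heart_failure": frozenset({"heart_failure", "overall_cvd"}),
    "cvd_death_other": frozenset({"overall_cvd"}),
    "noncvd_death": frozenset(),
    "administrative_censor": frozenset(),
}
OUTCOME_FAMILIES = ("overall_cvd", "ascvd", "heart_failure")

#: Cohort CSV column dictionary (one row per subject; empty string = missing;
#: dates ISO-8601).  Follow-up columns are per outcome family
#: (time_<family> in years, event_<family> 0/1) plus the raw terminal event.
COHORT_COLUMNS = [
    "id", "is_case", "birth_year", "enrollment_year", "index_date",
    "sex", "race", "age",
    "systolic_bp", "diastolic_bp", "total_chol", "ldl", "hdl", "bmi",
    "serum_creatinine", "egfr", "hba1c", "adi_percentile",
    "diabetes", "current_smoker", "smoking_status",
    "antihypertensive_use", "lipid_lowering_use", "aspirin_use",
    "seropositive", "prior_ascvd", "prior_hf",
]


@dataclass(frozen=True)
class FollowUp:
    """Censored follow-up for one subject within one outcome family."""

    time_years: float
    terminal_event: str  # key of EVENT_FAMILIES

    def __post_init__(self):
        if not 0.0 < self.time_years <= HORIZON_YEARS:
            raise InvalidInputError("time_years must lie in (0, 10]")
        if self.terminal_event not in EVENT_FAMILIES:
            raise InvalidInputError(
                f"unknown terminal event {self.terminal_event!r}")

    def is_event(self, family: str) -> bool:
        return family in EVENT_FAMILIES[self.terminal_event]


@dataclass(frozen=True)
class MatchedSet:
    """One case with its (up to ``ratio``) matched controls."""

    case_id: str
    control_ids: tuple

    def __post_init__(self):
        if len(set(self.control_ids)) != len(self.control_ids):
            raise ConfigError("duplicate control in matched set")


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def screen_eligibility(subjects: pd.DataFrame):
    """Retain subjects aged 30-79 at entry with no prior ASCVD or HF.

    Returns ``(eligible, exclusion_log)`` where the log counts subjects per
    exclusion reason (a subject may appear under several reasons).
    """
    age = pd.to_numeric(subjects.get("age"), errors="coerce")
    log = {
        "missing_age": int(age.isna().sum()),
        "age_below_30": int((age < 30).sum()),
        "age_above_79": int((age > 79).sum()),
        "prior_ascvd": int(subjects.get(
            "prior_ascvd", pd.Series(False, index=subjects.index))
            .fillna(False).astype(bool).sum()),
        "prior_hf": int(subjects.get(
            "prior_hf", pd.Series(False, index=subjects.index))
            .fillna(False).astype(bool).sum()),
    }
    keep = age.between(30, 79)
    for col in ("prior_ascvd", "prior_hf"):
        if col in subjects.columns:
            keep &= ~subjects[col].fillna(False).astype(bool)
    return subjects.loc[keep.fillna(False)], log


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

_MATCH_KEYS = ("birth_year", "sex", "enrollment_year")


def match_controls(cases: pd.DataFrame, control_pool: pd.DataFrame,
                   ratio: int, seed: int) -> list[MatchedSet]:
    """Exact matching on (birth year, sex, enrollment year).

    Each case receives up to ``ratio`` controls sampled uniformly without
    replacement from the pool sharing its key; no control is reused across
    sets; cases with zero eligible controls are dropped (count retrievable
    as the difference in lengths).  Deterministic given ``seed``.
    """
    if ratio < 1:
        raise ConfigError("matching ratio must be >= 1")
    overlap = set(cases["id"]) & set(control_pool["id"])
    if overlap:
        raise ConfigError("control pool overlaps cases")
    rng = np.random.default_rng(seed)
    pool_by_key: dict[tuple, list] = {
        key: list(grp["id"]) for key, grp in control_pool.groupby(
            list(_MATCH_KEYS), sort=True)
    }
    sets: list[MatchedSet] = []
    # iterate cases in a stable order so the draw sequence is reproducible
    for row in cases.sort_values("id").itertuples():
        key = (row.birth_year, row.sex, row.enrollment_year)
        avail = pool_by_key.get(key, [])
        if not avail:
            continue
        k = min(ratio, len(avail))
        picked = rng.choice(len(avail), size=k, replace=False)
        picked_ids = [avail[i] for i in sorted(picked)]
        for cid in picked_ids:
            avail.remove(cid)
        sets.append(MatchedSet(case_id=row.id, control_ids=tuple(picked_ids)))
    return sets


# ---------------------------------------------------------------------------
# Follow-up resolution
# ---------------------------------------------------------------------------

def resolve_followup(index_date, event_stream: Sequence[tuple], study_end,
                     family: str = "overall_cvd",
                     horizon: float = HORIZON_YEARS) -> FollowUp:
    """Earliest-qualifying-event rule for one subject and one outcome family.

    ``event_stream`` is a date-sorted sequence of ``(date, event_code)``
    pairs.  Qualifying terminators are: an event belonging to ``family``,
    a non-CVD death, the ``horizon`` (10 y) anniversary, or ``study_end``.
    CVD events of other families are ignored (cause-specific person-time).
    """
    index_date = pd.Timestamp(index_date)
    study_end = pd.Timestamp(study_end)
    admin_years = min(horizon, (study_end - index_date).days / DAYS_PER_YEAR)
    best_t, best_ev = admin_years, "administrative_censor"
    prev = None
    for date, code in event_stream:
        date = pd.Timestamp(date)
        if prev is not None and date < prev:
            raise DataIntegrityError("event stream not sorted by date")
        prev = date
        if date < index_date:
            raise DataIntegrityError("event dated before cohort entry")
        if code not in EVENT_FAMILIES:
            raise InvalidInputError(f"unknown event code {code!r}")
        t = (date - index_date).days / DAYS_PER_YEAR
        qualifies = code == "noncvd_death" or family in EVENT_FAMILIES[code]
        if qualifies and t < best_t:
            best_t, best_ev = t, code
            break  # stream is sorted; first qualifying event is earliest
    best_t = min(best_t, horizon)
    return FollowUp(time_years=max(best_t, 1 / DAYS_PER_YEAR),
                    terminal_event=best_ev)


def person_years(times: Iterable[float]) -> float:
    return float(np.sum(np.asarray(list(times), dtype=float)))


# ---------------------------------------------------------------------------
# Crude incidence
# ---------------------------------------------------------------------------

def incidence_rate(n_events: int, py: float):
    """Events per 1,000 person-years with exact Poisson 95% CI.

    Returns ``(rate, lower, upper)``.  Limits are chi-square-quantile
    (Garwood) bounds on the count, divided by person-time.
    """
    if py <= 0:
        raise InvalidInputError("person-years must be positive")
    if n_events < 0:
        raise InvalidInputError("event count must be non-negative")
    lo = 0.0 if n_events == 0 else stats.chi2.ppf(0.025, 2 * n_events) / 2
    hi = stats.chi2.ppf(0.975, 2 * (n_events + 1)) / 2
    scale = 1000.0 / py
    return n_events * scale, lo * scale, hi * scale


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

_FLAG_COLS = ["is_case", "diabetes", "current_smoker", "antihypertensive_use",
              "lipid_lowering_use", "aspirin_use", "seropositive",
              "prior_ascvd", "prior_hf"]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Lossless round-trip writer (empty string = missing, ISO dates)."""
    out = df.copy()
    for c in _FLAG_COLS:
        if c in out.columns:
            out[c] = out[c].map(
                lambda v: "" if pd.isna(v) else str(int(bool(v))))
    out.to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, coercing types and validating basic ranges."""
    df = pd.read_csv(path, dtype={"id": "string"}, keep_default_na=True)
    for c in _FLAG_COLS:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    num_cols = [c for c in df.columns
                if c not in ("id", "sex", "race", "smoking_status",
                             "index_date")]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    neg = [c for c in ("age", "systolic_bp", "total_chol", "hdl", "ldl",
                       "bmi", "serum_creatinine", "egfr", "hba1c")
           if c in df.columns and (df[c].dropna() < 0).any()]
    if neg:
        raise DataIntegrityError(f"negative values in column(s): {neg}")
    return df


def missingness_summary(df: pd.DataFrame) -> pd.Series:
    """Per-column fraction missing (reported by the CSV reader path)."""
    return df.isna().mean().sort_values(ascending=False)
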