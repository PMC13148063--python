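"""Calibration, discrimination and reclassification statistics.

The central quantity is the standardized incidence ratio SIR = O/E:
observed events over the expected count implied by the per-subject
10-year predicted risks.  Subjects censored event-free before the
horizon contribute their predicted probability scaled by the fraction
of the horizon they were observed (proportional person-time reduction);
subjects with the event, or with complete follow-up, contribute the
full probability.  SIR > 1 means the calculator underestimates risk,
SIR < 1 overestimation.  Confidence limits treat O as Poisson with E
fixed (exact chi-square-quantile limits).

Also provided: sensitivity at the 7.5% treatment-decision cutoff,
Harrell's C under censoring, equal-count calibration curves consistent
with the SIR machinery, the two-category net reclassification index
with a subject-level bootstrap, and a stratified driver producing the
per-stratum results table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HORIZON_YEARS
from .errors import ConfigError, InvalidInputError, UndefinedResultError

__all__ = [
    "ValidationResult",
    "ReclassificationResult",
    "StratumSpec",
    "expected_events",
    "sir",
    "sensitivity_at_cutoff",
    "harrells_c",
    "calibration_curve",
    "nri",
    "validate",
]

RISK_CUTOFF = 0.075
BMI_EDGES = (-np.inf, 20.0, 25.0, 30.0, 35.0, np.inf)
BMI_LABELS = ("<20", "20-25", "25-30", "30-35", ">=35")


@dataclass
class ValidationResult:
    """Calibration and discrimination of one model on one (sub)cohort."""

    stratum: str
    n: int
    observed_events: int
    expected_events: float
    sir: float
    sir_ci: tuple
    sensitivity: Optional[float]
    c_statistic: Optional[float]
    calibration_bins: Optional[pd.DataFrame] = None

    def to_row(self) -> dict:
        return {
            "stratum": self.stratum, "n": self.n,
            "observed": self.observed_events,
            "expected": self.expected_events,
            "sir": self.sir, "sir_lo": self.sir_ci[0],
            "sir_hi": self.sir_ci[1],
            "sensitivity": self.sensitivity,
            "c_statistic": self.c_statistic,
        }


@dataclass
class ReclassificationResult:
    """Two-category reclassification of new vs old risks, split by outcome."""

    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int
    n_events: int
    n_nonevents: int
    nri: float           # percent
    nri_se: float        # percent
    nri_ci: tuple        # percent, 95%

    @property
    def n_reclassified(self) -> int:
        return (self.up_events + self.down_events
                + self.up_nonevents + self.down_nonevents)

    def to_frame(self) -> pd.DataFrame:
        """Counts in the published reclassification-table shape."""
        return pd.DataFrame(
            {"experienced_event": [self.up_events, self.down_events],
             "event_free": [self.up_nonevents, self.down_nonevents]},
            index=[">=cutoff (reclassified up)", "<cutoff (reclassified down)"])


@dataclass(frozen=True)
class StratumSpec:
    """Stratification axis; strata partition the cohort (missing explicit)."""

    axis: str = "none"  # none|sex|seropositivity|diabetes|age65|bmi_category|ldl_quintile

    def assign(self, cohort: pd.DataFrame) -> pd.Series:
        if self.axis == "none":
            return pd.Series("all", index=cohort.index)
        if self.axis == "sex":
            lab = cohort["sex"].astype(str)
        elif self.axis == "seropositivity":
            lab = cohort["seropositive"].map(
                {1.0: "seropositive", 0.0: "seronegative", 1: "seropositive",
                 0: "seronegative"})
        elif self.axis == "diabetes":
            lab = cohort["diabetes"].map(
                {1.0: "diabetes", 0.0: "no_diabetes", 1: "diabetes",
                 0: "no_diabetes"})
        elif self.axis == "age65":
            lab = pd.Series(np.where(cohort["age"] >= 65, "age>=65", "age<65"),
                            index=cohort.index)
            lab[cohort["age"].isna()] = np.nan
        elif self.axis == "bmi_category":
            lab = pd.cut(cohort["bmi"], bins=BMI_EDGES, labels=BMI_LABELS,
                         right=False).astype(object)
        elif self.axis == "ldl_quintile":
            lab = (pd.qcut(cohort["ldl"].rank(method="first"), 5,
                           labels=[f"Q{i}" for i in range(1, 6)])
                   .astype(object))
        else:
            raise ConfigError(f"unknown stratification axis {self.axis!r}")
        return lab.fillna("missing").astype(str)


# ---------------------------------------------------------------------------
# Expected events and SIR
# ---------------------------------------------------------------------------

def expected_events(risks, times, events, horizon: float = HORIZON_YEARS,
                    proportional_adjustment: bool = True) -> float:
    """E = sum of per-subject expected contributions.

    A subject contributes the full predicted probability if the event
    occurred or follow-up reached the horizon, and (t / horizon) * p if
    censored event-free at t < horizon.  ``proportional_adjustment=False``
    is the ablation that skips the censoring reduction (every subject
    contributes full p); it is biased and exists for demonstration only.
    """
    p = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (len(p) == len(t) == len(e)):
        raise InvalidInputError("risks, times and events must align")
    if np.any((t <= 0) | (t > horizon + 1e-9)):
        raise InvalidInputError("follow-up times must lie in (0, horizon]")
    if not proportional_adjustment:
        return float(p.sum())
    frac = np.where(e | (t >= horizon - 1e-12), 1.0, t / horizon)
    return float((p * frac).sum())


def sir(observed: int, expected: float):
    """SIR point estimate with exact Poisson 95% limits (E fixed).

    Returns ``(sir, lower, upper)``.
    """
    if expected <= 0:
        raise InvalidInputError("expected events must be positive")
    if observed < 0:
        raise InvalidInputError("observed count must be non-negative")
    lo = 0.0 if observed == 0 else stats.chi2.ppf(0.025, 2 * observed) / 2
    hi = stats.chi2.ppf(0.975, 2 * (observed + 1)) / 2
    return observed / expected, lo / expected, hi / expected


def sensitivity_at_cutoff(risks, events, cutoff: float = RISK_CUTOFF) -> float:
    """Among subjects with the outcome, fraction with risk >= cutoff."""
    p = np.asarray(risks, dtype=float)
    e = np.asarray(events, dtype=bool)
    if e.sum() == 0:
        raise UndefinedResultError("sensitivity undefined with zero events")
    return float((p[e] >= cutoff).mean())


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def harrells_c(risks, times, events, chunk: int = 512) -> float:
    """Harrell's concordance index for censored follow-up.

    A pair is comparable iff the member with the shorter follow-up had
    the event (ties in time with one event and one censored treat the
    censored member as surviving longer; tied event times are not
    comparable).  Concordant = higher risk on the shorter-lived member;
    tied risks count 1/2.  O(n^2) in chunks; exact, no approximation.
    """
    p = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = len(p)
    if n < 2 or not (len(t) == len(e) == n):
        raise InvalidInputError("need >= 2 aligned subjects")
    conc = ties = comp = 0.0
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        # i in chunk is the shorter-lived event member of the pair
        shorter = (t[sl, None] < t[None, :]) | (
            (t[sl, None] == t[None, :]) & e[sl, None, ] & ~e[None, :])
        comparable = shorter & e[sl, None]
        comp += comparable.sum()
        conc += (comparable & (p[sl, None] > p[None, :])).sum()
        ties += (comparable & (p[sl, None] == p[None, :])).sum()
    if comp == 0:
        raise UndefinedResultError("no comparable pairs")
    return float((conc + 0.5 * ties) / comp)


# ---------------------------------------------------------------------------
# Calibration curve
# ---------------------------------------------------------------------------

def calibration_curve(risks, times, events, n_bins: int = 10,
                      horizon: float = HORIZON_YEARS) -> pd.DataFrame:
    """Equal-count bins of predicted risk vs censoring-adjusted observed risk.

    Per bin the observed probability is (O_bin / E_bin) * mean predicted,
    keeping the curve consistent with the SIR machinery.  Also returns a
    lowess-smoothed observed value per bin for plotting.  Constant risks
    collapse to a single effective bin.
    """
    p = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(p) < n_bins:
        raise ConfigError("need at least n_bins subjects")
    ranks = pd.Series(p).rank(method="first")
    if np.unique(p).size == 1:
        bins = pd.Series(0, index=ranks.index)
    else:
        bins = pd.qcut(ranks, min(n_bins, ranks.nunique()),
                       labels=False, duplicates="drop")
    rows = []
    for b in sorted(bins.unique()):
        m = (bins == b).to_numpy()
        e_bin = expected_events(p[m], t[m], e[m], horizon)
        o_bin = int(e[m].sum())
        mean_pred = float(p[m].mean())
        obs = (o_bin / e_bin) * mean_pred if e_bin > 0 else np.nan
        rows.append({"bin": int(b), "n": int(m.sum()),
                     "mean_predicted": mean_pred, "observed": obs,
                     "observed_events": o_bin, "expected_events": e_bin})
    out = pd.DataFrame(rows)
    if len(out) >= 3:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        out["observed_smoothed"] = lowess(
            out["observed"], out["mean_predicted"], frac=0.8,
            return_sorted=False)
    else:
        out["observed_smoothed"] = out["observed"]
    return out


# ---------------------------------------------------------------------------
# Net reclassification index
# ---------------------------------------------------------------------------

def _nri_point(old, new, e, cutoff):
    up = (old < cutoff) & (new >= cutoff)
    down = (old >= cutoff) & (new < cutoff)
    ne, nn = int(e.sum()), int((~e).sum())
    up_e, down_e = int((up & e).sum()), int((down & e).sum())
    up_n, down_n = int((up & ~e).sum()), int((down & ~e).sum())
    val = 100.0 * ((up_e - down_e) / ne + (down_n - up_n) / nn)
    return val, up_e, down_e, up_n, down_n, ne, nn


def nri(old_risks, new_risks, events, cutoff: float = RISK_CUTOFF,
        n_boot: int = 100, seed: int = 0,
        ci_method: str = "normal") -> ReclassificationResult:
    """Two-category NRI (percent) of new risks against old, with bootstrap SE.

    NRI = 100 * [(up_e - down_e)/n_events + (down_ne - up_ne)/n_nonevents]
    at the given cutoff; the SE comes from ``n_boot`` subject-level
    bootstrap resamples and the CI is estimate +/- 1.96 SE
    (``ci_method='percentile'`` for the percentile interval).
    """
    old = np.asarray(old_risks, dtype=float)
    new = np.asarray(new_risks, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (len(old) == len(new) == len(e)):
        raise InvalidInputError("risk vectors and outcomes must align")
    if e.sum() == 0 or (~e).sum() == 0:
        raise UndefinedResultError("NRI needs both events and nonevents")
    val, up_e, down_e, up_n, down_n, ne, nn = _nri_point(old, new, e, cutoff)
    rng = np.random.default_rng(seed)
    n = len(e)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        eb = e[idx]
        if eb.sum() == 0 or (~eb).sum() == 0:
            continue
        boots.append(_nri_point(old[idx], new[idx], eb, cutoff)[0])
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    if ci_method == "percentile" and len(boots) > 1:
        ci = (float(np.percentile(boots, 2.5)),
              float(np.percentile(boots, 97.5)))
    else:
        ci = (val - 1.96 * se, val + 1.96 * se)
    return ReclassificationResult(
        up_events=up_e, down_events=down_e, up_nonevents=up_n,
        down_nonevents=down_n, n_events=ne, n_nonevents=nn,
        nri=val, nri_se=se, nri_ci=ci)


# ---------------------------------------------------------------------------
# Stratified driver
# ---------------------------------------------------------------------------

def validate(cohort: pd.DataFrame, risks, times, events,
             strata: StratumSpec = StratumSpec("none"),
             cutoff: float = RISK_CUTOFF, n_bins: int = 10,
             compute_c: bool = True) -> dict[str, ValidationResult]:
    """Per-stratum O, E, SIR + CI, sensitivity, Harrell's C, calibration bins.

    Empty strata are reported with n=0 rather than raised; statistics that
    are undefined on a stratum (e.g. sensitivity with no events) are None.
    """
    p = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (len(p) == len(t) == len(e) == len(cohort)):
        raise InvalidInputError("cohort, risks and follow-up must align")
    labels = strata.assign(cohort).to_numpy()
    out: dict[str, ValidationResult] = {}
    for lab in pd.unique(labels):
        m = labels == lab
        n = int(m.sum())
        if n == 0:
            out[lab] = ValidationResult(lab, 0, 0, 0.0, np.nan,
                                        (np.nan, np.nan), None, None)
            continue
        E = expected_events(p[m], t[m], e[m])
        O = int(e[m].sum())
        s, lo, hi = sir(O, E) if E > 0 else (np.nan, np.nan, np.nan)
        try:
            sens = sensitivity_at_cutoff(p[m], e[m], cutoff)
        except UndefinedResultError:
            sens = None
        cstat = None
        if compute_c:
            try:
                cstat = harrells_c(p[m], t[m], e[m])
            except UndefinedResultError:
                cstat = None
        bins = None
        if n >= n_bins:
            bins = calibration_curve(p[m], t[m], e[m], n_bins)
        out[lab] = ValidationResult(
            stratum=str(lab), n=n, observed_events=O, expected_events=E,
            sir=s, sir_ci=(lo, hi), sensitivity=sens, c_statistic=cstat,
            calibration_bins=bins)
    return out
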