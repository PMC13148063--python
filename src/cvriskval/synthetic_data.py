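"""Synthetic matched RA / control cohorts with a plantable calibration ratio.

The generator emulates the covariate structure of a US veteran RA cohort
and its matched controls: marginal means/proportions follow the study
population's printed baseline table (RA cases: mean age 60.9 (SD 10.0),
84.9% male, 22.4% diabetic, SBP 128.4 (17.4), total cholesterol 183.3
(34.9), HDL 46.3 (14.5), eGFR 81.5 (19.9), 38.4% on a statin, 55.6% on an
antihypertensive; controls analogously), joined through a Gaussian copula
with a modest rank-correlation set, with per-field missingness injected
after value generation (MCAR by default, optional age/group-keyed MAR).

Outcomes carry a *planted truth*: the true 10-year event probability of a
subject is ``kappa * predicted_risk`` for a configurable calibration
ratio ``kappa``, so the observed-to-predicted ratio the validation module
estimates (the SIR) has a known recoverable value.  Event times are
exponential within the 10-year window (constant hazard), under which the
proportional person-time correction for censored subjects is exactly the
right adjustment; competing non-CVD death and administrative censoring
follow the cohort module's semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort import HORIZON_YEARS
from .errors import ConfigError
from .risk_models import egfr_ckdepi_2021

__all__ = [
    "GroupParams",
    "CovariateModel",
    "OutcomeModel",
    "default_covariate_model",
    "generate_profiles",
    "simulate_outcomes",
]

_CONT_FIELDS = ("age", "systolic_bp", "diastolic_bp", "total_chol",
                "ldl", "hdl", "bmi", "egfr")
# physiologic clipping bounds applied after the copula draw
_CLIP = {
    "age": (30.0, 79.0), "systolic_bp": (80.0, 220.0),
    "diastolic_bp": (40.0, 130.0), "total_chol": (90.0, 350.0),
    "ldl": (30.0, 250.0), "hdl": (15.0, 120.0),
    "bmi": (15.0, 55.0), "egfr": (8.0, 170.0),
}


@dataclass(frozen=True)
class GroupParams:
    """Marginals for one group (cases or controls)."""

    continuous: Mapping[str, tuple]      # field -> (mean, sd)
    male_frac: float
    race_probs: Mapping[str, float]      # white/black/other/missing
    smoking_probs: Mapping[str, float]   # current/former/never/missing
    diabetes_prev: float
    antihypertensive_frac: float
    lipid_lowering_frac: float
    aspirin_frac: float
    missingness: Mapping[str, float]     # field -> P(missing)

    def __post_init__(self):
        for name, probs in (("race", self.race_probs),
                            ("smoking", self.smoking_probs)):
            total = sum(probs.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigError(f"{name} probabilities must sum to 1")
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ConfigError(f"{name} probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CovariateModel:
    """Case and control marginals plus the shared copula correlation."""

    case: GroupParams
    control: GroupParams
    correlation: Mapping[tuple, float] = field(default_factory=dict)
    seropositive_prev: float = 0.70
    diabetes_bmi_slope: float = 0.30   # logit shift per BMI SD
    mar: bool = False                  # age/group-keyed missingness
    mar_age_slope: float = 0.30        # log-scale per age SD when mar=True

    def correlation_matrix(self) -> np.ndarray:
        n = len(_CONT_FIELDS)
        r = np.eye(n)
        idx = {f: i for i, f in enumerate(_CONT_FIELDS)}
        for (a, b), v in self.correlation.items():
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ConfigError("correlation matrix is not positive semi-definite")
        return r

    def without_missingness(self) -> "CovariateModel":
        """Copy with no injected missingness and no missing categories."""
        def strip(g: GroupParams) -> GroupParams:
            smoke = {k: v for k, v in g.smoking_probs.items() if k != "missing"}
            tot = sum(smoke.values())
            smoke = {k: v / tot for k, v in smoke.items()}
            return replace(g, smoking_probs=smoke, missingness={})
        return replace(self, case=strip(self.case), control=strip(self.control))


def default_covariate_model() -> CovariateModel:
    """Defaults reproducing the study cohort's baseline characteristics."""
    case = GroupParams(
        continuous={
            "age": (60.9, 10.0), "systolic_bp": (128.4, 17.4),
            "diastolic_bp": (74.5, 10.3), "total_chol": (183.3, 34.9),
            "ldl": (105.2, 33.5), "hdl": (46.3, 14.5),
            "bmi": (29.0, 5.3), "egfr": (81.5, 19.9),
        },
        male_frac=0.849,
        race_probs={"white": 0.754, "black": 0.154, "other": 0.024,
                    "missing": 0.068},
        smoking_probs={"current": 0.526, "former": 0.304, "never": 0.153,
                       "missing": 0.017},
        diabetes_prev=0.224,
        antihypertensive_frac=0.556,
        lipid_lowering_frac=0.384,
        aspirin_frac=0.106,
        missingness={"bmi": 0.013, "total_chol": 0.05, "ldl": 0.05,
                     "hdl": 0.05, "serum_creatinine": 0.04,
                     "systolic_bp": 0.01, "diastolic_bp": 0.01,
                     "hba1c": 0.30, "adi_percentile": 0.05},
    )
    control = GroupParams(
        continuous={
            "age": (59.6, 10.1), "systolic_bp": (129.7, 17.1),
            "diastolic_bp": (75.7, 10.3), "total_chol": (186.1, 35.7),
            "ldl": (107.1, 34.5), "hdl": (46.4, 14.2),
            "bmi": (28.6, 5.3), "egfr": (80.1, 18.7),
        },
        male_frac=0.832,
        race_probs={"white": 0.631, "black": 0.177, "other": 0.031,
                    "missing": 0.161},
        smoking_probs={"current": 0.410, "former": 0.240, "never": 0.207,
                       "missing": 0.143},
        diabetes_prev=0.157,
        antihypertensive_frac=0.320,
        lipid_lowering_frac=0.243,
        aspirin_frac=0.062,
        missingness={"bmi": 0.235, "total_chol": 0.12, "ldl": 0.12,
                     "hdl": 0.12, "serum_creatinine": 0.10,
                     "systolic_bp": 0.03, "diastolic_bp": 0.03,
                     "hba1c": 0.45, "adi_percentile": 0.05},
    )
    correlation = {
        ("age", "systolic_bp"): 0.25, ("age", "egfr"): -0.35,
        ("systolic_bp", "diastolic_bp"): 0.60,
        ("total_chol", "ldl"): 0.85, ("total_chol", "hdl"): 0.15,
        ("bmi", "systolic_bp"): 0.15, ("age", "bmi"): -0.05,
    }
    return CovariateModel(case=case, control=control, correlation=correlation)


# ---------------------------------------------------------------------------
# Profile generation
# ---------------------------------------------------------------------------

def _creatinine_from_egfr(egfr, age, female):
    """Invert the CKD-EPI 2021 formula so creatinine and eGFR agree."""
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    knee = 142.0 * 0.9938 ** age * np.where(female, 1.012, 1.0)
    ratio = egfr / knee
    below = egfr < knee  # creatinine above the knot, steep slope -1.2
    scr = np.where(below,
                   kappa * ratio ** (-1.0 / 1.2),
                   kappa * ratio ** (1.0 / np.where(alpha == 0, 1, alpha)))
    return scr


def _draw_group(g: GroupParams, corr_chol: np.ndarray, n: int,
                rng: np.random.Generator,
                forced_age: Optional[np.ndarray] = None,
                forced_male: Optional[np.ndarray] = None) -> pd.DataFrame:
    z = rng.standard_normal((n, len(_CONT_FIELDS))) @ corr_chol.T
    df = pd.DataFrame(index=range(n))
    for j, f in enumerate(_CONT_FIELDS):
        mu, sd = g.continuous[f]
        lo, hi = _CLIP[f]
        df[f] = np.clip(mu + sd * z[:, j], lo, hi)
    if forced_age is not None:
        df["age"] = forced_age
    if forced_male is None:
        male = rng.random(n) < g.male_frac
    else:
        male = forced_male
    df["sex"] = np.where(male, "male", "female")
    races = list(g.race_probs)
    df["race"] = rng.choice(races, size=n, p=[g.race_probs[r] for r in races])
    # true smoking status is always one of current/former/never; the
    # 'missing' share of the marginal is injected as missingness later
    smokes = [s for s in g.smoking_probs if s != "missing"]
    sp = np.array([g.smoking_probs[s] for s in smokes])
    df["smoking_status"] = rng.choice(smokes, size=n, p=sp / sp.sum())
    df["current_smoker"] = (df["smoking_status"] == "current").astype(float)
    bmi_z = (df["bmi"] - g.continuous["bmi"][0]) / g.continuous["bmi"][1]
    logit0 = np.log(g.diabetes_prev / (1 - g.diabetes_prev))
    p_dm = 1 / (1 + np.exp(-(logit0 + 0.30 * bmi_z)))
    df["diabetes"] = (rng.random(n) < p_dm).astype(float)
    df["antihypertensive_use"] = (
        rng.random(n) < g.antihypertensive_frac).astype(float)
    df["lipid_lowering_use"] = (
        rng.random(n) < g.lipid_lowering_frac).astype(float)
    df["aspirin_use"] = (rng.random(n) < g.aspirin_frac).astype(float)
    dm = df["diabetes"].to_numpy() > 0
    hba1c = np.where(dm,
                     np.clip(rng.normal(7.3, 1.3, n), 5.5, 14.0),
                     np.clip(rng.normal(5.6, 0.4, n), 4.5, 6.4))
    df["hba1c"] = hba1c
    df["adi_percentile"] = rng.integers(1, 101, size=n).astype(float)
    female = (~male).astype(bool)
    df["serum_creatinine"] = np.round(_creatinine_from_egfr(
        df["egfr"].to_numpy(), df["age"].to_numpy(), female), 4)
    # keep the stored eGFR consistent with the rounded creatinine
    df["egfr"] = egfr_ckdepi_2021(
        df["serum_creatinine"].to_numpy(), df["age"].to_numpy(), df["sex"])
    df["prior_ascvd"] = 0.0
    df["prior_hf"] = 0.0
    return df


def _inject_missingness(df: pd.DataFrame, g: GroupParams,
                        model: CovariateModel,
                        rng: np.random.Generator) -> pd.DataFrame:
    out = df.copy()
    p_smoke = g.smoking_probs.get("missing", 0.0)
    if p_smoke > 0:
        mask = rng.random(len(out)) < p_smoke
        out.loc[mask, "smoking_status"] = "missing"
        out.loc[mask, "current_smoker"] = np.nan
    if not g.missingness:
        return out
    age_mu, age_sd = g.continuous["age"]
    age_z = (df["age"].to_numpy(float) - age_mu) / age_sd
    for fld, p0 in g.missingness.items():
        if fld not in out.columns or p0 <= 0:
            continue
        if model.mar:
            p = np.clip(p0 * np.exp(model.mar_age_slope * age_z), 0.0, 0.95)
        else:
            p = np.full(len(out), p0)
        mask = rng.random(len(out)) < p
        out.loc[mask, fld] = np.nan
        if fld == "serum_creatinine":
            out.loc[mask, "egfr"] = np.nan  # eGFR derives from creatinine
    return out


def generate_profiles(model: CovariateModel, n_cases: int, ratio: int,
                      seed: int):
    """Generate ``n_cases`` RA-like cases plus ``ratio`` matched controls each.

    Controls share each case's matching key (birth year, sex, enrollment
    year), hence its integer age at entry; their remaining covariates
    follow the control marginals.  Returns ``(cohort, complete)`` — the
    cohort with injected missingness and the pre-mask complete table (the
    truth sidecar for mask-and-recover tests; never an input to the
    validation path).  Deterministic given ``seed``; ``ratio`` may be 0
    for a cases-only cohort.
    """
    if n_cases < 1:
        raise ConfigError("n_cases must be >= 1")
    if ratio < 0:
        raise ConfigError("ratio must be >= 0")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        model.correlation_matrix() + 1e-12 * np.eye(len(_CONT_FIELDS)))

    cases = _draw_group(model.case, chol, n_cases, rng)
    cases["id"] = [f"RA{i:07d}" for i in range(n_cases)]
    cases["is_case"] = 1.0
    cases["seropositive"] = (
        rng.random(n_cases) < model.seropositive_prev).astype(float)
    cases["enrollment_year"] = rng.integers(2006, 2015, size=n_cases)
    entry_day = rng.integers(0, 365, size=n_cases)
    cases["index_date"] = [
        (pd.Timestamp(int(y), 1, 1) + pd.Timedelta(days=int(d))).date().isoformat()
        for y, d in zip(cases["enrollment_year"], entry_day)]
    cases["birth_year"] = (
        cases["enrollment_year"] - np.floor(cases["age"])).astype(int)

    frames = [cases]
    if ratio > 0:
        idx = np.repeat(np.arange(n_cases), ratio)
        ctrl = _draw_group(
            model.control, chol, len(idx), rng,
            forced_age=cases["age"].to_numpy()[idx],
            forced_male=(cases["sex"].to_numpy() == "male")[idx])
        ctrl["id"] = [f"C{i:08d}" for i in range(len(idx))]
        ctrl["is_case"] = 0.0
        ctrl["seropositive"] = np.nan
        ctrl["enrollment_year"] = cases["enrollment_year"].to_numpy()[idx]
        ctrl["index_date"] = cases["index_date"].to_numpy()[idx]
        ctrl["birth_year"] = cases["birth_year"].to_numpy()[idx]
        ctrl["matched_case_id"] = cases["id"].to_numpy()[idx]
        frames.append(ctrl)
    complete = pd.concat(frames, ignore_index=True)

    masked = []
    for is_case, g in ((1.0, model.case), (0.0, model.control)):
        grp = complete[complete["is_case"] == is_case]
        if len(grp):
            masked.append(_inject_missingness(grp, g, model, rng))
    cohort = pd.concat(masked).sort_index()
    return cohort, complete


# ---------------------------------------------------------------------------
# Outcome simulation (planted truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModel:
    """Planted-truth event model for one outcome family.

    ``calibration_ratio`` multiplies model-predicted 10-year risk to give
    the true event probability; ``predicted_risk_cap`` truncates predicted
    risk before multiplication (the same truncated risks must be fed to
    the validation side); the product must stay below
    ``risk_truncation_cap``.  Administrative censoring is uniform over
    ``admin_censor`` years (``None`` = everyone reaches the horizon);
    non-CVD death is exponential at ``noncvd_death_rate`` per year.
    """

    calibration_ratio: float = 1.0
    noncvd_death_rate: float = 0.0
    admin_censor: Optional[tuple] = None  # (t_min, t_max) in years
    predicted_risk_cap: float = 0.40
    risk_truncation_cap: float = 0.95

    def __post_init__(self):
        if self.calibration_ratio < 0:
            raise ConfigError("calibration ratio must be non-negative")
        if not 0 < self.risk_truncation_cap < 1:
            raise ConfigError("risk truncation cap must lie in (0, 1)")
        if self.admin_censor is not None:
            lo, hi = self.admin_censor
            if not (0 < lo <= hi):
                raise ConfigError("admin censor window must satisfy 0 < lo <= hi")


_FAMILY_EVENT = {"overall_cvd": "ami", "ascvd": "ami",
                 "heart_failure": "heart_failure"}


def simulate_outcomes(risks, outcome_model: OutcomeModel, seed: int,
                      family: str = "overall_cvd") -> pd.DataFrame:
    """Draw per-subject follow-up with true P(event by 10 y) = kappa * risk.

    ``risks`` are the model-predicted (already capped) probabilities the
    validation side will use.  Event times are exponential with the
    10-year cumulative probability matched to the target; non-CVD death
    and administrative censoring compete.  Returns a DataFrame with
    ``time_years``, ``terminal_event``, ``event`` (0/1 for ``family``)
    and ``true_prob``.
    """
    rng = np.random.default_rng(seed)
    p = np.minimum(np.asarray(risks, dtype=float),
                   outcome_model.predicted_risk_cap)
    if np.any((p < 0) | (p >= 1) | np.isnan(p)):
        raise ConfigError("risks must lie in [0, 1) and be non-missing")
    target = outcome_model.calibration_ratio * p
    if np.any(target > outcome_model.risk_truncation_cap):
        raise ConfigError(
            "calibration_ratio x predicted risk exceeds the truncation cap; "
            "lower the ratio or the predicted-risk cap")
    n = len(p)
    lam = -np.log1p(-target) / HORIZON_YEARS
    with np.errstate(divide="ignore"):
        t_event = np.where(lam > 0,
                           rng.exponential(1.0, n) / np.where(lam > 0, lam, 1.0),
                           np.inf)
    if outcome_model.noncvd_death_rate > 0:
        t_death = rng.exponential(1.0 / outcome_model.noncvd_death_rate, n)
    else:
        t_death = np.full(n, np.inf)
    if outcome_model.admin_censor is not None:
        lo, hi = outcome_model.admin_censor
        t_admin = rng.uniform(lo, hi, n)
    else:
        t_admin = np.full(n, np.inf)

    t = np.minimum.reduce([t_event, t_death, t_admin,
                           np.full(n, HORIZON_YEARS)])
    t = np.maximum(t, 1e-6)
    event = (t_event <= t) & (t_event < HORIZON_YEARS + 1e-12)
    terminal = np.where(
        event, _FAMILY_EVENT[family],
        np.where(t_death <= t, "noncvd_death", "administrative_censor"))
    return pd.DataFrame({
        "time_years": t,
        "terminal_event": terminal,
        "event": event.astype(int),
        "true_prob": target,
    })
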