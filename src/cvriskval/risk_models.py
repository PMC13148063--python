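"""Table-driven 10-year cardiovascular risk equations.

Implements the PREVENT equations (overall CVD, ASCVD and heart failure;
sex-specific logistic models, with optional social-deprivation and HbA1c
add-on variants) and the Pooled Cohort Equations (PCE; race- and
sex-specific ASCVD model in baseline-survival form), plus the race-free
CKD-EPI 2021 creatinine eGFR formula and the valid-range eligibility
screen applied before risk calculation.

The equations are driven entirely by bundled coefficient tables
(``data/*.csv``, sha256-pinned in ``data/checksums.json``): a model is an
ordered list of (predictor transform, coefficient) pairs plus link
metadata, so transcription issues are localized to data files rather than
code.  The add-on variant terms live in
``prevent_addon_terms_synthetic.csv``; as the file name indicates these
add-on coefficients are constructed stand-ins layered on the base models,
not a transcription of the source publication's re-estimated variant
models.

All operations accept either a single :class:`RiskProfile` or a pandas
DataFrame with one row per subject (vectorized path used by the cohort
pipeline).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, MissingDataError

__all__ = [
    "RiskProfile",
    "ModelSpec",
    "RISK_CATEGORIES",
    "egfr_ckdepi_2021",
    "resolve_egfr",
    "load_model",
    "available_models",
    "linear_predictor",
    "predicted_risk",
    "classify_risk",
    "screen_validity",
]

MGDL_TO_MMOL_CHOL = 0.02586  # cholesterol mg/dL -> mmol/L

#: Half-open treatment-decision categories on 10-year risk (probability units).
#: 7.5% and 20% belong to the upper category; ``high`` is closed at 1.
RISK_CATEGORIES = {
    "low_borderline": (0.0, 0.075),
    "intermediate": (0.075, 0.20),
    "high": (0.20, 1.0),
}


@dataclass
class RiskProfile:
    """One subject's baseline predictor values; every field nullable.

    Units: age years, pressures mm Hg, lipids mg/dL, creatinine mg/dL,
    eGFR mL/min/1.73m^2, BMI kg/m^2, HbA1c %, ADI national percentile 1-100.
    """

    age: Optional[float] = None
    sex: Optional[str] = None  # 'female' | 'male'
    race: Optional[str] = None  # 'white' | 'black' | 'other' | None (PCE only)
    systolic_bp: Optional[float] = None
    diastolic_bp: Optional[float] = None
    total_chol: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    bmi: Optional[float] = None
    serum_creatinine: Optional[float] = None
    egfr: Optional[float] = None
    diabetes: Optional[bool] = None
    current_smoker: Optional[bool] = None
    smoking_status: Optional[str] = None  # 'current' | 'former' | 'never' | None
    antihypertensive_use: Optional[bool] = None
    lipid_lowering_use: Optional[bool] = None
    aspirin_use: Optional[bool] = None
    hba1c: Optional[float] = None
    adi_percentile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise InvalidInputError("age must be non-negative")
        for f in ("systolic_bp", "diastolic_bp", "total_chol", "hdl", "ldl",
                  "bmi", "serum_creatinine", "egfr", "hba1c"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise InvalidInputError(f"{f} must be non-negative")
        if self.smoking_status is not None and self.current_smoker is not None:
            if self.current_smoker != (self.smoking_status == "current"):
                raise InvalidInputError(
                    "current_smoker inconsistent with smoking_status")
        if self.current_smoker is None and self.smoking_status is not None:
            # 'former' and 'never' both map to non-smoker
            self.current_smoker = self.smoking_status == "current"

    def to_frame(self) -> pd.DataFrame:
        row = {k: (np.nan if v is None else v) for k, v in self.__dict__.items()}
        row["diabetes"] = _flag(self.diabetes)
        row["current_smoker"] = _flag(self.current_smoker)
        row["antihypertensive_use"] = _flag(self.antihypertensive_use)
        row["lipid_lowering_use"] = _flag(self.lipid_lowering_use)
        row["aspirin_use"] = _flag(self.aspirin_use)
        return pd.DataFrame([row])


def _flag(v) -> float:
    return np.nan if v is None else float(bool(v))


# ---------------------------------------------------------------------------
# CKD-EPI 2021 creatinine eGFR
# ---------------------------------------------------------------------------

def egfr_ckdepi_2021(serum_creatinine, age, sex):
    """Race-free CKD-EPI 2021 creatinine eGFR (mL/min/1.73 m^2).

    Two-slope spline in standardized serum creatinine with sex-specific
    knot (0.7 mg/dL female, 0.9 male) and below-knot exponent
    (-0.241 female, -0.302 male); above-knot exponent -1.200; age decay
    0.9938 per year; 1.012 multiplier for women.  Accepts scalars or
    aligned arrays.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age_a <= 0):
        raise InvalidInputError("creatinine and age must be positive")
    female = _sex_is_female(sex, scr.shape)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    ratio = scr / kappa
    out = (142.0
           * np.minimum(ratio, 1.0) ** alpha
           * np.maximum(ratio, 1.0) ** -1.200
           * 0.9938 ** age_a
           * np.where(female, 1.012, 1.0))
    if np.isscalar(serum_creatinine) or out.ndim == 0:
        return float(out)
    return out


def _sex_is_female(sex, shape):
    if isinstance(sex, str):
        if sex not in ("female", "male"):
            raise InvalidInputError(f"unknown sex {sex!r}")
        return np.full(shape, sex == "female")
    s = pd.Series(np.asarray(sex)).astype(str)
    bad = ~s.isin(["female", "male"])
    if bad.any():
        raise InvalidInputError("sex must be 'female' or 'male'")
    return (s == "female").to_numpy()


def resolve_egfr(df: pd.DataFrame) -> pd.Series:
    """eGFR with creatinine precedence.

    Where serum creatinine is present, eGFR is recomputed from it for
    internal consistency; where only a reported eGFR is present, it is
    used as-is.
    """
    egfr = df.get("egfr", pd.Series(np.nan, index=df.index)).astype(float).copy()
    scr = df.get("serum_creatinine")
    if scr is not None:
        have = scr.notna() & df["age"].notna() & df["sex"].notna()
        if have.any():
            sub = df.loc[have]
            egfr.loc[have] = egfr_ckdepi_2021(
                sub["serum_creatinine"].to_numpy(float),
                sub["age"].to_numpy(float),
                sub["sex"],
            )
    return egfr


# ---------------------------------------------------------------------------
# Predictor transforms
# ---------------------------------------------------------------------------
# Each transform id maps to (fields required non-missing, function(df)->array).

def _nhdl(df):
    return (df["total_chol"] - df["hdl"]) * MGDL_TO_MMOL_CHOL - 3.5


def _chdl(df):
    return (df["hdl"] * MGDL_TO_MMOL_CHOL - 1.3) / 0.3


_TRANSFORMS: dict[str, tuple[tuple[str, ...], Callable]] = {
    "cage": (("age",), lambda d: (d["age"] - 55.0) / 10.0),
    "cnhdl": (("total_chol", "hdl"), _nhdl),
    "chdl": (("hdl",), _chdl),
    "csbp_lt110": (("systolic_bp",),
                   lambda d: (np.minimum(d["systolic_bp"], 110.0) - 110.0) / 20.0),
    "csbp_ge110": (("systolic_bp",),
                   lambda d: (np.maximum(d["systolic_bp"], 110.0) - 130.0) / 20.0),
    "diabetes": (("diabetes",), lambda d: d["diabetes"].astype(float)),
    "smoker": (("current_smoker",), lambda d: d["current_smoker"].astype(float)),
    "cegfr_lt60": (("egfr",),
                   lambda d: (np.minimum(d["egfr"], 60.0) - 60.0) / -15.0),
    "cegfr_ge60": (("egfr",),
                   lambda d: (np.maximum(d["egfr"], 60.0) - 90.0) / -15.0),
    "bptx": (("antihypertensive_use",),
             lambda d: d["antihypertensive_use"].astype(float)),
    "statin": (("lipid_lowering_use",),
               lambda d: d["lipid_lowering_use"].astype(float)),
    "cbmi_lt30": (("bmi",), lambda d: (np.minimum(d["bmi"], 30.0) - 25.0) / 5.0),
    "cbmi_ge30": (("bmi",), lambda d: (np.maximum(d["bmi"], 30.0) - 30.0) / 5.0),
    "hba1c_dm": (("hba1c", "diabetes"),
                 lambda d: (d["hba1c"] - 5.3) * d["diabetes"].astype(float)),
    "hba1c_nodm": (("hba1c", "diabetes"),
                   lambda d: (d["hba1c"] - 5.3) * (1.0 - d["diabetes"].astype(float))),
    "cadi_decile": (("adi_percentile",),
                    lambda d: np.ceil(d["adi_percentile"] / 10.0) - 5.5),
    # PCE (log-scale predictors; treated/untreated SBP split on therapy flag)
    "ln_age": (("age",), lambda d: np.log(d["age"])),
    "ln_age_sq": (("age",), lambda d: np.log(d["age"]) ** 2),
    "ln_tc": (("total_chol",), lambda d: np.log(d["total_chol"])),
    "ln_age_x_ln_tc": (("age", "total_chol"),
                       lambda d: np.log(d["age"]) * np.log(d["total_chol"])),
    "ln_hdl": (("hdl",), lambda d: np.log(d["hdl"])),
    "ln_age_x_ln_hdl": (("age", "hdl"),
                        lambda d: np.log(d["age"]) * np.log(d["hdl"])),
    "ln_sbp_tx": (("systolic_bp", "antihypertensive_use"),
                  lambda d: np.log(d["systolic_bp"])
                  * d["antihypertensive_use"].astype(float)),
    "ln_sbp_untx": (("systolic_bp", "antihypertensive_use"),
                    lambda d: np.log(d["systolic_bp"])
                    * (1.0 - d["antihypertensive_use"].astype(float))),
    "ln_age_x_ln_sbp_tx": (("age", "systolic_bp", "antihypertensive_use"),
                           lambda d: np.log(d["age"]) * np.log(d["systolic_bp"])
                           * d["antihypertensive_use"].astype(float)),
    "ln_age_x_ln_sbp_untx": (("age", "systolic_bp", "antihypertensive_use"),
                             lambda d: np.log(d["age"]) * np.log(d["systolic_bp"])
                             * (1.0 - d["antihypertensive_use"].astype(float))),
    "ln_age_x_smoker": (("age", "current_smoker"),
                        lambda d: np.log(d["age"]) * d["current_smoker"].astype(float)),
}

# Interaction terms of the PREVENT family expressed as products of the above.
for _a, _b in [("bptx", "csbp_ge110"), ("statin", "cnhdl"),
               ("cage", "cnhdl"), ("cage", "chdl"), ("cage", "csbp_ge110"),
               ("cage", "diabetes"), ("cage", "smoker"),
               ("cage", "cegfr_lt60"), ("cage", "cbmi_ge30")]:
    _fa, _ga = _TRANSFORMS[_a]
    _fb, _gb = _TRANSFORMS[_b]
    _TRANSFORMS[f"{_a}_x_{_b}"] = (
        tuple(dict.fromkeys(_fa + _fb)),
        (lambda ga, gb: lambda d: np.asarray(ga(d)) * np.asarray(gb(d)))(_ga, _gb),
    )


# ---------------------------------------------------------------------------
# Valid input ranges (closed intervals), per calculator, from the source
# publications' stated input domains.  Subjects with any present predictor
# outside the relevant range are excluded from risk calculation.
# ---------------------------------------------------------------------------

_PREVENT_RANGES = {
    "age": (30.0, 79.0),
    "total_chol": (130.0, 320.0),
    "hdl": (20.0, 100.0),
    "systolic_bp": (90.0, 200.0),
    "egfr": (15.0, 140.0),
}
_PREVENT_BMI_RANGE = (18.5, 39.9)
_PREVENT_HBA1C_RANGE = (4.5, 15.0)
_PCE_RANGES = {
    "age": (40.0, 79.0),
    "total_chol": (130.0, 320.0),
    "hdl": (20.0, 100.0),
    "systolic_bp": (90.0, 200.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One published risk equation: coefficient table + link metadata."""

    calculator: str  # 'PREVENT' | 'PCE'
    outcome: str     # 'overall_cvd' | 'ascvd' | 'heart_failure'
    sex: str         # 'female' | 'male'
    variant: str = "base"  # 'base' | 'adi' | 'hba1c'
    race_arm: Optional[str] = None  # PCE only: 'white' | 'black'
    terms: tuple = ()  # ordered ((transform_id, coefficient), ...)
    intercept: float = 0.0
    link: str = "logistic"  # 'logistic' | 'baseline_survival'
    baseline_survival: Optional[float] = None
    mean_linear_predictor: Optional[float] = None
    valid_ranges: Mapping[str, tuple] = field(default_factory=dict)
    source_version: str = ""

    def __post_init__(self):
        if self.link == "logistic":
            if self.baseline_survival is not None:
                raise ConfigError("logistic link takes no baseline survival")
        elif self.link == "baseline_survival":
            if self.baseline_survival is None or self.mean_linear_predictor is None:
                raise ConfigError(
                    "baseline_survival link requires S0 and mean linear predictor")
            if not 0.0 < self.baseline_survival < 1.0:
                raise ConfigError("S0 must lie in (0, 1)")
        else:
            raise ConfigError(f"unknown link {self.link!r}")
        for t, _ in self.terms:
            if t not in _TRANSFORMS:
                raise ConfigError(f"unknown transform {t!r}")

    @property
    def required_fields(self) -> tuple:
        seen: dict[str, None] = {}
        for t, _ in self.terms:
            for f in _TRANSFORMS[t][0]:
                seen[f] = None
        return tuple(seen)


# ---------------------------------------------------------------------------
# Coefficient-table loading
# ---------------------------------------------------------------------------

_DATA_FILES = ("prevent_base_coefficients.csv", "pce_coefficients.csv",
               "prevent_addon_terms_synthetic.csv")
_META_TERMS = ("_intercept_", "_mean_lp_", "_s0_")
_table_cache: dict[str, pd.DataFrame] = {}


def _data_path(name: str):
    return resources.files("cvriskval.data") / name


def coefficient_table_version() -> str:
    """Short fingerprint of the bundled coefficient tables (for provenance)."""
    h = hashlib.sha256()
    for name in _DATA_FILES:
        h.update(_data_path(name).read_bytes())
    return h.hexdigest()[:12]


def _load_tables(path: Optional[str] = None) -> pd.DataFrame:
    if path is not None:
        return pd.read_csv(path, dtype={"race_arm": "string"})
    if "bundled" not in _table_cache:
        checks = json.loads(_data_path("checksums.json").read_text())
        frames = []
        for name in _DATA_FILES:
            raw = _data_path(name).read_bytes()
            digest = hashlib.sha256(raw).hexdigest()
            if checks.get(name) != digest:
                raise ConfigError(f"coefficient table {name} fails checksum")
            frames.append(pd.read_csv(_data_path(name), dtype={"race_arm": "string"}))
        _table_cache["bundled"] = pd.concat(frames, ignore_index=True)
    return _table_cache["bundled"]


def available_models(path: Optional[str] = None) -> pd.DataFrame:
    """Distinct (calculator, outcome, sex, variant, race_arm) combinations."""
    t = _load_tables(path)
    base = (t[t["variant"] == "base"]
            [["calculator", "outcome", "sex", "variant", "race_arm"]]
            .drop_duplicates())
    addons = (t[t["variant"] != "base"]
              [["calculator", "outcome", "sex", "variant", "race_arm"]]
              .drop_duplicates())
    return pd.concat([base, addons], ignore_index=True)


def load_model(calculator: str, outcome: str, sex: str, variant: str = "base",
               race_arm: Optional[str] = None,
               path: Optional[str] = None) -> ModelSpec:
    """Build a :class:`ModelSpec` from the bundled (or user-supplied) tables.

    PREVENT add-on variants ('adi', 'hba1c') are the base coefficient set
    plus the variant's add-on terms; the three variants are loaded as
    distinct specs and never silently substituted for one another.
    """
    t = _load_tables(path)
    sel = (t["calculator"] == calculator) & (t["outcome"] == outcome) \
        & (t["sex"] == sex)
    if calculator == "PCE":
        arm = race_arm or "white"
        rows = t[sel & (t["variant"] == "base") & (t["race_arm"] == arm)]
        if rows.empty:
            raise ConfigError(
                f"no PCE model for outcome={outcome} sex={sex} race_arm={arm}")
        meta = dict(zip(rows["term"], rows["coefficient"]))
        terms = tuple((r.term, float(r.coefficient)) for r in rows.itertuples()
                      if r.term not in _META_TERMS)
        return ModelSpec(
            calculator="PCE", outcome=outcome, sex=sex, variant="base",
            race_arm=arm, terms=terms, intercept=float(meta["_intercept_"]),
            link="baseline_survival",
            baseline_survival=float(meta["_s0_"]),
            mean_linear_predictor=float(meta["_mean_lp_"]),
            valid_ranges=dict(_PCE_RANGES),
            source_version=coefficient_table_version() if path is None else "user",
        )
    if calculator != "PREVENT":
        raise ConfigError(f"unknown calculator {calculator!r}")
    base_rows = t[sel & (t["variant"] == "base")]
    if base_rows.empty:
        raise ConfigError(f"no PREVENT model for outcome={outcome} sex={sex}")
    terms = [(r.term, float(r.coefficient)) for r in base_rows.itertuples()
             if r.term != "_intercept_"]
    intercept = float(
        base_rows.loc[base_rows["term"] == "_intercept_", "coefficient"].iloc[0])
    if variant != "base":
        addon = t[sel & (t["variant"] == variant)]
        if addon.empty:
            raise ConfigError(
                f"no PREVENT {variant!r} add-on for outcome={outcome} sex={sex}")
        terms += [(r.term, float(r.coefficient)) for r in addon.itertuples()]
    ranges = dict(_PREVENT_RANGES)
    if outcome == "heart_failure":
        ranges["bmi"] = _PREVENT_BMI_RANGE
    if variant == "hba1c":
        ranges["hba1c"] = _PREVENT_HBA1C_RANGE
    return ModelSpec(
        calculator="PREVENT", outcome=outcome, sex=sex, variant=variant,
        terms=tuple(terms), intercept=intercept, link="logistic",
        valid_ranges=ranges,
        source_version=coefficient_table_version() if path is None else "user",
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _as_frame(profile) -> tuple[pd.DataFrame, bool]:
    if isinstance(profile, RiskProfile):
        return profile.to_frame(), True
    return profile, False


def linear_predictor(profile, spec: ModelSpec):
    """intercept + sum(coefficient * transform(profile)); deterministic.

    Raises :class:`MissingDataError` naming the field(s) if any predictor
    required by ``spec`` is absent.
    """
    df, scalar = _as_frame(profile)
    missing = [f for f in spec.required_fields
               if f not in df.columns or pd.isna(df[f]).any()]
    if missing:
        raise MissingDataError(missing)
    lp = np.full(len(df), spec.intercept, dtype=float)
    for term, coef in spec.terms:
        lp += coef * np.asarray(_TRANSFORMS[term][1](df), dtype=float)
    return float(lp[0]) if scalar else lp


def predicted_risk(profile, spec: ModelSpec):
    """10-year event probability under the spec's link function.

    logistic: 1 / (1 + exp(-lp)); baseline survival (PCE):
    1 - S0 ** exp(lp - mean_lp).
    """
    lp = linear_predictor(profile, spec)
    lp_a = np.asarray(lp, dtype=float)
    if spec.link == "logistic":
        p = 1.0 / (1.0 + np.exp(-lp_a))
    else:
        p = 1.0 - spec.baseline_survival ** np.exp(
            lp_a - spec.mean_linear_predictor)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(lp) else p


def classify_risk(p):
    """Treatment-decision category of a 10-year risk.

    '<7.5%' -> low_borderline, '7.5%-19.9%' -> intermediate,
    '>=20%' -> high.  Vectorized over arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise InvalidInputError("risk must lie in [0, 1]")
    out = np.where(arr >= 0.20, "high",
                   np.where(arr >= 0.075, "intermediate", "low_borderline"))
    return str(out[()]) if arr.ndim == 0 else out


def screen_validity(profile, spec: ModelSpec):
    """Valid-range screen before risk calculation.

    Returns ``(eligible, reasons)``: for a single profile a bool and a
    list of human-readable violations; for a DataFrame a boolean Series
    and a list-of-lists aligned to rows.  Missing values are never range
    violations (they go to imputation instead).
    """
    df, scalar = _as_frame(profile)
    ok = np.ones(len(df), dtype=bool)
    reasons: list[list[str]] = [[] for _ in range(len(df))]
    for fld, (lo, hi) in spec.valid_ranges.items():
        if fld not in df.columns:
            continue
        v = pd.to_numeric(df[fld], errors="coerce").to_numpy(dtype=float)
        bad = (~np.isnan(v)) & ((v < lo) | (v > hi))
        ok &= ~bad
        for i in np.flatnonzero(bad):
            reasons[i].append(f"{fld}={v[i]:g} outside [{lo:g}, {hi:g}]")
    if scalar:
        return bool(ok[0]), reasons[0]
    return pd.Series(ok, index=df.index), reasons
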