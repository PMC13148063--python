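"""Multiple imputation by chained equations for risk-calculator inputs.

Missing calculator inputs are imputed with chained equations (predictive
mean matching within each conditional model, Gaussian parameter
perturbation between cycles), producing ``m`` completed cohorts; the
10-year risk for a subject is then the arithmetic mean of their ``m``
per-completion risks on the probability scale.  Note that the mean of
probabilities is not the probability of the mean log-odds — averaging is
deliberately done on the scale on which risks are reported.

The chained-equation engine is statsmodels' ``MICEData``; imputations are
taken as thinned snapshots of a single chain (``iterations`` full cycles
between snapshots).  Predictors for each conditional model are all other
calculator inputs plus, when available, case/control status and the
event indicator (standard practice: the imputation model includes the
outcome).  Observed values are never altered; complete-case subjects'
risks are invariant to every imputation setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .risk_models import ModelSpec, predicted_risk, resolve_egfr

__all__ = ["ImputationConfig", "impute", "averaged_risk", "risk_with_imputation"]

#: Calculator inputs eligible for imputation (numeric encodings).
IMPUTABLE_FIELDS = [
    "systolic_bp", "diastolic_bp", "total_chol", "ldl", "hdl", "bmi",
    "serum_creatinine", "hba1c", "adi_percentile",
    "current_smoker", "diabetes", "antihypertensive_use",
    "lipid_lowering_use", "aspirin_use",
]
#: Auxiliary predictors included in every chained model when present.
AUXILIARY_FIELDS = ["age", "is_case", "event"]

#: Clipping bounds applied to imputed values that fall outside plausible
#: input ranges (observed values are never clipped).
_IMPUTE_BOUNDS = {
    "systolic_bp": (90.0, 200.0), "diastolic_bp": (40.0, 130.0),
    "total_chol": (130.0, 320.0), "ldl": (30.0, 250.0),
    "hdl": (20.0, 100.0), "bmi": (15.0, 55.0),
    "serum_creatinine": (0.2, 10.0), "hba1c": (4.5, 15.0),
    "adi_percentile": (1.0, 100.0),
}


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the chained-equation imputer.

    ``m`` imputations (default 10), ``iterations`` chain cycles between
    snapshots (default 10), predictive-mean-matching donor pool ``k_pmm``.
    """

    m: int = 10
    iterations: int = 10
    k_pmm: int = 20
    seed: int = 0
    fields: Sequence[str] = tuple(IMPUTABLE_FIELDS)

    def __post_init__(self):
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")


def impute(cohort: pd.DataFrame, config: ImputationConfig = ImputationConfig(),
           event_col: Optional[str] = None) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of ``cohort``.

    Only the configured calculator-input fields are imputed; all other
    columns (including any remaining missingness outside the field list)
    pass through untouched.  Columns that are entirely missing are a
    configuration error.  Deterministic given ``config.seed``.
    """
    fields = [f for f in config.fields if f in cohort.columns]
    all_missing = [f for f in fields if cohort[f].isna().all()]
    if all_missing:
        raise ConfigError(f"column(s) entirely missing: {all_missing}")
    work_cols = fields + [a for a in AUXILIARY_FIELDS if a in cohort.columns]
    if (event_col is not None and event_col in cohort.columns
            and event_col not in work_cols):
        work_cols.append(event_col)
    work = cohort[work_cols].astype(float).copy()
    work.index = pd.RangeIndex(len(work))

    if not work[fields].isna().any().any():
        return [cohort.copy() for _ in range(config.m)]

    from statsmodels.imputation.mice import MICEData

    # statsmodels draws from the global numpy RNG; pin it for determinism
    state = np.random.get_state()
    np.random.seed(config.seed % (2 ** 31))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = MICEData(work, k_pmm=config.k_pmm)
            completed = []
            for _ in range(config.m):
                md.update_all(config.iterations)
                snap = md.data[fields].copy()
                completed.append(snap)
    finally:
        np.random.set_state(state)

    out = []
    clipped_total = 0
    for snap in completed:
        c = cohort.copy()
        for f in fields:
            vals = snap[f].to_numpy(dtype=float)
            was_missing = cohort[f].isna().to_numpy()
            if f in _IMPUTE_BOUNDS:
                lo, hi = _IMPUTE_BOUNDS[f]
                bad = was_missing & ((vals < lo) | (vals > hi))
                clipped_total += int(bad.sum())
                vals = np.where(was_missing, np.clip(vals, lo, hi), vals)
            if f in ("current_smoker", "diabetes", "antihypertensive_use",
                     "lipid_lowering_use", "aspirin_use"):
                vals = np.where(was_missing, np.round(np.clip(vals, 0, 1)), vals)
            c[f] = np.where(was_missing, vals,
                            cohort[f].to_numpy(dtype=float))
        if "serum_creatinine" in fields:
            c["egfr"] = resolve_egfr(c)
        out.append(c)
    if clipped_total:
        warnings.warn(f"{clipped_total} imputed value(s) clipped to valid "
                      "ranges", stacklevel=2)
    return out


def averaged_risk(completed_cohorts: Sequence[pd.DataFrame],
                  spec: ModelSpec) -> np.ndarray:
    """Per-subject mean predicted risk over the completed cohorts.

    Averaging is on the probability scale (the scale on which the risk
    score is reported), not on log-odds.
    """
    if not completed_cohorts:
        raise ConfigError("need at least one completed cohort")
    risks = np.stack([
        np.asarray(predicted_risk(c, spec), dtype=float)
        for c in completed_cohorts])
    return risks.mean(axis=0)


def risk_with_imputation(cohort: pd.DataFrame, spec: ModelSpec,
                         config: ImputationConfig = ImputationConfig(),
                         event_col: Optional[str] = None) -> np.ndarray:
    """Impute, then average risks: the standard path from raw cohort to risk."""
    completed = impute(cohort, config, event_col=event_col)
    return averaged_risk(completed, spec)
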