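"""End-to-end orchestration: config -> cohort -> risks -> validation tables.

A run generates (or loads) a matched cohort, simulates planted-truth
outcomes per outcome family, imputes missing calculator inputs (or
restricts to complete cases), computes averaged risks for each calculator
variant, and writes the result tables: baseline characteristics,
per-variant calibration/discrimination, reclassification against the
PCE, calibration bins, and stratified SIRs, plus a provenance log
(config echo, seeds, coefficient-table fingerprint).  Identical seeds
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .cohort import screen_eligibility, write_cohort_csv
from .errors import ConfigError
from .imputation import ImputationConfig, averaged_risk, impute
from .risk_models import (coefficient_table_version, load_model,
                          predicted_risk, resolve_egfr, screen_validity)
from .synthetic_data import (OutcomeModel, default_covariate_model,
                             generate_profiles, simulate_outcomes)
from .validation import StratumSpec, nri, validate

__all__ = ["RunConfig", "run_pipeline", "compute_risk", "baseline_table"]

#: Planted observed-to-predicted ratios mirroring the published standard-
#: calculator validation results (cases vs controls, per outcome family),
#: so a demo run reproduces the reported calibration pattern out of the box.
DEFAULT_KAPPA = {
    "case": {"overall_cvd": 1.83, "ascvd": 2.25, "heart_failure": 1.41},
    "control": {"overall_cvd": 1.44, "ascvd": 1.86, "heart_failure": 0.89},
}

VARIANTS = (("PREVENT", "base"), ("PREVENT", "adi"), ("PREVENT", "hba1c"),
            ("PCE", "base"))


class RunConfig(BaseModel):
    """Structured run configuration; every seed is explicit and echoed."""

    n_cases: int = 2000
    control_ratio: int = 10
    outcomes: list[str] = ["overall_cvd", "ascvd", "heart_failure"]
    strata: list[str] = ["none"]
    cutoff: float = 0.075
    complete_case: bool = False
    m_imputations: int = 10
    imputation_iterations: int = 10
    n_boot: int = 100
    kappa: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_KAPPA.items()})
    truth_variant: str = "base"
    predicted_risk_cap: float = 0.40
    noncvd_death_rate: float = 0.015
    admin_censor: Optional[tuple[float, float]] = (4.0, 14.0)
    seed_generation: int = 20060101
    seed_outcomes: int = 20120101
    seed_imputation: int = 20150101
    seed_bootstrap: int = 20190101
    out_dir: str = "cvriskval_run"
    compute_c: bool = True

    @field_validator("cutoff")
    @classmethod
    def _cutoff_open_unit(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")
        return v


def compute_risk(df: pd.DataFrame, calculator: str, outcome: str,
                 variant: str = "base"):
    """Vectorized per-subject risk for a sex- (and race-) stratified model.

    Profiles with race 'other' or 'missing' are evaluated with the
    white-race PCE arm; the substitution count is returned alongside.
    eGFR is recomputed from creatinine wherever creatinine is present.
    """
    work = df.copy()
    work["egfr"] = resolve_egfr(work)
    risks = pd.Series(np.nan, index=work.index, dtype=float)
    substitutions = 0
    for sex in ("female", "male"):
        sub = work[work["sex"] == sex]
        if sub.empty:
            continue
        if calculator == "PCE":
            race = sub["race"].fillna("missing") if "race" in sub else \
                pd.Series("missing", index=sub.index)
            for arm in ("white", "black"):
                if arm == "white":
                    m = race != "black"
                    substitutions += int((~race.isin(["white", "black"])
                                          & m).sum())
                else:
                    m = race == "black"
                part = sub[m]
                if part.empty:
                    continue
                spec = load_model("PCE", outcome, sex, race_arm=arm)
                risks.loc[part.index] = predicted_risk(part, spec)
        else:
            spec = load_model(calculator, outcome, sex, variant)
            risks.loc[sub.index] = predicted_risk(sub, spec)
    return risks, {"pce_white_arm_substitutions": substitutions}


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table by case/control group."""
    rows = []
    for label, grp in (("RA", cohort[cohort["is_case"] == 1]),
                       ("non-RA", cohort[cohort["is_case"] == 0])):
        if grp.empty:
            continue
        r = {"group": label, "n": len(grp)}
        for f in ("age", "systolic_bp", "diastolic_bp", "total_chol", "ldl",
                  "hdl", "bmi", "egfr"):
            r[f"{f}_mean"] = round(float(grp[f].mean()), 2)
            r[f"{f}_sd"] = round(float(grp[f].std()), 2)
        r["male_pct"] = round(100 * float((grp["sex"] == "male").mean()), 1)
        for f in ("diabetes", "antihypertensive_use", "lipid_lowering_use",
                  "aspirin_use"):
            r[f"{f}_pct"] = round(100 * float(grp[f].mean()), 1)
        r["current_smoker_pct"] = round(
            100 * float(grp["current_smoker"].mean()), 1)
        rows.append(r)
    return pd.DataFrame(rows)


def _results_frame(results: dict, calculator, variant, outcome) -> pd.DataFrame:
    rows = []
    for group, by_stratum in results.items():
        for res in by_stratum.values():
            row = {"calculator": calculator, "variant": variant,
                   "outcome": outcome, "group": group}
            row.update(res.to_row())
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, cohort: Optional[pd.DataFrame] = None):
    """Execute a full validation run; returns the summary dict.

    Stages: generate/load -> eligibility -> planted outcomes -> imputation
    (or complete-case) -> per-variant risks -> validity screen -> stratified
    validation -> reclassification vs PCE -> artifact files under
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = default_covariate_model()
    if cohort is None:
        cohort, complete = generate_profiles(
            model, config.n_cases, config.control_ratio,
            config.seed_generation)
    else:
        complete = cohort.copy()
    cohort, exclusion_log = screen_eligibility(cohort)
    complete = complete.loc[cohort.index]
    cohort = cohort.reset_index(drop=True)
    complete = complete.reset_index(drop=True)

    # planted truth: events per family from kappa x truth-variant risk,
    # computed on the complete (pre-missingness) covariates
    followups = {}
    truth_rows = {}
    for fam_i, fam in enumerate(config.outcomes):
        truth_calc = "PREVENT"
        risks_true, _ = compute_risk(complete, truth_calc, fam,
                                     config.truth_variant)
        risks_true = np.minimum(risks_true.to_numpy(float),
                                config.predicted_risk_cap)
        kap = np.where(
            complete["is_case"].to_numpy(float) == 1,
            config.kappa["case"][fam], config.kappa["control"][fam])
        max_k = float(np.max(kap))
        om = OutcomeModel(
            calibration_ratio=1.0,  # ratio folded into risks below
            noncvd_death_rate=config.noncvd_death_rate,
            admin_censor=config.admin_censor,
            predicted_risk_cap=1.0, risk_truncation_cap=0.95)
        fu = simulate_outcomes(np.clip(kap * risks_true, 0, 0.95 - 1e-9),
                               om, config.seed_outcomes + fam_i, fam)
        followups[fam] = fu
        truth_rows[fam] = pd.DataFrame({
            "id": complete["id"], "family": fam, "kappa": kap,
            "true_prob": fu["true_prob"]})

    # analysis side: imputation or complete-case on the masked cohort
    if config.complete_case:
        from .imputation import IMPUTABLE_FIELDS
        fields = [f for f in IMPUTABLE_FIELDS if f in cohort.columns]
        keep = cohort[fields].notna().all(axis=1)
        analysis_sets = [cohort.loc[keep].reset_index(drop=True)]
        analysis_index = np.flatnonzero(keep.to_numpy())
    else:
        icfg = ImputationConfig(m=config.m_imputations,
                                iterations=config.imputation_iterations,
                                seed=config.seed_imputation)
        work = cohort.copy()
        work["event"] = followups[config.outcomes[0]]["event"].to_numpy()
        analysis_sets = impute(work, icfg, event_col="event")
        analysis_index = np.arange(len(cohort))

    summary: dict = {
        "package_version": __version__,
        "coefficient_table_version": coefficient_table_version(),
        "config": json.loads(config.model_dump_json()),
        "n_generated": int(len(cohort)),
        "eligibility_exclusions": exclusion_log,
        "results": {},
        "reclassification": {},
    }

    table2_frames, calib_frames, strat_frames = [], [], []
    risks_by_variant: dict[tuple, np.ndarray] = {}
    eligible_by_variant: dict[tuple, np.ndarray] = {}
    for calculator, variant in VARIANTS:
        outcomes = ["ascvd"] if calculator == "PCE" else config.outcomes
        for fam in outcomes:
            per_set = [compute_risk(c, calculator, fam, variant)[0]
                       for c in analysis_sets]
            risks = np.minimum(
                np.stack([r.to_numpy(float) for r in per_set]).mean(axis=0),
                config.predicted_risk_cap)
            # valid ranges are shared across sexes; screen with one spec
            spec_f = load_model(calculator, fam, "female", variant,
                                race_arm="white" if calculator == "PCE" else None)
            ok, _ = screen_validity(analysis_sets[0], spec_f)
            eligible = ok.to_numpy() & ~np.isnan(risks)
            fu = followups[fam].iloc[analysis_index].reset_index(drop=True)
            coh = analysis_sets[0]
            key = (calculator, variant, fam)
            risks_by_variant[key] = risks
            eligible_by_variant[key] = eligible
            for axis in config.strata:
                res = {}
                for group, gmask in (
                        ("case", coh["is_case"].to_numpy(float) == 1),
                        ("control", coh["is_case"].to_numpy(float) == 0)):
                    m = eligible & gmask
                    if not m.any():
                        continue
                    res[group] = validate(
                        coh[m], risks[m], fu["time_years"].to_numpy()[m],
                        fu["event"].to_numpy()[m].astype(bool),
                        StratumSpec(axis), config.cutoff,
                        compute_c=config.compute_c)
                frame = _results_frame(res, calculator, variant, fam)
                frame.insert(0, "axis", axis)
                (table2_frames if axis == "none" else strat_frames).append(frame)
                if axis == "none":
                    for group, by_s in res.items():
                        for res_s in by_s.values():
                            if res_s.calibration_bins is not None:
                                cb = res_s.calibration_bins.copy()
                                cb.insert(0, "group", group)
                                cb.insert(0, "outcome", fam)
                                cb.insert(0, "variant", variant)
                                cb.insert(0, "calculator", calculator)
                                calib_frames.append(cb)
                    summary["results"]["/".join(key)] = {
                        g: {s: {k: (None if v is None or (
                            isinstance(v, float) and np.isnan(v)) else v)
                            for k, v in r.to_row().items()
                            if k not in ("stratum",)}
                            for s, r in by_s.items()}
                        for g, by_s in res.items()}

    # reclassification of PCE ASCVD risk by each PREVENT variant (cases)
    table3_rows = []
    pce_key = ("PCE", "base", "ascvd")
    if pce_key in risks_by_variant and "ascvd" in config.outcomes:
        coh = analysis_sets[0]
        fu = followups["ascvd"].iloc[analysis_index].reset_index(drop=True)
        case_mask = coh["is_case"].to_numpy(float) == 1
        for variant in ("base", "adi", "hba1c"):
            key = ("PREVENT", variant, "ascvd")
            if key not in risks_by_variant:
                continue
            m = (case_mask & eligible_by_variant[key]
                 & eligible_by_variant[pce_key])
            rec = nri(risks_by_variant[pce_key][m], risks_by_variant[key][m],
                      fu["event"].to_numpy()[m].astype(bool),
                      cutoff=config.cutoff, n_boot=config.n_boot,
                      seed=config.seed_bootstrap)
            table3_rows.append({
                "new_model": f"PREVENT_{variant}", "old_model": "PCE",
                "up_events": rec.up_events, "down_events": rec.down_events,
                "up_nonevents": rec.up_nonevents,
                "down_nonevents": rec.down_nonevents,
                "n_reclassified": rec.n_reclassified,
                "nri_pct": rec.nri, "nri_se_pct": rec.nri_se,
                "nri_lo_pct": rec.nri_ci[0], "nri_hi_pct": rec.nri_ci[1]})
            summary["reclassification"][f"PREVENT_{variant}_vs_PCE"] = \
                table3_rows[-1]

    # artifacts
    baseline_table(cohort).to_csv(out_dir / "table1_baseline.csv", index=False)
    pd.concat(table2_frames, ignore_index=True).to_csv(
        out_dir / "table2_validation.csv", index=False)
    if table3_rows:
        pd.DataFrame(table3_rows).to_csv(
            out_dir / "table3_reclassification.csv", index=False)
    if calib_frames:
        pd.concat(calib_frames, ignore_index=True).to_csv(
            out_dir / "calibration_bins.csv", index=False)
    if strat_frames:
        pd.concat(strat_frames, ignore_index=True).to_csv(
            out_dir / "stratified_validation.csv", index=False)
    write_cohort_csv(cohort, out_dir / "cohort.csv")
    pd.concat(truth_rows.values(), ignore_index=True).to_csv(
        out_dir / "truth_sidecar.csv", index=False)
    summary_text = json.dumps(summary, indent=2, sort_keys=True,
                              default=_json_default)
    (out_dir / "summary.json").write_text(summary_text + "\n")
    provenance = {
        "package_version": __version__,
        "coefficient_table_version": coefficient_table_version(),
        "config_sha256": hashlib.sha256(
            config.model_dump_json().encode()).hexdigest(),
        "seeds": {"generation": config.seed_generation,
                  "outcomes": config.seed_outcomes,
                  "imputation": config.seed_imputation,
                  "bootstrap": config.seed_bootstrap},
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
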