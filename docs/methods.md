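# Methods

`cvriskval` implements an external-validation study design for 10-year
cardiovascular risk calculators — the AHA PREVENT equations and the
Pooled Cohort Equations (PCE) — in a matched case/control cohort where
the cases carry an inflammatory condition (rheumatoid arthritis) that
elevates cardiovascular risk beyond what general-population calculators
capture. Because subject-level data of this kind are access-restricted,
the package pairs the validation machinery with a synthetic-cohort
generator whose ground truth is known by construction, so every
statistic can be verified by parameter recovery rather than by
comparison against unavailable records.

## Risk equations

**PREVENT.** Sex-specific logistic models for three outcome families
over 10 years: overall CVD (fatal and nonfatal myocardial infarction,
stroke, or heart failure), ASCVD (MI or stroke), and heart failure.
Predictors are age, non-HDL and HDL cholesterol, systolic blood
pressure (two-slope spline with a knot at 110 mm Hg), diabetes, current
smoking, eGFR (two-slope spline with a knot at 60), antihypertensive
and statin use, treatment and age interactions, and — for the heart
failure model — BMI (knot at 30 kg/m²). Risk is
`1 / (1 + exp(-lp))` with `lp = β₀ + Σ βᵢ xᵢ` on centered, rescaled
predictors. Coefficients live in `data/prevent_base_coefficients.csv`
and are sha256-pinned; the loader refuses a table that fails its
checksum. The engine is cross-checked in the test suite against
hand-summed log-odds written out term by term.

**Add-on variants.** Two optional predictor sets are supported:
a social-deprivation term (Area Deprivation Index national percentile,
entered per decile centered at 5.5) and HbA1c (centered at 5.3%, with
separate slopes by diabetes status). The shipped add-on coefficients
(`prevent_addon_terms_synthetic.csv`) are constructed stand-ins layered
on the base models — plausible magnitudes, not transcriptions of the
fully re-estimated published variant models; the file name and
docstrings mark them as synthetic. Every result in this package that
depends on them is a planted-truth recovery, which is insensitive to
the specific coefficient values; users validating real cohorts should
substitute transcribed variant tables via the user-override path of
`load_model(..., path=...)`.

**PCE.** Race- and sex-specific ASCVD model in baseline-survival form:
risk `= 1 − S₀^exp(lp − mean_lp)` on log-transformed predictors. The
transcribed tables reproduce the four published worked examples
(55-year-old, TC 213, HDL 50, SBP 120 untreated, nonsmoker,
nondiabetic → 5.3/6.1/2.1/3.0% by sex/race arm) to within printed
rounding. Subjects with race other/unknown are evaluated with the
white-race arm, and the substitution count is reported — a common
convention in external validation. The published baseline-survival form
is implemented as published rather than re-expressed as a logistic
model.

**eGFR.** The race-free CKD-EPI 2021 creatinine equation, continuous at
the sex-specific creatinine knot. When both creatinine and a reported
eGFR are present, eGFR is recomputed from creatinine for internal
consistency; a reported eGFR alone is used as-is.

**Valid ranges.** Before risk calculation, subjects with any *present*
predictor outside the calculator's published input domain are excluded
(PREVENT: age 30–79, TC 130–320, HDL 20–100, SBP 90–200 mm Hg, eGFR
15–140, BMI 18.5–39.9 for the HF model, HbA1c 4.5–15 for that variant;
PCE: age 40–79 and the same lipid/BP ranges). Missing values are never
range violations — they go to imputation.

**Risk categories.** Half-open treatment-decision bands on 10-year
risk: <7.5% low/borderline, 7.5–19.9% intermediate, ≥20% high. 7.5% and
20% belong to the upper band.

## Cohort semantics

Follow-up runs from cohort entry to the earliest of: an event of the
outcome family under analysis, death from a non-CVD cause, 10 years, or
the administrative end of study. An event from a *different* CVD family
does not terminate follow-up (cause-specific person-time); fatal CVD
events carry a cause tag so they route to the correct composite.
Matching is exact on (birth year, sex, enrollment year) with up to a
configurable number of controls per case, sampled uniformly without
replacement under the run seed; controls are never reused. Crude
incidence uses exact (Garwood, chi-square-quantile) Poisson intervals.

## Validation statistics

**Expected events and SIR.** Each subject contributes their predicted
probability `p` to E if the event occurred or follow-up reached the
10-year horizon, and `(t/10)·p` if censored event-free at `t` — the
proportional person-time reduction. SIR = O/E; O is treated as Poisson
with E fixed, giving exact 95% limits `χ²(0.025, 2O)/2E` and
`χ²(0.975, 2(O+1))/2E`. SIR > 1 means the calculator underestimates
risk. Under the generator's constant-hazard event times the
proportional reduction is first-order exact; the test suite
demonstrates both that the adjusted estimator is unbiased and that the
ablation skipping the reduction (full `p` for censored subjects,
inflating E) biases the SIR downward. The proportional rule is applied
literally: only event-free censored subjects are down-weighted;
subjects with events contribute full `p`.

**Sensitivity.** Among subjects who experience the outcome, the
fraction with predicted risk at or above the 7.5% cutoff.

**Harrell's C.** Authored pair-enumeration implementation: a pair is
comparable iff the member with the shorter follow-up had the event
(time ties with one event treat the censored member as longer; tied
event times are not comparable); tied risks count ½. Chunked O(n²),
exact. `lifelines`' concordance index serves as an independent
cross-check in the tests, never as the implementation.

**Calibration curves.** Equal-count bins of predicted risk; the
per-bin "observed" probability is `(O_bin/E_bin) × mean predicted`,
which keeps the curve consistent with the censoring-adjusted SIR. A
lowess smooth is attached for plotting. The polynomial-logistic
"calibration belt" is deliberately out of scope; binned curves are the
documented simplification.

**NRI.** Two-category net reclassification at the 7.5% cutoff:
`100·[(up_e − down_e)/n_events + (down_ne − up_ne)/n_nonevents]`, with
a Table-3-shaped count matrix. SE from 100 subject-level bootstrap
resamples (default); CI = estimate ± 1.96·SE, with a percentile option.
Event status is the observed (possibly censored) outcome dichotomy; a
censoring-aware (Kaplan–Meier) NRI is out of scope.

## Synthetic cohorts and the planted truth

Continuous covariates are drawn from a Gaussian copula (default
rank-correlations: age–SBP 0.25, age–eGFR −0.35, SBP–DBP 0.60, TC–LDL
0.85, TC–HDL 0.15, BMI–SBP 0.15, age–BMI −0.05; any user matrix is
checked for positive semi-definiteness) with group-specific marginals
matching the study population's baseline table, lightly clipped to
physiologic ranges. Diabetes prevalence is tied to BMI through a logit
shift (0.30 per BMI SD); HbA1c is drawn conditionally on diabetes;
serum creatinine is obtained by inverting the CKD-EPI equation so the
generated eGFR and creatinine agree exactly. Controls share their
case's matching key (hence its age); their remaining covariates follow
control marginals. Missingness is injected after value generation —
MCAR per field by default (BMI 1.3%/23.5% case/control, smoking status
1.7%/14.3%, lipids 5%/12%, creatinine 4%/10%, HbA1c 30%/45%, blood
pressure 1%/3%, ADI 5%), with an optional MAR mode scaling the rates
with age. Lipid, creatinine, blood-pressure, HbA1c and ADI rates are
package defaults chosen to resemble routine-care laboratory capture;
they are not printed in the source baseline table.

The outcome model plants a known calibration ratio κ: the true 10-year
event probability is κ × predicted risk (predicted risk truncated at
0.40 by default; the same truncated risks must be passed to the
validation side). Event times are exponential within the window with
the 10-year cumulative probability matched to the target; non-CVD death
(exponential) and administrative censoring (uniform window) compete.
A κ·p exceeding the 0.95 cap raises an error rather than silently
clipping. Because truth is planted multiplicatively on whatever the
calculator predicts, SIR recovery is exact in expectation regardless of
coefficient provenance — that is what the acceptance runs measure.

What the generator does *not* emulate: calendar-time secular trends,
site effects, coding/adjudication noise, informative censoring, or
real covariate-outcome confounding beyond what the risk equations
encode. Passing recovery tests therefore demonstrates correctness of
the estimators and pipeline plumbing, not real-world calibration of the
calculators.

## Imputation

Chained equations via statsmodels' `MICEData`: predictive mean matching
(donor pool 20) with Gaussian parameter perturbation, m = 10 completed
datasets by default, taken as thinned snapshots of a single chain with
10 full cycles between snapshots. Each conditional model uses all other
calculator inputs plus case/control status and the event indicator
(standard practice includes the outcome in the imputation model).
Observed values are never altered; imputed values that land outside
plausible input ranges are clipped with a logged count; binary fields
are rounded to {0, 1}. Race is not imputed (the PCE white-arm
substitution handles unknown race). Per-subject risk is the arithmetic
mean of the m per-completion risks **on the probability scale** — the
mean of probabilities, deliberately not the inverse-logit of mean
log-odds (the two differ; a regression test pins the distinction).
Complete-case subjects' risks are invariant to every imputation
setting, and a `complete_case` pipeline flag bypasses imputation
entirely. Validation statistics are computed once on the averaged
risks; no Rubin's-rules pooling of the statistics themselves is
performed.

## Numerical and design choices

- Probabilities are computed and stored in [0, 1]; percent formatting
  is presentation-layer only.
- "Current smoker" means smoking status *current*; former and never
  both map to non-smoker, mirroring the calculators' predictor.
- Exact Poisson limits are used throughout rather than normal
  approximations; at large event counts the two coincide to printed
  precision.
- Degenerate inputs: constant risks collapse the calibration curve to
  one bin; empty strata are reported as empty rather than raised;
  statistics undefined on a stratum (no events, no comparable pairs)
  are reported as missing.
- All randomness flows through explicit seeds (generation, outcomes,
  imputation, bootstrap); reruns with identical configuration are
  byte-identical. The statsmodels imputer uses numpy's global RNG,
  which the imputation wrapper pins and restores.
- Problem sizes used by the shipped recovery runs: 30,000 subjects per
  planted-ratio run (Monte-Carlo SE of the SIR ≈ 0.03), 1,000
  replicates of n = 2,000 for CI coverage, n = 10,000 for the
  imputation-recovery check. These sizes put Monte-Carlo error well
  inside the tolerances being asserted while keeping a full run in the
  minutes range on one CPU.

## Known limitations

- The PREVENT base coefficients are transcribed without an independent
  machine-readable source to diff against; the bundled tables are
  checksummed and engine-verified against hand-computed examples, and
  the add-on variant terms are explicitly synthetic stand-ins.
- The 30-year PREVENT horizon, urine-albumin-based variants, non-US
  scores (SCORE2, QRISK), RA-specific multipliers, and the calibration
  belt are out of scope.
- The two-category NRI ignores censoring, matching the crude
  event/event-free dichotomy of the reclassification table it mirrors.
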