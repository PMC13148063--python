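"""Validation statistics against independent oracles and planted truth."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cvriskval.errors import (ConfigError, InvalidInputError,
                              UndefinedResultError)
from cvriskval.synthetic_data import OutcomeModel, simulate_outcomes
from cvriskval.validation import (StratumSpec, calibration_curve,
                                  expected_events, harrells_c, nri,
                                  sensitivity_at_cutoff, sir, validate)


class TestExpectedEvents:
    def test_censored_subject_contributes_proportionally(self):
        # p = 0.20 censored event-free at 5 y -> (5/10) * 0.20 = 0.10
        assert expected_events([0.2], [5.0], [False]) == pytest.approx(0.10)

    def test_event_subject_contributes_full_probability(self):
        assert expected_events([0.2], [3.0], [True]) == pytest.approx(0.20)

    def test_full_followup_sums_risks(self):
        p = np.array([0.1, 0.2, 0.3])
        assert expected_events(p, [10.0] * 3, [False] * 3) == \
            pytest.approx(p.sum())

    def test_monotone_in_time_and_risk(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.3, 50)
        t = rng.uniform(1, 10, 50)
        e = np.zeros(50, bool)
        base = expected_events(p, t, e)
        assert expected_events(p, np.minimum(t + 1, 10), e) >= base
        assert expected_events(p * 1.1, t, e) >= base

    def test_rejects_misaligned_or_bad_times(self):
        with pytest.raises(InvalidInputError):
            expected_events([0.1, 0.2], [5.0], [False])
        with pytest.raises(InvalidInputError):
            expected_events([0.1], [11.0], [False])


class TestSir:
    def test_point_estimate_is_ratio(self):
        s, _, _ = sir(183, 100.0)
        assert s == pytest.approx(1.83)

    def test_exact_ci_at_100_events(self):
        s, lo, hi = sir(100, 100.0)
        assert s == pytest.approx(1.0)
        assert lo == pytest.approx(0.814, abs=5e-4)
        assert hi == pytest.approx(1.216, abs=5e-4)

    def test_zero_count_upper_limit(self):
        s, lo, hi = sir(0, 50.0)
        assert s == 0.0 and lo == 0.0
        assert hi == pytest.approx(3.689 / 50, abs=1e-4)

    @pytest.mark.parametrize("O,E", [(3, 7.2), (57, 40.0), (411, 385.5)])
    def test_limits_match_gamma_quantile_oracle(self, O, E):
        # chi-square limits equal gamma quantiles: chi2(2k)/2 ~ Gamma(k, 1)
        _, lo, hi = sir(O, E)
        assert lo == pytest.approx(stats.gamma.ppf(0.025, O) / E, abs=1e-9)
        assert hi == pytest.approx(stats.gamma.ppf(0.975, O + 1) / E,
                                   abs=1e-9)

    def test_rejects_nonpositive_expected(self):
        with pytest.raises(InvalidInputError):
            sir(5, 0.0)


class TestSensitivity:
    def test_fraction_of_events_at_or_above_cutoff(self):
        risks = [0.05, 0.08, 0.10, 0.02]
        assert sensitivity_at_cutoff(risks, [True] * 4) == 0.5

    def test_all_events_captured(self):
        assert sensitivity_at_cutoff([0.2, 0.9], [True, True]) == 1.0

    def test_degenerate_zero_cutoff(self):
        assert sensitivity_at_cutoff([0.0, 0.5], [True, True], cutoff=0.0) \
            == 1.0

    def test_zero_events_undefined(self):
        with pytest.raises(UndefinedResultError):
            sensitivity_at_cutoff([0.1], [False])


def _c_oracle(risks, times, events):
    """Exhaustive pair enumeration with the stated comparability rules."""
    conc = ties = comp = 0.0
    for i, j in itertools.permutations(range(len(risks)), 2):
        shorter = times[i] < times[j] or (
            times[i] == times[j] and events[i] and not events[j])
        if not (shorter and events[i]):
            continue
        comp += 1
        if risks[i] > risks[j]:
            conc += 1
        elif risks[i] == risks[j]:
            ties += 1
    if comp == 0:
        return None
    return (conc + 0.5 * ties) / comp


class TestHarrellsC:
    def test_perfect_inverse_ranking_gives_one(self):
        assert harrells_c([0.9, 0.5, 0.1], [1.0, 2.0, 3.0],
                          [True] * 3) == 1.0

    def test_censoring_comparability_example(self):
        # pairs (1,2) and (1,3) comparable, both concordant -> 1.0
        c = harrells_c([0.3, 0.2, 0.1], [2.0, 5.0, 8.0],
                       [True, False, True])
        assert c == 1.0

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(5)
        n = 10_000
        c = harrells_c(rng.random(n), rng.random(n) * 10,
                       np.ones(n, bool))
        assert c == pytest.approx(0.5, abs=0.02)

    @given(st.integers(2, 8).flatmap(lambda n: st.tuples(
        st.lists(st.sampled_from([0.1, 0.2, 0.3, 0.5]), min_size=n,
                 max_size=n),
        st.lists(st.sampled_from([1.0, 2.0, 3.0, 4.0]), min_size=n,
                 max_size=n),
        st.lists(st.booleans(), min_size=n, max_size=n))))
    def test_equals_exhaustive_enumeration(self, data):
        risks, times, events = data
        oracle = _c_oracle(risks, times, events)
        if oracle is None:
            with pytest.raises(UndefinedResultError):
                harrells_c(risks, times, events)
        else:
            assert harrells_c(risks, times, events) == pytest.approx(
                oracle, abs=1e-12)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(11)
        n = 300
        risks = rng.random(n)
        times = rng.exponential(5, n)
        events = rng.random(n) < 0.7
        from lifelines.utils import concordance_index
        # lifelines ranks by predicted survival time: negate risk
        expected = concordance_index(times, -risks, events)
        assert harrells_c(risks, times, events) == pytest.approx(
            expected, abs=1e-12)


class TestCalibrationCurve:
    def test_planted_unit_ratio_lies_on_diagonal(self, small_cohort_risks):
        coh, risks = small_cohort_risks
        fu = simulate_outcomes(risks, OutcomeModel(calibration_ratio=1.0),
                               seed=2, family="overall_cvd")
        bins = calibration_curve(risks, fu["time_years"], fu["event"] == 1)
        ratio = bins["observed"] / bins["mean_predicted"]
        # each decile's observed/predicted near 1 within Monte-Carlo noise
        se = 1 / np.sqrt(bins["expected_events"])
        assert (np.abs(ratio - 1.0) < 3.5 * se).all()

    def test_planted_double_ratio_doubles_observed(self, small_cohort_risks):
        coh, risks = small_cohort_risks
        fu = simulate_outcomes(risks, OutcomeModel(calibration_ratio=2.0),
                               seed=3, family="overall_cvd")
        bins = calibration_curve(risks, fu["time_years"], fu["event"] == 1)
        ratio = bins["observed"] / bins["mean_predicted"]
        se = 2 / np.sqrt(bins["expected_events"])
        assert (np.abs(ratio - 2.0) < 3.5 * se).all()

    def test_constant_risks_collapse_to_single_bin(self):
        p = np.full(100, 0.1)
        t = np.full(100, 10.0)
        e = np.zeros(100, bool); e[:12] = True
        bins = calibration_curve(p, t, e)
        assert len(bins) == 1 and bins.loc[0, "n"] == 100

    def test_too_few_subjects_is_config_error(self):
        with pytest.raises(ConfigError):
            calibration_curve([0.1] * 5, [10.0] * 5, [False] * 5, n_bins=10)


class TestNri:
    def test_hand_computed_example(self):
        """2 up / 1 down of 10 events; 5 down / 3 up of 100 nonevents -> 12%."""
        e = np.array([True] * 10 + [False] * 100)
        old = np.full(110, 0.05)
        new = old.copy()
        new[[0, 1]] = 0.10          # events reclassified up
        old[2], new[2] = 0.10, 0.05  # event reclassified down
        old[10:15], new[10:15] = 0.10, 0.05  # nonevents down
        new[15:18] = 0.10            # nonevents up
        res = nri(old, new, e, n_boot=50, seed=0)
        assert res.nri == pytest.approx(12.0)
        assert (res.up_events, res.down_events) == (2, 1)
        assert (res.up_nonevents, res.down_nonevents) == (3, 5)
        # closed-form identity on the emitted counts
        assert res.nri == pytest.approx(100 * (
            (res.up_events - res.down_events) / res.n_events
            + (res.down_nonevents - res.up_nonevents) / res.n_nonevents))

    def test_identical_risks_give_zero(self):
        e = np.array([True] * 5 + [False] * 20)
        p = np.linspace(0.01, 0.3, 25)
        res = nri(p, p, e, n_boot=20, seed=0)
        assert res.nri == 0.0 and res.n_reclassified == 0

    def test_bootstrap_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        e = rng.random(200) < 0.3
        old, new = rng.random(200) * 0.3, rng.random(200) * 0.3
        a = nri(old, new, e, seed=9)
        b = nri(old, new, e, seed=9)
        assert a.nri_ci == b.nri_ci

    def test_bootstrap_se_stable_across_seeds(self):
        rng = np.random.default_rng(12)
        e = rng.random(500) < 0.3
        old, new = rng.random(500) * 0.3, rng.random(500) * 0.3
        ses = np.array([nri(old, new, e, n_boot=100, seed=s).nri_se
                        for s in (1, 2, 3)])
        assert (np.abs(ses - ses.mean()) / ses.mean() < 0.2).all()

    def test_requires_events_and_nonevents(self):
        with pytest.raises(UndefinedResultError):
            nri([0.1], [0.2], [True])


class TestValidate:
    def test_unstratified_equals_single_stratum(self, small_cohort_risks):
        coh, risks = small_cohort_risks
        fu = simulate_outcomes(risks, OutcomeModel(calibration_ratio=1.5),
                               seed=4, family="overall_cvd")
        t = fu["time_years"].to_numpy()
        e = fu["event"].to_numpy(bool)
        res = validate(coh, risks, t, e, StratumSpec("none"),
                       compute_c=False)
        assert list(res) == ["all"]
        assert res["all"].observed_events == int(e.sum())

    def test_per_stratum_observed_sums_to_overall(self, small_cohort_risks):
        coh, risks = small_cohort_risks
        fu = simulate_outcomes(risks, OutcomeModel(calibration_ratio=1.5),
                               seed=4, family="overall_cvd")
        t = fu["time_years"].to_numpy()
        e = fu["event"].to_numpy(bool)
        overall = validate(coh, risks, t, e, StratumSpec("none"),
                           compute_c=False)["all"]
        for axis in ("sex", "age65", "bmi_category", "ldl_quintile"):
            parts = validate(coh, risks, t, e, StratumSpec(axis),
                             compute_c=False)
            assert sum(r.observed_events for r in parts.values()) == \
                overall.observed_events
            assert sum(r.n for r in parts.values()) == overall.n

    def test_stratum_specific_planted_ratios_recovered(self,
                                                       small_cohort_risks):
        coh, risks = small_cohort_risks
        male = (coh["sex"] == "male").to_numpy()
        kap = np.where(male, 2.0, 1.0)
        fu = simulate_outcomes(
            np.clip(kap * risks, 0, 0.94),
            OutcomeModel(calibration_ratio=1.0, predicted_risk_cap=1.0),
            seed=6, family="overall_cvd")
        t = fu["time_years"].to_numpy()
        e = fu["event"].to_numpy(bool)
        res = validate(coh, risks, t, e, StratumSpec("sex"),
                       compute_c=False)
        for sex, target in (("male", 2.0), ("female", 1.0)):
            r = res[sex]
            se = np.sqrt(max(r.observed_events, 1)) / r.expected_events
            assert r.sir == pytest.approx(target, abs=3.5 * se)

    def test_sir_sign_tracks_planted_direction(self, small_cohort_risks):
        """SIR > 1 iff observed exceeds predicted (underestimation)."""
        coh, risks = small_cohort_risks
        for kappa, above in ((1.6, True), (0.6, False)):
            fu = simulate_outcomes(risks, OutcomeModel(
                calibration_ratio=kappa), seed=10, family="overall_cvd")
            res = validate(coh, risks, fu["time_years"].to_numpy(),
                           fu["event"].to_numpy(bool), compute_c=False)
            assert (res["all"].sir > 1.0) is above

    def test_missing_axis_forms_explicit_stratum(self, small_cohort_risks):
        coh, risks = small_cohort_risks
        coh = coh.copy()
        coh.loc[coh.index[:50], "ldl"] = np.nan
        fu = simulate_outcomes(risks, OutcomeModel(calibration_ratio=1.0),
                               seed=11, family="overall_cvd")
        res = validate(coh, risks, fu["time_years"].to_numpy(),
                       fu["event"].to_numpy(bool),
                       StratumSpec("ldl_quintile"), compute_c=False)
        assert "missing" in res and res["missing"].n == 50
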