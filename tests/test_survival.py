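"""Survival analysis: median split, Kaplan-Meier, log-rank, Cox models."""

import math

import numpy as np
import pytest
from scipy import stats

import oracles
from temporalis.phantom import CohortSpec, cohort_to_records, simulate_cohort
from temporalis.survival import (
    PatientRecord,
    cohort_characteristics,
    cox_fit,
    dichotomize_by_median,
    km_logrank,
)


def patient(i, csa, time, event, age=55.0, sex="male"):
    return PatientRecord(
        id=f"p{i}", csa_mm2=csa, age=age, sex=sex, time_months=time, event=event
    )


def toy_cohort(csas, times=None, events=None):
    n = len(csas)
    times = times or [10.0 + i for i in range(n)]
    events = events if events is not None else [1] * n
    return [patient(i, c, t, e) for i, (c, t, e) in enumerate(zip(csas, times, events))]


class TestDichotomize:
    def test_even_cohort_without_ties(self):
        cohort = toy_cohort([1.0, 2.0, 3.0, 4.0])
        res = dichotomize_by_median(cohort)
        assert res.median_csa_mm2 == 2.5
        assert res.n_low == 2 and res.n_high == 2
        assert res.group["p0"] == "low" and res.group["p3"] == "high"

    def test_45_distinct_values_split_22_23(self):
        rng = np.random.default_rng(8)
        csas = rng.normal(574, 117, 45)
        assert len(np.unique(csas)) == 45
        res = dichotomize_by_median(toy_cohort(list(csas)))
        # odd n: the median patient lands in the high group under the >= rule
        assert (res.n_low, res.n_high) == (22, 23)

    def test_opposite_tie_rule(self):
        rng = np.random.default_rng(9)
        csas = list(rng.normal(600, 100, 45))
        res = dichotomize_by_median(toy_cohort(csas), high_if_equal=False)
        assert (res.n_low, res.n_high) == (23, 22)

    def test_all_equal_is_degenerate_and_flagged(self):
        res = dichotomize_by_median(toy_cohort([500.0] * 6))
        assert res.n_high == 6 and res.n_low == 0
        assert "degenerate_split" in res.flags

    def test_groups_never_interleave(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            cohort = toy_cohort(list(rng.normal(550, 120, 31)))
            res = dichotomize_by_median(cohort)
            high = [p.csa_mm2 for p in cohort if res.group[p.id] == "high"]
            low = [p.csa_mm2 for p in cohort if res.group[p.id] == "low"]
            assert min(high) >= max(low)

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError):
            dichotomize_by_median(toy_cohort([1.0]))


class TestKaplanMeier:
    def test_worked_product_limit_example(self):
        """times {1, 2+, 3}: S(1) = 2/3 and S(3) = 0, computed by hand."""
        cohort = [
            patient(0, 400, 1.0, 1),
            patient(1, 450, 2.0, 0),
            patient(2, 480, 3.0, 1),
            patient(3, 700, 1.0, 1),
            patient(4, 720, 2.0, 0),
            patient(5, 740, 3.0, 1),
        ]
        groups = dichotomize_by_median(cohort)
        res = km_logrank(cohort, groups)
        for grp in res.groups.values():
            s_at = dict(zip(grp.times, grp.survival))
            assert s_at[1.0] == pytest.approx(2 / 3)
            assert s_at[3.0] == pytest.approx(0.0)
            assert grp.median_months == pytest.approx(3.0)

    def test_matches_hand_product_limit_on_simulated_data(self):
        cohort = cohort_to_records(simulate_cohort(CohortSpec(n_patients=40, seed=3)))
        groups = dichotomize_by_median(cohort)
        res = km_logrank(cohort, groups)
        for name in ("low", "high"):
            members = [p for p in cohort if groups.group[p.id] == name]
            want = oracles.km_product_limit(
                [p.time_months for p in members], [p.event for p in members]
            )
            got = dict(zip(res.groups[name].times, res.groups[name].survival))
            for t, s in want:
                assert got[t] == pytest.approx(s, abs=1e-9)

    def test_survival_curves_are_valid_step_functions(self):
        cohort = cohort_to_records(simulate_cohort(CohortSpec(n_patients=60, seed=4)))
        res = km_logrank(cohort, dichotomize_by_median(cohort))
        for grp in res.groups.values():
            assert grp.survival[0] <= 1.0 + 1e-12
            assert np.all(np.diff(grp.survival) <= 1e-12)
            assert np.all((grp.survival >= 0) & (grp.survival <= 1))

    def test_no_events_curve_stays_at_one_median_not_reached(self):
        cohort = toy_cohort([1, 2, 3, 4], events=[0, 0, 0, 0])
        res = km_logrank(cohort, dichotomize_by_median(cohort))
        for grp in res.groups.values():
            assert np.all(grp.survival == 1.0)
            assert math.isinf(grp.median_months)

    def test_identical_groups_give_logrank_p_near_one(self):
        base = [(10.0, 1), (15.0, 0), (20.0, 1), (25.0, 1), (30.0, 0)]
        cohort = []
        for i, (t, e) in enumerate(base):
            cohort.append(patient(2 * i, 400 + i, t, e))       # low group
            cohort.append(patient(2 * i + 1, 700 + i, t, e))   # high group
        res = km_logrank(cohort, dichotomize_by_median(cohort))
        assert res.logrank_p == pytest.approx(1.0, abs=1e-6)

    def test_logrank_p_uniform_under_null(self):
        """Under no group effect the log-rank p-value is ~Uniform(0,1)."""
        pvals = []
        for rep in range(200):
            spec = CohortSpec(n_patients=80, log_hr_high_vs_low=0.0,
                              censoring_rate_per_month=0.01, seed=1000 + rep)
            cohort = cohort_to_records(simulate_cohort(spec))
            res = km_logrank(cohort, dichotomize_by_median(cohort))
            pvals.append(res.logrank_p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestCox:
    def test_null_effect_recovers_hr_one(self):
        spec = CohortSpec(n_patients=600, log_hr_high_vs_low=0.0, seed=5)
        cohort = cohort_to_records(simulate_cohort(spec))
        groups = dichotomize_by_median(cohort)
        res = cox_fit(cohort, ("group",), groups)
        eff = res.effects["group"]
        assert eff.ci_low <= 1.0 <= eff.ci_high
        assert abs(eff.coef) < 3 * eff.se

    def test_parameter_recovery_within_three_se(self):
        spec = CohortSpec(n_patients=2000, log_hr_high_vs_low=math.log(0.5),
                          baseline_hazard_per_month=0.2, seed=6)
        cohort = cohort_to_records(simulate_cohort(spec))
        res = cox_fit(cohort, ("group",), dichotomize_by_median(cohort))
        eff = res.effects["group"]
        assert abs(eff.coef - math.log(0.5)) < 3 * eff.se
        assert eff.hazard_ratio == pytest.approx(math.exp(eff.coef))

    def test_toy_table_matches_partial_likelihood_grid_search(self):
        """Six patients, tie-free times, one binary covariate: the fitted
        coefficient must match exhaustive maximisation of the partial
        likelihood."""
        times = [3.0, 5.0, 7.0, 9.0, 12.0, 15.0]
        events = [1, 1, 1, 0, 1, 1]
        x = [1, 0, 1, 0, 1, 0]
        cohort = [
            patient(i, 700.0 if xi else 400.0, t, e)
            for i, (t, e, xi) in enumerate(zip(times, events, x))
        ]
        groups = dichotomize_by_median(cohort)
        res = cox_fit(cohort, ("group",), groups)
        want = oracles.cox_grid_coef(times, events, x)
        assert res.effects["group"].coef == pytest.approx(want, abs=2e-3)

    def test_multivariate_adjusts_for_age_and_sex(self):
        spec = CohortSpec(n_patients=400, seed=7)
        cohort = cohort_to_records(simulate_cohort(spec))
        res = cox_fit(cohort, ("group", "age", "sex"), dichotomize_by_median(cohort))
        assert res.model_type == "multivariate"
        assert set(res.effects) == {"group", "age", "sex"}
        for eff in res.effects.values():
            assert eff.ci_low <= eff.hazard_ratio <= eff.ci_high
            assert eff.hazard_ratio > 0

    def test_no_events_raises(self):
        cohort = toy_cohort([1, 2, 3, 4], events=[0, 0, 0, 0])
        with pytest.raises(ValueError, match="event"):
            cox_fit(cohort, ("group",), dichotomize_by_median(cohort))

    def test_constant_covariate_raises(self):
        cohort = [patient(i, 500.0, 10.0 + i, 1, sex="male") for i in range(6)]
        with pytest.raises(ValueError, match="sex"):
            cox_fit(cohort, ("sex",))


class TestCohortCharacteristics:
    def test_constructed_negative_correlation(self):
        rng = np.random.default_rng(11)
        ages = rng.uniform(30, 80, 500)
        cohort = [
            patient(i, 1000.0 - a + rng.normal(0, 2), 10.0, 1, age=a,
                    sex="male" if i % 2 else "female")
            for i, a in enumerate(ages)
        ]
        res = cohort_characteristics(cohort)
        assert res.pearson_r_csa_age < -0.95

    def test_simulator_sex_gap_recovered(self):
        spec = CohortSpec(n_patients=10_000, seed=12)
        res = cohort_characteristics(cohort_to_records(simulate_cohort(spec)))
        gap = res.csa_mean_male - res.csa_mean_female
        n_m = 10_000 * spec.male_fraction
        n_f = 10_000 - n_m
        se = math.sqrt(spec.csa_sd_male_mm2**2 / n_m + spec.csa_sd_female_mm2**2 / n_f)
        assert abs(gap - 135.0) < 3 * se
        assert res.ttest_p < 1e-10

    def test_single_sex_skips_ttest_with_notice(self):
        cohort = [patient(i, 500.0 + i, 10.0, 1, sex="male") for i in range(5)]
        res = cohort_characteristics(cohort)
        assert math.isnan(res.ttest_p)
        assert "ttest_skipped_single_sex" in res.notices

    def test_zero_variance_csa_notice(self):
        cohort = [
            patient(i, 500.0, 10.0, 1, age=40.0 + i, sex="male" if i % 2 else "female")
            for i in range(6)
        ]
        res = cohort_characteristics(cohort)
        assert math.isnan(res.pearson_r_csa_age)
        assert "pearson_undefined_zero_variance" in res.notices
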