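"""Exponential MLE fit, one-sided tests, dual decision, effect sizes, KM path."""

import itertools
import math
from math import erfc, sqrt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nisurv import (
    Conclusion,
    NonInferiorityMargin,
    SurvivalSummary,
    TrialData,
    decide_from_median_ci,
    dual_test,
    effect_sizes,
    fit_exponential,
    km_decision,
    one_sided_exponential_test,
)

LN2 = math.log(2.0)


def phi(z: float) -> float:
    return 0.5 * erfc(-z / sqrt(2.0))


class TestTrialData:
    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            TrialData(time=np.array([1.0, 0.0]), event=np.array([1, 0]))

    def test_rejects_bad_flags(self):
        with pytest.raises(ValueError):
            TrialData(time=np.array([1.0]), event=np.array([2]))

    def test_entry_validation_against_study_window(self):
        data = TrialData(
            time=np.array([30.0]), event=np.array([0]), entry=np.array([10.0])
        )
        with pytest.raises(ValueError):
            data.validate_against_study(accrual=12, followup=24)
        data.validate_against_study(accrual=12, followup=30)

    def test_dataframe_round_trip(self, metastatic_data):
        df = metastatic_data.to_dataframe()
        back = TrialData.from_dataframe(df)
        np.testing.assert_allclose(back.time, metastatic_data.time)
        np.testing.assert_array_equal(back.event, metastatic_data.event)


class TestFitExponential:
    def test_metastatic_final_analysis(self, metastatic_outcome):
        assert metastatic_outcome.events == 54
        assert metastatic_outcome.hazard_hat == pytest.approx(0.058, abs=5e-4)
        assert metastatic_outcome.median_hat == pytest.approx(12.0, rel=1e-12)

    def test_single_event_unit_time(self):
        out = fit_exponential(TrialData(np.array([1.0]), np.array([1])))
        assert out.hazard_hat == 1.0

    def test_mle_consistency_monte_carlo(self):
        lam = 0.05
        rng = np.random.default_rng(20230711)
        times = rng.exponential(1 / lam, 10_000)
        out = fit_exponential(TrialData(times, np.ones(10_000, dtype=int)))
        se = lam / sqrt(10_000)
        assert abs(out.hazard_hat - lam) < 3 * se

    def test_zero_events_directs_to_km(self):
        with pytest.raises(ValueError, match="Kaplan-Meier"):
            fit_exponential(TrialData(np.array([5.0, 6.0]), np.array([0, 0])))

    def test_invariant_to_order_and_exposure_split(self, metastatic_data):
        base = fit_exponential(metastatic_data)
        perm = np.random.default_rng(1).permutation(len(metastatic_data))
        shuffled = fit_exponential(
            TrialData(metastatic_data.time[perm], metastatic_data.event[perm])
        )
        assert shuffled.hazard_hat == pytest.approx(base.hazard_hat, rel=1e-12)
        # split each censored exposure in two: same total exposure and events
        t, e = [], []
        for ti, ei in zip(metastatic_data.time, metastatic_data.event):
            if ei:
                t.append(ti), e.append(1)
            else:
                t.extend([ti / 2, ti / 2]), e.extend([0, 0])
        split = fit_exponential(TrialData(np.array(t), np.array(e)))
        assert split.hazard_hat == pytest.approx(base.hazard_hat, rel=1e-12)


class TestOneSidedTest:
    def test_non_inferiority_p_value(self, metastatic_outcome):
        res = one_sided_exponential_test(metastatic_outcome, LN2 / 10)
        assert res.p_value == pytest.approx(0.0902, abs=5e-5)
        assert res.p_value < 0.1

    def test_superiority_p_value_exactly_half(self, metastatic_outcome):
        res = one_sided_exponential_test(metastatic_outcome, LN2 / 12)
        assert res.p_value == 0.5
        assert res.z_value == 0.0

    def test_against_trapezoid_normal_integration(self, metastatic_outcome):
        z = sqrt(54) * (math.log(LN2 / 10) - math.log(LN2 / 12))
        grid = np.linspace(z, z + 12, 200_001)
        dens = np.exp(-grid**2 / 2) / sqrt(2 * math.pi)
        p_oracle = np.trapezoid(dens, grid)
        res = one_sided_exponential_test(metastatic_outcome, LN2 / 10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-8)

    def test_p_half_at_null_for_any_event_count(self):
        for d in (1, 7, 40, 54, 200):
            out = fit_exponential(
                TrialData(np.full(d, 3.0), np.ones(d, dtype=int))
            )
            res = one_sided_exponential_test(out, out.hazard_hat)
            assert res.p_value == 0.5

    def test_p_decreasing_in_events_and_increasing_in_hazard(self):
        null = LN2 / 10
        lam_hat = LN2 / 12

        def p_at(d, lam):
            out = fit_exponential(TrialData(np.full(d, d / lam / d), np.ones(d, int)))
            # exposure d/lam gives hazard_hat exactly lam
            return one_sided_exponential_test(out, null).p_value

        ps_by_d = [p_at(d, lam_hat) for d in (10, 25, 54, 100, 300)]
        assert all(a > b for a, b in zip(ps_by_d, ps_by_d[1:]))
        ps_by_lam = [p_at(54, LN2 / m) for m in (16, 14, 12, 11, 10.5)]
        assert all(a < b for a, b in zip(ps_by_lam, ps_by_lam[1:]))


class TestDualTest:
    def test_metastatic_decision_is_non_inferior_only(
        self, metastatic_outcome, control12
    ):
        dec = dual_test(metastatic_outcome, control12, NonInferiorityMargin(1.2), 0.1)
        assert dec.conclusion is Conclusion.NON_INFERIOR_ONLY
        assert dec.ni_result.p_value < 0.1 <= dec.sup_result.p_value

    def test_clear_superiority(self, control12):
        out = fit_exponential(
            TrialData(np.full(100, 24 / LN2), np.ones(100, dtype=int))
        )
        dec = dual_test(out, control12, NonInferiorityMargin(1.2), 0.1)
        assert dec.conclusion is Conclusion.SUPERIOR
        assert dec.ni_result.p_value < 0.1 and dec.sup_result.p_value < 0.1

    def test_at_ni_boundary_inconclusive(self, control12):
        out = fit_exponential(
            TrialData(np.full(54, 10 / LN2), np.ones(54, dtype=int))
        )
        dec = dual_test(out, control12, NonInferiorityMargin(1.2), 0.1)
        assert dec.ni_result.p_value == 0.5
        assert dec.conclusion is Conclusion.INCONCLUSIVE
        assert dec.sup_result is None  # gate: superiority never tested

    @settings(derandomize=True, deadline=None)
    @given(
        st.integers(min_value=1, max_value=300),
        st.floats(min_value=2.0, max_value=40.0),
        st.floats(min_value=1.0, max_value=2.5),
    )
    def test_ni_p_never_exceeds_sup_p(self, d, median_hat, nim):
        out = fit_exponential(
            TrialData(np.full(d, (d * median_hat / LN2) / d), np.ones(d, int))
        )
        control = SurvivalSummary.from_median(12.0)
        p_ni = one_sided_exponential_test(out, control.hazard * nim).p_value
        p_sup = one_sided_exponential_test(out, control.hazard).p_value
        assert p_ni <= p_sup

    @settings(derandomize=True, deadline=None)
    @given(
        st.integers(min_value=1, max_value=200),
        st.floats(min_value=2.0, max_value=40.0),
    )
    def test_hierarchy_is_structural(self, d, median_hat):
        out = fit_exponential(
            TrialData(np.full(d, median_hat / LN2), np.ones(d, int))
        )
        dec = dual_test(out, SurvivalSummary.from_median(12.0), 1.2, 0.1)
        if dec.conclusion is Conclusion.SUPERIOR:
            assert dec.ni_result.p_value < 0.1
        if dec.conclusion is Conclusion.INCONCLUSIVE:
            assert dec.sup_result is None


class TestEffectSizes:
    def test_worked_values(self, metastatic_outcome, control12):
        es = effect_sizes(metastatic_outcome, control12, 1.2)
        assert es["superiority"]["median"] == pytest.approx(0.0, abs=1e-9)
        assert es["non_inferiority"]["median"] == pytest.approx(2.0)

    def test_median_18(self, control12):
        out = fit_exponential(TrialData(np.full(10, 18 / LN2), np.ones(10, int)))
        es = effect_sizes(out, control12, 1.2)
        assert es["superiority"]["median"] == pytest.approx(6.0)
        assert es["non_inferiority"]["median"] == pytest.approx(8.0)

    def test_ni_effect_dominates_when_median_reaches_control(self, control12):
        for median_hat in np.linspace(12.0, 40.0, 15):
            for nim in np.linspace(1.01, 2.0, 8):
                out = fit_exponential(
                    TrialData(np.full(5, median_hat / LN2), np.ones(5, int))
                )
                es = effect_sizes(out, control12, nim)
                assert abs(es["non_inferiority"]["median"]) > abs(
                    es["superiority"]["median"]
                )
                assert abs(es["non_inferiority"]["hazard"]) > abs(
                    es["superiority"]["hazard"]
                )


def brute_force_product_limit(times, events):
    """Independent product-limit oracle: S at each distinct observed time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    pts = np.unique(times)
    surv = {}
    s = 1.0
    for t in pts:
        at_risk = np.sum(times >= t)  # events precede censorings at ties
        d = np.sum((times == t) & (events == 1))
        if d:
            s *= 1 - d / at_risk
        surv[t] = s
    return surv


class TestKMDecision:
    def test_discussion_style_dataset(self, km_data):
        dec = km_decision(km_data, sup_threshold=4.0, ni_threshold=3.3, confidence=0.9)
        assert 3.3 < dec.ci_lower <= 4.0
        assert dec.conclusion is Conclusion.NON_INFERIOR_ONLY

    @pytest.mark.parametrize(
        "lower, expected",
        [
            (3.6, Conclusion.NON_INFERIOR_ONLY),
            (4.5, Conclusion.SUPERIOR),
            (3.0, Conclusion.INCONCLUSIVE),
            (math.inf, Conclusion.INCONCLUSIVE),
            (math.nan, Conclusion.INCONCLUSIVE),
        ],
    )
    def test_ci_ranking_rule(self, lower, expected):
        assert decide_from_median_ci(lower, 3.3, 4.0) is expected

    def test_threshold_order_enforced(self, km_data):
        with pytest.raises(ValueError):
            km_decision(km_data, sup_threshold=3.0, ni_threshold=4.0)

    def test_uncensored_median_is_order_statistic(self):
        times = np.array([2.0, 5.0, 3.0, 9.0, 1.0, 7.0, 4.0])
        dec = km_decision(
            TrialData(times, np.ones(7, int)), sup_threshold=2.0, ni_threshold=1.0
        )
        assert dec.median == pytest.approx(4.0)  # middle order statistic

    def test_undefined_lower_bound_is_diagnosed(self):
        # tiny all-censored sample: survival CI never crosses 0.5
        dec = km_decision(
            TrialData(np.array([5.0, 6.0, 7.0]), np.zeros(3, int)),
            sup_threshold=4.0,
            ni_threshold=3.3,
        )
        assert dec.conclusion is Conclusion.INCONCLUSIVE
        assert "undefined" in dec.diagnostic

    def test_km_matches_brute_force_small_instances(self, km_data):
        from lifelines import KaplanMeierFitter

        # random small datasets plus the example dataset's first 8 patients
        rng = np.random.default_rng(3)
        datasets = [(km_data.time[:8], km_data.event[:8])]
        for _ in range(25):
            n = rng.integers(1, 9)
            t = np.round(rng.uniform(0.5, 10.0, n), 1)
            e = rng.integers(0, 2, n)
            datasets.append((t, e))
        for t, e in datasets:
            kmf = KaplanMeierFitter().fit(t, e)
            oracle = brute_force_product_limit(t, e)
            for tt, s in oracle.items():
                assert float(
                    kmf.survival_function_at_times(tt).iloc[0]
                ) == pytest.approx(s, abs=1e-12)
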