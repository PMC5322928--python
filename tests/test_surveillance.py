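"""Weekly aggregation, ACF/PACF, AR fitting, diagnostics and CUSUM."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from seasonwatch.surveillance import (
    ConstantSeriesError,
    acf,
    cusum,
    detect_arrivals,
    detect_events,
    diagnose,
    fit_ar,
    pacf,
    select_order,
    significance_bound,
    standardize,
    weekly_counts,
)
from seasonwatch.synthetic import generate_ar, inject_shift
from seasonwatch.tweetstore import CoveragePeriod
from conftest import make_record


class TestWeeklyCounts:
    def test_zero_hits_zero_filled(self):
        period = CoveragePeriod(date(2013, 9, 2), date(2013, 11, 11))
        weeks = weekly_counts([], period)
        assert len(weeks) == 10 and not weeks.counts.any()

    def test_seven_consecutive_days_one_week(self):
        period = CoveragePeriod(date(2013, 9, 2), date(2013, 9, 16))
        hits = [make_record(i, date(2013, 9, 2) + timedelta(days=i)) for i in range(7)]
        weeks = weekly_counts(hits, period)
        assert weeks.counts.tolist() == [7, 0]

    def test_matches_brute_force_bucketing(self):
        rng = np.random.default_rng(0)
        period = CoveragePeriod(date(2013, 7, 1), date(2014, 7, 1))
        days = rng.integers(0, 365, size=500)
        hits = [make_record(i, date(2013, 7, 1) + timedelta(days=int(d)))
                for i, d in enumerate(days)]
        weeks = weekly_counts(hits, period)
        brute = np.zeros(len(weeks), dtype=int)
        for rec in hits:
            brute[(rec.date - weeks.week_starts[0]).days // 7] += 1
        assert weeks.counts.tolist() == brute.tolist()

    def test_gap_weeks_masked_and_partial_flagged(self):
        period = CoveragePeriod(
            date(2013, 9, 2), date(2013, 10, 14),
            gaps=((date(2013, 9, 11), date(2013, 9, 25)),),
        )
        hits = [make_record(1, date(2013, 9, 9)), make_record(2, date(2013, 9, 26))]
        weeks = weekly_counts(hits, period)
        # week of 16 Sep lies wholly inside the gap; its neighbours overlap it
        assert weeks.missing.tolist() == [False, False, True, False, False, False]
        assert weeks.partial.tolist() == [False, True, False, True, False, False]
        assert weeks.counts[2] == 0


class TestAcfPacf:
    def test_lag_zero_is_one(self):
        x = np.random.default_rng(1).normal(size=50)
        assert acf(x, 5)[0] == 1.0

    def test_white_noise_inside_bound(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        r = acf(x, 10)
        bound = significance_bound(1000)
        assert np.sum(np.abs(r[1:]) < bound) >= 9

    def test_ar1_acf_matches_theory(self):
        x = generate_ar([0.8], n=2000, seed=3)
        assert acf(x, 1)[1] == pytest.approx(0.8, abs=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSeriesError):
            acf(np.ones(50), 3)

    def test_pacf_ar1_cuts_off_after_lag_one(self):
        x = generate_ar([0.6], n=2000, seed=4)
        p = pacf(x, 5)
        assert p[1] == pytest.approx(0.6, abs=0.05)
        assert np.all(np.abs(p[2:]) < 0.1)

    def test_pacf_lag1_equals_acf_lag1_exactly(self):
        x = np.random.default_rng(5).normal(size=300)
        assert pacf(x, 4)[1] == acf(x, 4)[1]

    def test_pacf_matches_statsmodels_yule_walker(self):
        from statsmodels.tsa.stattools import pacf as sm_pacf

        x = generate_ar([0.5, -0.3], n=500, seed=6)
        ours = pacf(x, 8)
        theirs = sm_pacf(x, nlags=8, method="ywm")
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_white_noise_pacf_inside_bound(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=1000)
        p = pacf(x, 10)
        assert np.sum(np.abs(p[1:]) < significance_bound(1000)) >= 9


class TestSelectOrder:
    def test_white_noise_mostly_order_zero(self):
        zeros = sum(
            select_order(np.random.default_rng(s).normal(size=500), max_lag=8) == 0
            for s in range(40)
        )
        # per-lag type-I error ~5%: order 0 should still dominate
        assert zeros >= 20

    def test_recovers_ar3(self):
        ok = 0
        for seed in range(50):
            x = generate_ar([0.5, -0.4, 0.3], n=1000, seed=seed)
            ok += select_order(x, max_lag=8) == 3
        assert ok >= 40

    def test_manual_override_accepts_chart_orders(self):
        # the hand-chosen lags used for the real weekly series
        hand_orders = {"moth_common": 5, "koel_symptomatic_2": 1, "koel_common_12": 3}
        x = generate_ar([0.5], n=400, seed=8)
        for p in hand_orders.values():
            assert fit_ar(x, p).order == p


class TestFitAr:
    def test_order_zero_mean_centers(self):
        fit = fit_ar(np.arange(1.0, 13.0), 0)
        assert np.allclose(fit.residuals, np.arange(1.0, 13.0) - 6.5)

    def test_ar1_parameter_recovery(self):
        ok = 0
        for seed in range(100):
            x = generate_ar([0.6], n=1000, sigma=1.0, seed=seed)
            phi = fit_ar(x, 1).coefficients[0]
            ok += 0.5 <= phi <= 0.7
        assert ok >= 95

    def test_matches_normal_equations_solve(self):
        x = generate_ar([0.7, -0.2], n=50 + 2, seed=9)[:52]
        fit = fit_ar(x, 2)
        # independent conditional-least-squares oracle
        y = x[2:]
        X = np.column_stack([np.ones(len(y)), x[1:-1], x[:-2]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(fit.coefficients, beta[1:], atol=1e-8)
        assert np.allclose(fit.residuals, y - X @ beta, atol=1e-8)

    def test_residual_mean_is_zero(self):
        x = generate_ar([0.4], n=300, seed=10)
        assert abs(fit_ar(x, 1).residuals.mean()) < 1e-8

    def test_short_series_guarded(self):
        with pytest.raises(ValueError, match="too short"):
            fit_ar(np.random.default_rng(0).normal(size=20), 4)

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSeriesError):
            fit_ar(np.full(60, 3.0), 1)


class TestDiagnose:
    def test_correct_specification_passes(self):
        passed = sum(
            diagnose(fit_ar(generate_ar([0.6, -0.3], n=400, seed=s), 2)).independent
            for s in range(40)
        )
        assert passed >= 36

    def test_underfit_detected(self):
        x = generate_ar([0.8], n=600, seed=11)
        assert not diagnose(fit_ar(x, 0)).independent

    def test_ljung_box_matches_formula(self):
        e = np.random.default_rng(12).normal(size=120)
        fit = fit_ar(e, 0)
        d = diagnose(fit, max_lag=10)
        n = len(fit.residuals)
        r = acf(fit.residuals, 10)
        brute = n * (n + 2) * sum(r[k] ** 2 / (n - k) for k in range(1, 11))
        assert d.ljung_box_stat == pytest.approx(brute, rel=1e-9)


class TestStandardizeCusum:
    def test_standardize_scales_by_residual_sd(self):
        fit = fit_ar(np.array([0.0, 4.0] * 30), 0)
        z = standardize(fit)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_standardize_is_idempotent(self):
        x = generate_ar([0.3], n=200, seed=13)
        z = standardize(fit_ar(x, 1))
        z2 = z / np.std(z, ddof=1)
        assert np.allclose(z, z2)

    def test_all_zero_z_stays_in_control(self):
        chart = cusum(np.zeros(30))
        assert not chart.violations
        assert not chart.c_plus.any() and not chart.c_minus.any()

    def test_step_shift_of_two_alarms_at_fourth_point(self):
        # +2 shift with k = 0.5 accrues 1.5 per step: 1.5, 3.0, 4.5, 6.0
        z = np.r_[np.zeros(20), np.full(10, 2.0)]
        chart = cusum(z, k=0.5, h=5.0)
        first = chart.upper_violations()[0]
        assert first == 23  # 4th shifted point
        assert chart.c_plus[first] == pytest.approx(6.0)

    def test_matches_brute_force_recursion(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=200)
        chart = cusum(z, k=0.5, h=5.0)
        cp = cm = 0.0
        for t, zt in enumerate(z):
            cp = max(0.0, cp + zt - 0.5)
            cm = min(0.0, cm + zt + 0.5)
            assert chart.c_plus[t] == pytest.approx(cp)
            assert chart.c_minus[t] == pytest.approx(cm)
            assert ((t, "upper") in chart.violations) == (cp > 5.0)
            assert ((t, "lower") in chart.violations) == (cm < -5.0)

    def test_translation_property(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=100)
        k = 0.5
        base = cusum(z, k=k, h=1e12)
        shifted = cusum(z + k, k=k, h=1e12)
        # adding k to every z turns the C+ increment into plain z
        increments = np.diff(np.r_[0.0, shifted.c_plus])
        expected = np.diff(np.r_[0.0, base.c_plus]) + k
        on_ramp = base.c_plus > 0  # away from the max(0, .) clamp
        assert np.allclose(increments[on_ramp], expected[on_ramp])

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            cusum(np.array([1.0, np.nan]))


class TestDetectEvents:
    def _weeks(self, counts, start=date(2013, 7, 1)):
        from seasonwatch.surveillance import WeeklySeries

        starts = tuple(start + timedelta(days=7 * i) for i in range(len(counts)))
        return WeeklySeries(starts, np.asarray(counts), np.zeros(len(counts), bool))

    def test_no_violations_empty_list(self):
        weeks = self._weeks([1] * 40)
        chart = cusum(np.zeros(38))
        assert detect_events(chart, weeks, order=2) == []

    def test_offset_by_ar_order(self):
        weeks = self._weeks([0] * 40)
        z = np.zeros(35)
        z[10] = 100.0  # single huge residual
        chart = cusum(z)
        events = detect_events(chart, weeks, order=5)
        # C+ stays above h while it decays by k per step, so the violation
        # persists; the first alarm is what carries the offset
        assert events[0] == (weeks.week_starts[15], "upper")
        assert all(d == "upper" for _, d in events)

    def test_length_mismatch_rejected(self):
        weeks = self._weeks([0] * 40)
        with pytest.raises(ValueError, match="chart length"):
            detect_events(cusum(np.zeros(30)), weeks, order=2)

    def test_detects_injected_arrival_pulse(self):
        # weekly counts jump 2 -> 20 for 3 weeks; an upper event must land
        # inside the pulse in nearly every seed
        hits_in_pulse = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(2.0, size=80)
            counts[50:53] = rng.poisson(20.0, size=3)
            weeks = self._weeks(counts)
            res = detect_arrivals(weeks, order=None)
            p = res["order"]
            pulse_weeks = set(weeks.week_starts[50:54])
            hits_in_pulse += any(
                ws in pulse_weeks for ws, d in res["events"] if d == "upper"
            )
        assert hits_in_pulse >= int(0.9 * n_seeds)

    def test_mean_shift_detection_delay(self):
        # +2 sigma sustained shift: median delay at most 5 points
        delays = []
        for seed in range(60):
            rng = np.random.default_rng(100 + seed)
            z = rng.normal(size=150)
            z = inject_shift(z, 100, 2.0)
            z = z / np.std(z, ddof=1)
            chart = cusum(z)
            after = [t for t in chart.upper_violations() if t >= 100]
            if after:
                delays.append(after[0] - 100)
        assert len(delays) >= 54  # detected in >= 90% of seeds
        assert np.median(delays) <= 5

    def test_detection_rate_monotone_in_pulse_amplitude(self):
        rates = []
        for mult in (2, 5, 10):
            detected = 0
            for seed in range(30):
                rng = np.random.default_rng(1000 + seed)
                counts = rng.poisson(3.0, size=80)
                counts[50:53] = rng.poisson(3.0 * mult, size=3)
                res = detect_arrivals(self._weeks(counts))
                pulse_weeks = set(self._weeks(counts).week_starts[50:54])
                detected += any(
                    ws in pulse_weeks for ws, d in res["events"] if d == "upper"
                )
            rates.append(detected / 30)
        assert rates[0] <= rates[1] <= rates[2]


def test_prewhitening_bounds_residual_acf_exceedances():
    good = 0
    for seed in range(60):
        x = generate_ar([0.7, -0.2], n=300, seed=seed)
        fit = fit_ar(x, 2)
        r = acf(fit.residuals, 10)
        bound = significance_bound(len(fit.residuals))
        good += np.sum(np.abs(r[1:]) > bound) <= 2
    assert good >= 54
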