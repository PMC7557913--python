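import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sckinetics import (
    DataError,
    DegenerateSeriesError,
    FitError,
    ResponseSeries,
    conversion_series,
    degree_of_hydration,
    fit_first_order,
    fit_power_law,
    hydration_time,
    round_half_up_minutes,
    summarize_kinetics,
)
from sckinetics.kinetics import ConversionSeries, PowerLawFit, degree_at


class TestConversionSeries:
    def test_endpoints_give_zero_and_one(self, make_first_order_series):
        series = make_first_order_series(0.01, np.arange(0, 961, 30))
        conv = conversion_series(series, 0.0, 960.0)
        assert conv.alpha[0] == pytest.approx(0.0)
        assert conv.alpha[-1] == pytest.approx(1.0)

    def test_exponential_response_alpha_closed_form(self, make_first_order_series):
        # EIR(t) = EIR_f + (EIR_i − EIR_f) e^(−kt), k = 0.01: substituting in the
        # conversion formula gives α(t) = (1 − e^(−kt)) / (1 − e^(−k t_f))
        k, t_f = 0.01, 5000.0
        times = np.array([0.0, 100.0, 500.0, t_f])
        series = make_first_order_series(k, times)
        conv = conversion_series(series, 0.0, t_f)
        expected = (1 - math.exp(-k * 100.0)) / (1 - math.exp(-k * t_f))
        assert conv.alpha[1] == pytest.approx(expected, rel=1e-12)
        assert conv.alpha[1] == pytest.approx(1 - math.exp(-1), abs=1e-2)

    def test_falling_response_treated_identically(self):
        # low-frequency impedance falls on hydration; the formula is sign-agnostic
        times = np.arange(0, 961, 60.0)
        k = 0.008
        values = 50e3 + (250e3 - 50e3) * np.exp(-k * times)
        series = ResponseSeries(times, values, "impedance_magnitude")
        conv = conversion_series(series)
        assert np.all(np.diff(conv.alpha) > 0)
        assert conv.alpha[0] == pytest.approx(0.0)

    def test_degenerate_series_rejected(self):
        series = ResponseSeries(np.array([0.0, 480.0, 960.0]), np.array([5.0, 7.0, 5.0]), "conductance")
        with pytest.raises(DegenerateSeriesError):
            conversion_series(series)


class TestFitFirstOrder:
    @pytest.mark.parametrize("k", [0.005, 0.0136])
    def test_exact_first_order_recovers_rate(self, k):
        t = np.array([30.0, 60.0, 90.0, 120.0])
        conv = ConversionSeries(t, 1 - np.exp(-k * t), 0.0, 960.0, "conductance", 1.0, 0.0)
        fit = fit_first_order(conv)
        assert fit.k_per_s == pytest.approx(k, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 4

    def test_constant_alpha_flagged_non_converging(self):
        t = np.array([30.0, 60.0, 90.0, 120.0])
        conv = ConversionSeries(t, np.full(4, 0.5), 0.0, 960.0, "conductance", 1.0, 0.0)
        fit = fit_first_order(conv)
        assert fit.k_per_s == 0.0
        assert not fit.converging

    def test_saturated_points_dropped_with_warning(self):
        t = np.array([30.0, 60.0, 90.0, 120.0])
        alpha = np.array([0.2, 0.5, 1.0, 1.01])
        conv = ConversionSeries(t, alpha, 0.0, 960.0, "conductance", 1.0, 0.0)
        with pytest.warns(UserWarning, match="α ≥ 1"):
            fit = fit_first_order(conv)
        assert fit.n_points == 2

    def test_too_few_usable_points_is_fit_error(self):
        t = np.array([30.0, 60.0, 90.0])
        conv = ConversionSeries(t, np.array([0.3, 1.0, 1.0]), 0.0, 960.0, "conductance", 1.0, 0.0)
        with pytest.warns(UserWarning):
            with pytest.raises(FitError):
                fit_first_order(conv)


class TestHydrationTime:
    def test_printed_rate_constant_examples(self):
        # k = 0.0136 → 220.3 s → 4 min; k = 0.0034 → 881.1 s → 15 min
        t = hydration_time(0.0136, 0.95)
        assert t == pytest.approx(220.26, abs=0.05)
        assert round_half_up_minutes(t) == 4
        t = hydration_time(0.0034, 0.95)
        assert t == pytest.approx(881.1, abs=0.1)
        assert round_half_up_minutes(t) == 15

    def test_zero_target_gives_zero_time(self):
        assert hydration_time(0.01, 0.0) == 0.0

    def test_non_positive_rate_rejected(self):
        with pytest.raises(DataError):
            hydration_time(0.0)
        with pytest.raises(DataError):
            hydration_time(-0.01)

    @settings(max_examples=60, deadline=None)
    @given(
        k1=st.floats(1e-4, 0.1),
        factor=st.floats(1.01, 10.0),
        a1=st.floats(0.05, 0.9),
        da=st.floats(0.01, 0.09),
    )
    def test_monotone_in_rate_and_target(self, k1, factor, a1, da):
        assert hydration_time(k1 * factor, a1) < hydration_time(k1, a1)
        assert hydration_time(k1, a1 + da) > hydration_time(k1, a1)

    def test_round_half_up(self):
        assert round_half_up_minutes(150.0) == 3  # 2.5 min rounds up
        assert round_half_up_minutes(149.9) == 2


class TestPowerLaw:
    def test_model_true_parameters_recovered(self):
        a, b, c = -0.8, 0.99, 2.0
        t = np.arange(30.0, 990.0, 30.0)
        values = a * b**t + c
        series = ResponseSeries(t, values, "conductance", normalized=True)
        fit = fit_power_law(series)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.c == pytest.approx(c, rel=1e-6)
        assert fit.rmse < 1e-9
        assert 0 < fit.b < 1

    def test_constant_series_flagged_degenerate(self):
        t = np.arange(30.0, 400.0, 30.0)
        series = ResponseSeries(t, np.full(len(t), 3.0), "conductance")
        fit = fit_power_law(series)
        assert fit.degenerate
        assert fit.a == pytest.approx(0.0, abs=1e-9)

    def test_three_points_is_error(self):
        series = ResponseSeries(np.array([30.0, 60.0, 90.0]), np.array([1.0, 2.0, 3.0]), "conductance")
        with pytest.raises(FitError):
            fit_power_law(series)


class TestDegreeOfHydration:
    def exponential_fit(self, k=0.005, t_start=30.0):
        return PowerLawFit(a=-0.8, b=math.exp(-k), c=2.0, t_start_s=t_start, rmse=0.0)

    def test_cumulative_zero_at_start_and_one_at_infinity(self):
        fit = self.exponential_fit()
        assert degree_at(fit, fit.t_start_s) == pytest.approx(0.0)
        assert degree_at(fit, 1e7) == pytest.approx(1.0)

    def test_cumulative_hits_target_at_hydration_time(self):
        # for a pure-exponential fit with rate k, the cumulative degree at
        # t_start + t_h(α = 0.95) is exactly 0.95
        k = 0.005
        fit = self.exponential_fit(k)
        t_h = hydration_time(k, 0.95)
        assert degree_at(fit, fit.t_start_s + t_h) == pytest.approx(0.95, rel=1e-12)

    def test_cumulative_equals_conversion_with_asymptote_as_final(self):
        # θ_cum(t) is algebraically α of the conversion formula with EIR_f
        # replaced by the asymptote c
        fit = self.exponential_fit(0.008)
        t = np.arange(30.0, 600.0, 10.0)
        curve = fit(t)
        alpha_with_asymptote = (curve[0] - curve) / (curve[0] - fit.c)
        degrees = degree_of_hydration(fit, 590.0, dt_s=10.0)
        np.testing.assert_allclose(degrees.theta_cumulative, alpha_with_asymptote, rtol=1e-10)

    def test_derivative_is_finite_difference_of_fit(self):
        fit = self.exponential_fit(0.01)
        deg = degree_of_hydration(fit, 40.0, dt_s=1.0)
        expected = fit(np.arange(31.0, 41.0)) - fit(np.arange(30.0, 40.0))
        np.testing.assert_allclose(deg.theta_derivative[1:], expected, rtol=1e-10)
        assert np.all(np.diff(deg.theta_cumulative) > 0)

    def test_degenerate_fit_rejected(self):
        fit = PowerLawFit(a=0.0, b=0.5, c=1.0, t_start_s=30.0, rmse=0.0, degenerate=True)
        with pytest.raises(DegenerateSeriesError):
            degree_at(fit, 100.0)


class TestSummarizeKinetics:
    def test_single_fit_mean_equals_row(self):
        summary = summarize_kinetics(
            [{"label": "only", "group": "HP", "k_per_s": 0.0136, "r_squared": 0.99}]
        )
        stat = summary.time_stat()
        assert stat.n == 1
        assert stat.mean_rounded == 4
        assert stat.sd is None

    def test_low_r2_rows_excluded_with_reason(self):
        summary = summarize_kinetics(
            [
                {"label": "good", "group": "NE", "k_per_s": 0.005, "r_squared": 0.9},
                {"label": "bad", "group": "NE", "k_per_s": 0.005, "r_squared": 0.5},
            ]
        )
        rows = summary.rows.set_index("label")
        assert not rows.loc["good", "excluded"]
        assert rows.loc["bad", "excluded"]
        assert "below threshold" in rows.loc["bad", "exclusion_reason"]
        assert summary.time_stat().n == 1

    def test_missing_rate_constant_kept_but_excluded(self):
        summary = summarize_kinetics(
            [
                {"label": "ok", "group": "4E", "k_per_s": 0.008, "r_squared": 0.96},
                {"label": "none", "group": "NE", "k_per_s": float("nan"), "r_squared": None},
            ]
        )
        assert len(summary.rows) == 2
        assert summary.rows["excluded"].sum() == 1

    def test_everything_excluded_is_error(self):
        with pytest.raises(DataError):
            summarize_kinetics([{"label": "x", "group": "g", "k_per_s": 0.01, "r_squared": 0.1}])
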