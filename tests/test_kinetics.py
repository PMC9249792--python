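"""Interpolation, derivative curves, dT_df, hysteresis and regression."""

import numpy as np
import pytest

from picocell.kinetics import (
    DegenerateSeriesError,
    DerivativeCurve,
    HysteresisPath,
    TimeSeries,
    delta_t_df,
    derivative_curve,
    hysteresis_area,
    interpolate_series,
    linear_regression,
    rank_delta_t_df,
)

SAMPLING = np.array([0.0, 0.5, 1.0, 3.0, 6.0, 12.0])


def logistic_series(midpoint, steepness=4.0, amplitude=1.0, times=SAMPLING,
                    label="x"):
    values = amplitude / (1.0 + np.exp(-steepness * (times - midpoint)))
    return TimeSeries(times, values, label)


class TestInterpolation:
    def test_linear_data_stays_linear(self):
        series = TimeSeries(SAMPLING, 2.0 * SAMPLING + 1.0)
        grid, dense = interpolate_series(series)
        assert np.max(np.abs(dense - (2.0 * grid + 1.0))) < 1e-9

    def test_observations_reproduced_exactly(self):
        series = logistic_series(0.9)
        grid, dense = interpolate_series(series, grid_step=0.01)
        for t, v in zip(series.times, series.values):
            idx = np.argmin(np.abs(grid - t))
            assert dense[idx] == pytest.approx(v, abs=1e-9)

    def test_monotone_input_gives_monotone_interpolant(self):
        series = TimeSeries(SAMPLING, np.array([5.0, 4.0, 3.5, 2.0, 1.0, 0.9]))
        _, dense = interpolate_series(series)
        assert np.all(np.diff(dense) <= 1e-12)

    def test_grid_covers_observation_window(self):
        grid, _ = interpolate_series(logistic_series(0.9), grid_step=0.01)
        assert grid[0] == 0.0
        assert grid[-1] == 12.0

    def test_grid_step_must_resolve_sampling(self):
        with pytest.raises(ValueError):
            interpolate_series(logistic_series(0.9), grid_step=0.6)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            TimeSeries(np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestDerivativeCurve:
    def test_linear_ramp_constant_derivative_scaled_plus_100(self):
        series = TimeSeries(SAMPLING, 2.0 * SAMPLING)
        curve = derivative_curve(series)
        assert np.allclose(curve.derivative, 2.0, atol=1e-6)
        assert np.allclose(curve.scaled, 100.0, atol=1e-6)

    def test_constant_series_flagged_degenerate(self):
        curve = derivative_curve(TimeSeries(SAMPLING, np.full(6, 3.0)))
        assert curve.degenerate
        with pytest.raises(DegenerateSeriesError):
            delta_t_df(curve)

    def test_scaled_channel_attains_but_never_exceeds_100(self):
        for midpoint in (0.3, 0.9, 2.0, 5.0):
            curve = derivative_curve(logistic_series(midpoint))
            assert np.max(np.abs(curve.scaled)) == pytest.approx(100.0)

    def test_densely_sampled_logistic_peaks_at_midpoint(self):
        times = np.round(np.arange(0.0, 2.0001, 0.02), 10)
        values = 1.0 / (1.0 + np.exp(-8.0 * (times - 1.0)))
        curve = derivative_curve(TimeSeries(times, values), grid_step=0.01)
        assert abs(delta_t_df(curve).time - 1.0) <= 0.01


class TestDeltaTdf:
    def test_ramp_takes_first_grid_time(self):
        curve = derivative_curve(TimeSeries(SAMPLING, 2.0 * SAMPLING))
        assert delta_t_df(curve).time == 0.0
        assert delta_t_df(curve).sign == 100

    def test_decreasing_turgor_course_signs_minus_100(self):
        series = logistic_series(0.9, amplitude=-0.2)
        assert delta_t_df(derivative_curve(series)).sign == -100

    def test_sparse_logistic_midpoint_recovered_within_half_interval(self):
        series = logistic_series(0.92)
        d = delta_t_df(derivative_curve(series, steady_state_start=True))
        assert abs(d.time - 0.92) <= 0.25

    def test_recovery_property_over_random_midpoints(self):
        rng = np.random.default_rng(0)
        intervals = list(zip(SAMPLING[:-1], SAMPLING[1:]))

        def local_interval(t0):
            return next(b - a for a, b in intervals if a <= t0 <= b)

        for _ in range(100):
            t0 = rng.uniform(0.1, 6.0)
            amp = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
            series = logistic_series(t0, amplitude=amp)
            d = delta_t_df(derivative_curve(series, steady_state_start=True))
            assert abs(d.time - t0) <= local_interval(t0) / 2

    def test_noisy_recovery_within_local_interval(self):
        rng = np.random.default_rng(1)
        successes = 0
        for _ in range(100):
            t0 = rng.uniform(0.2, 0.9)
            clean = logistic_series(t0)
            noisy = TimeSeries(
                clean.times, clean.values + rng.normal(0, 0.02, clean.times.size)
            )
            d = delta_t_df(derivative_curve(noisy, steady_state_start=True))
            if abs(d.time - t0) <= 0.5:
                successes += 1
        assert successes >= 95


class TestHysteresis:
    def test_unit_square_counterclockwise_direct(self):
        path = HysteresisPath([(0, 0), (1, 0), (1, 1), (0, 1)])
        area, label = hysteresis_area(path)
        assert area == pytest.approx(1.0)
        assert label == "direct"

    def test_clockwise_is_inverse(self):
        path = HysteresisPath([(0, 0), (0, 1), (1, 1), (1, 0)])
        area, label = hysteresis_area(path)
        assert area == pytest.approx(-1.0)
        assert label == "inverse"

    def test_reversal_flips_sign_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pts = rng.normal(size=(12, 2))
            forward, _ = hysteresis_area(HysteresisPath(pts))
            backward, _ = hysteresis_area(HysteresisPath(pts[::-1]))
            assert backward == -forward

    def test_matches_independent_shoelace_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(20, 2))
        area, _ = hysteresis_area(HysteresisPath(pts))
        oracle = 0.0
        for i in range(20):
            x1, y1 = pts[i]
            x2, y2 = pts[(i + 1) % 20]
            oracle += x1 * y2 - x2 * y1
        assert area == pytest.approx(oracle / 2.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            HysteresisPath([(0, 0), (1, 0), (1, 1)])


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_regression(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_convention(self):
        with pytest.warns(UserWarning):
            fit = linear_regression([0.0, 1.0, 2.0], [4.0, 4.0, 4.0])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.uniform(-5, 5, size=10)
            y = 1.7 * x - 0.4 + rng.normal(0, 0.5, size=10)
            fit = linear_regression(x, y)
            design = np.column_stack([x, np.ones_like(x)])
            slope, intercept = np.linalg.solve(design.T @ design, design.T @ y)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_parameter_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(8)
        a, b, sigma, n = 2.5, -1.0, 0.3, 30
        misses = 0
        for _ in range(100):
            x = rng.uniform(0, 10, size=n)
            y = a * x + b + rng.normal(0, sigma, size=n)
            fit = linear_regression(x, y)
            sxx = np.sum((x - x.mean()) ** 2)
            residuals = y - (fit.slope * x + fit.intercept)
            s = np.sqrt(np.sum(residuals**2) / (n - 2))
            se_slope = s / np.sqrt(sxx)
            if abs(fit.slope - a) > 3 * se_slope:
                misses += 1
        assert misses <= 5


class TestRank:
    def test_singleton(self):
        curve = derivative_curve(logistic_series(0.9))
        ordered, flagged = rank_delta_t_df([("only", curve)])
        assert [label for label, _ in ordered] == ["only"]
        assert flagged == []

    def test_ties_keep_input_order(self):
        curve = derivative_curve(logistic_series(0.9))
        ordered, _ = rank_delta_t_df([("b", curve), ("a", curve)])
        assert [label for label, _ in ordered] == ["b", "a"]

    def test_degenerate_curve_flagged_not_dropped(self):
        good = derivative_curve(logistic_series(0.9))
        bad = derivative_curve(TimeSeries(SAMPLING, np.full(6, 1.0)))
        ordered, flagged = rank_delta_t_df([("good", good), ("flat", bad)])
        assert [label for label, _ in ordered] == ["good"]
        assert flagged == ["flat"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_delta_t_df([])
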