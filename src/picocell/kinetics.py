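"""Time-derivative kinetics of sparsely sampled cellular parameters.

Stress-response trajectories are observed at a handful of irregular time
points (0, 0.5, 1, 3, 6, 12 h in the experiments this package models).  Each
trajectory is interpolated with a shape-preserving monotone piecewise cubic
(no overshoot, hence no spurious derivative extrema), differentiated on a
dense uniform grid, and rescaled so the largest absolute rate maps to +100%
(a maximal increase) or -100% (a maximal decrease).  The delay from treatment
to that extremum — dT_df — is the kinetic feature used to order cellular
events.  Hysteresis loops in (water-potential gradient, volume) space are
quantified by their signed shoelace area, and ordinary least squares with R^2
backs the tortuosity-vs-cardiolipin regression and the calibration curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TimeSeries",
    "DerivativeCurve",
    "DeltaTdf",
    "HysteresisPath",
    "RegressionFit",
    "DegenerateSeriesError",
    "interpolate_series",
    "derivative_curve",
    "delta_t_df",
    "hysteresis_area",
    "linear_regression",
    "rank_delta_t_df",
]


class DegenerateSeriesError(ValueError):
    """Raised when a constant series leaves the scaled derivative undefined."""


@dataclass(frozen=True)
class TimeSeries:
    """An irregularly sampled parameter trajectory starting at treatment (t=0)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size < 3 or v.size != t.size:
            raise ValueError("need >= 3 samples with matching times and values")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("first observation must be at t = 0 (treatment)")


@dataclass(frozen=True)
class DerivativeCurve:
    """Dense time derivative of a trajectory plus its +/-100% scaled channel.

    `scaled` is None for a degenerate (constant) input; otherwise its largest
    absolute value is exactly 100.
    """

    grid: np.ndarray
    derivative: np.ndarray
    scaled: np.ndarray | None
    label: str = ""

    @property
    def degenerate(self) -> bool:
        return self.scaled is None


@dataclass(frozen=True)
class DeltaTdf:
    """Time (h) at which the scaled rate first reaches +/-100%, with its sign."""

    time: float
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (100, -100):
            raise ValueError("sign must be +100 or -100")
        if self.time < 0:
            raise ValueError("time must be >= 0")


@dataclass(frozen=True)
class HysteresisPath:
    """An ordered stress-then-recovery path in (gradient, volume) space.

    The closing edge from the last point back to the first is implicit; the
    signed shoelace area over that closed loop quantifies the hysteresis.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", arr)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
            raise ValueError("path needs >= 4 (x, y) points")


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares slope, intercept and coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def _dense_grid(t0: float, t1: float, step: float) -> np.ndarray:
    n = int(round((t1 - t0) / step))
    grid = t0 + step * np.arange(n + 1)
    grid[-1] = t1  # cover the full observation window exactly
    return grid


def _monotone_interpolant(times: np.ndarray, values: np.ndarray):
    """Shape-preserving cubic with secant boundary slopes.

    Interior slopes come from the monotone piecewise-cubic rule; the two
    boundary slopes are replaced by the one-sided secants.  The default
    endpoint extrapolation rule can exceed the first secant and manufacture a
    spurious rate maximum at the observation boundary, which would corrupt
    the derivative-extremum feature.  Secant boundary slopes keep the
    Fritsch-Carlson monotonicity bound (m <= 3*secant), so the interpolant
    still introduces no local extrema between samples, and linear data stay
    exactly linear.
    """
    from scipy.interpolate import CubicHermiteSpline

    slopes = PchipInterpolator(times, values).derivative()(times)
    slopes[0] = (values[1] - values[0]) / (times[1] - times[0])
    slopes[-1] = (values[-1] - values[-2]) / (times[-1] - times[-2])
    return CubicHermiteSpline(times, values, slopes)


def interpolate_series(series: TimeSeries, grid_step: float = 0.01):
    """Monotone piecewise-cubic interpolation of a sparse trajectory.

    Returns (grid, values).  The interpolant passes through every observation
    exactly and introduces no local extrema between samples.
    """
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    if grid_step >= np.min(np.diff(series.times)):
        raise ValueError("grid step must be smaller than the closest sample spacing")
    interpolant = _monotone_interpolant(series.times, series.values)
    grid = _dense_grid(series.times[0], series.times[-1], grid_step)
    return grid, interpolant(grid)


def derivative_curve(
    series: TimeSeries, grid_step: float = 0.01, steady_state_start: bool = False
) -> DerivativeCurve:
    """Central-difference derivative of the dense interpolant, scaled to +/-100%.

    The scaled channel divides by the maximum absolute derivative and keeps
    the sign, so exactly one of +100 (largest increase) or -100 (largest
    decrease) is attained.  A constant series leaves the scaling undefined;
    the curve is returned flagged degenerate (scaled is None).

    With `steady_state_start` the parameter is treated as constant before
    treatment (the pre-stress steady state): a virtual pre-treatment sample
    equal to the first observation anchors the boundary, pinning the rate at
    t=0 to zero.  This resolves the boundary degeneracy that otherwise makes
    the rate-extremum time insensitive to where a fast transition sits within
    the first sampling interval.  Off by default: without it the derivative
    of the interpolant is reported exactly as observed (a linear ramp keeps
    its slope all the way to t=0).
    """
    if steady_state_start:
        if grid_step <= 0:
            raise ValueError("grid step must be positive")
        if grid_step >= np.min(np.diff(series.times)):
            raise ValueError("grid step must be smaller than the closest sample spacing")
        dt0 = series.times[1] - series.times[0]
        t_ext = np.concatenate([[series.times[0] - dt0], series.times])
        v_ext = np.concatenate([[series.values[0]], series.values])
        interpolant = _monotone_interpolant(t_ext, v_ext)
        grid = _dense_grid(series.times[0], series.times[-1], grid_step)
        dense = interpolant(grid)
    else:
        grid, dense = interpolate_series(series, grid_step)
    deriv = np.gradient(dense, grid)
    peak = float(np.max(np.abs(deriv)))
    # exact constancy check: spline evaluation leaves O(1e-14) dust that must
    # not masquerade as a rate extremum
    if peak == 0.0 or np.all(series.values == series.values[0]):
        return DerivativeCurve(grid, np.zeros_like(grid), None, series.label)
    return DerivativeCurve(grid, deriv, 100.0 * deriv / peak, series.label)


def delta_t_df(curve: DerivativeCurve) -> DeltaTdf:
    """Earliest time the scaled rate attains +/-100%, with the attained sign.

    Ties (a flat extremal rate) break to the earliest grid time.
    """
    if curve.degenerate:
        raise DegenerateSeriesError(
            f"constant series {curve.label!r}: scaled derivative undefined"
        )
    magnitude = np.abs(curve.scaled)
    peak = magnitude.max()
    idx = int(np.argmax(magnitude >= peak * (1 - 1e-12)))
    sign = 100 if curve.scaled[idx] > 0 else -100
    return DeltaTdf(time=float(curve.grid[idx]), sign=sign)


def hysteresis_area(path: HysteresisPath) -> tuple[float, str]:
    """Signed shoelace area of the implicitly closed loop and its orientation.

    Counterclockwise (positive) loops are labelled "direct", clockwise
    (negative) "inverse"; reversing the point order flips the sign exactly.
    """
    pts = path.points
    n = pts.shape[0]
    # per-edge cross products totalled with fsum: each edge term is exactly
    # negated under path reversal, so the signed area flips sign exactly
    terms = [
        pts[i, 0] * pts[(i + 1) % n, 1] - pts[(i + 1) % n, 0] * pts[i, 1]
        for i in range(n)
    ]
    area = 0.5 * math.fsum(terms)
    label = "direct" if area > 0 else "inverse" if area < 0 else "flat"
    return area, label


def linear_regression(x, y) -> RegressionFit:
    """Ordinary least squares with R^2 = 1 - SS_res / SS_tot.

    Zero-variance y has no explainable variation; R^2 is defined as 0 with a
    warning.  Zero-variance x is a domain error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x and y with >= 3 points")
    if np.all(x == x[0]):
        raise ValueError("x values are all equal; slope is undefined")
    if np.all(y == y[0]):
        warnings.warn("y has zero variance; R^2 defined as 0", stacklevel=2)
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    result = stats.linregress(x, y)
    return RegressionFit(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue) ** 2,
    )


def rank_delta_t_df(
    curves: list[tuple[str, DerivativeCurve]],
) -> tuple[list[tuple[str, DeltaTdf]], list[str]]:
    """Order parameters by ascending dT_df.

    Returns (ordered [(label, DeltaTdf)], flagged labels).  Degenerate curves
    are reported in the flagged list, never silently dropped; ties keep the
    input order (stable sort).
    """
    if not curves:
        raise ValueError("need at least one curve")
    measured: list[tuple[str, DeltaTdf]] = []
    flagged: list[str] = []
    for label, curve in curves:
        if curve.degenerate:
            flagged.append(label)
        else:
            measured.append((label, delta_t_df(curve)))
    measured.sort(key=lambda item: item[1].time)
    return measured, flagged
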