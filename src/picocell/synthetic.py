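"""Seeded generators emulating the study's measurement structure.

Every pipeline stage is testable without downloads: logistic stress-response
time courses sampled at the experimental time points, spectra whose peaks sit
within a known ppm jitter of theoretical ion m/z, sine-arc contours with a
prescribed arc-chord ratio, constant-speed vesicle tracks, and closed
hysteresis loops of prescribed signed area.  All generators are deterministic
functions of (seed, config): the same inputs give bit-identical outputs.

The default scenario reproduces the ordering of cellular events under salt
stress: turgor drops first (midpoint 0.16 h), mitochondria swell while the
cell shrinks (0.23 / 0.24 h), osmotic adjustment lowers psi_s (0.47 h), TCA
metabolites accumulate (0.65 h), water potential falls (0.69 h), crista
tortuosity rises (0.85 h) and cardiolipin accumulates last (0.92 h).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import MetaboliteRecord, Peak
from .chem import ion_mz
from .kinetics import HysteresisPath, TimeSeries
from .morphometrics import Contour, VesicleTrack

__all__ = [
    "LogisticSpec",
    "ScenarioConfig",
    "SpectrumSpec",
    "SpectrumTruth",
    "DEFAULT_SAMPLING_TIMES_H",
    "default_scenario",
    "gen_time_courses",
    "gen_spectrum",
    "gen_contour",
    "gen_tracks",
    "gen_hysteresis_path",
]

#: Experimental sampling times after treatment, h.
DEFAULT_SAMPLING_TIMES_H = (0.0, 0.5, 1.0, 3.0, 6.0, 12.0)


@dataclass(frozen=True)
class LogisticSpec:
    """One parameter's stress-response shape.

    value(t) = baseline + amplitude * sigmoid(steepness * (t - midpoint_h)),
    optionally followed by a recovery transition of the opposite sign (same
    amplitude, gentler rate) so transient parameters return to baseline.  The
    signed amplitude encodes the response direction; the primary rate must
    dominate the recovery rate so the derivative extremum stays at the primary
    midpoint.
    """

    baseline: float
    amplitude: float
    midpoint_h: float
    steepness: float = 4.0
    recovery: bool = False
    recovery_midpoint_h: float = 6.0
    recovery_steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")
        if self.steepness <= 0 or self.recovery_steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.recovery and (
            abs(self.recovery_steepness) >= abs(self.steepness)
        ):
            raise ValueError("recovery must be slower than the primary transition")

    def value(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self.baseline + self.amplitude / (
            1.0 + np.exp(-self.steepness * (t - self.midpoint_h))
        )
        if self.recovery:
            out -= self.amplitude / (
                1.0 + np.exp(-self.recovery_steepness * (t - self.recovery_midpoint_h))
            )
        return out


@dataclass(frozen=True)
class ScenarioConfig:
    """Per-parameter logistic specs plus sampling times, noise level and seed."""

    specs: dict[str, LogisticSpec]
    times_h: tuple[float, ...] = DEFAULT_SAMPLING_TIMES_H
    noise_sd_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_frac < 0:
            raise ValueError("noise sd must be >= 0")
        t0, t1 = min(self.times_h), max(self.times_h)
        for label, spec in self.specs.items():
            if not t0 <= spec.midpoint_h <= t1:
                raise ValueError(
                    f"{label}: midpoint {spec.midpoint_h} h outside the "
                    f"sampling window [{t0}, {t1}] h"
                )


def default_scenario(seed: int = 0, noise_sd_frac: float = 0.0) -> ScenarioConfig:
    """The salt-stress scenario: eight parameters, midpoints 0.16-0.92 h."""
    specs = {
        "psi_p": LogisticSpec(0.51, -0.20, 0.16, recovery=True),
        "V_Mito": LogisticSpec(1.0, +0.30, 0.23, recovery=True),
        "V_o": LogisticSpec(1750.0, -250.0, 0.24),
        "psi_s": LogisticSpec(-0.76, -0.37, 0.47),
        "TCA": LogisticSpec(1.0e5, +5.0e4, 0.65),
        "psi_w": LogisticSpec(-0.25, -0.20, 0.69),
        "tau": LogisticSpec(1.23, +0.30, 0.85, recovery=True),
        "CL": LogisticSpec(1.0e5, +6.0e4, 0.92),
    }
    return ScenarioConfig(specs=specs, noise_sd_frac=noise_sd_frac, seed=seed)


def gen_time_courses(config: ScenarioConfig) -> dict[str, TimeSeries]:
    """Sample every parameter's logistic at the configured times, with seeded
    additive Gaussian noise (sd = noise_sd_frac * |amplitude|)."""
    t = np.asarray(config.times_h, dtype=float)
    series: dict[str, TimeSeries] = {}
    for index, (label, spec) in enumerate(sorted(config.specs.items())):
        values = spec.value(t)
        if config.noise_sd_frac > 0:
            rng = np.random.default_rng([config.seed % (2**31), index])
            values = values + rng.normal(
                0.0, config.noise_sd_frac * abs(spec.amplitude), size=t.size
            )
        series[label] = TimeSeries(times=t, values=values, label=label)
    return series


@dataclass(frozen=True)
class SpectrumTruth:
    """Ground truth for one generated peak (the recall/precision oracle)."""

    name: str
    ion_mode: str
    theoretical_mz: float
    observed_mz: float


@dataclass(frozen=True)
class SpectrumSpec:
    """Recipe for a synthetic spectrum.

    One peak per (record, allowed ion mode) at the theoretical m/z perturbed
    uniformly within +/- ppm_jitter, plus seeded baseline-noise peaks strictly
    below 3x `baseline_noise` (so the limit-of-detection filter removes all of
    them).  `tolerance_ppm` records the annotation tolerance the spectrum is
    meant to exercise; a jitter at or above it triggers a warning.
    """

    records: tuple[tuple[MetaboliteRecord, float], ...]
    ppm_jitter: float = 4.0
    baseline_noise: float = 10.0
    n_noise_peaks: int = 20
    mz_range: tuple[float, float] = (80.0, 900.0)
    tolerance_ppm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_jitter < 0 or self.baseline_noise <= 0:
            raise ValueError("jitter must be >= 0 and baseline noise positive")
        if self.ppm_jitter >= self.tolerance_ppm:
            warnings.warn(
                "ppm jitter >= annotation tolerance: recall will not be 1",
                stacklevel=2,
            )


def gen_spectrum(spec: SpectrumSpec) -> tuple[list[Peak], list[SpectrumTruth]]:
    """Generate a peak list plus the bookkeeping needed to score annotation."""
    rng = np.random.default_rng([spec.seed % (2**31), 17])
    peaks: list[Peak] = []
    truth: list[SpectrumTruth] = []
    for record, intensity in spec.records:
        for ion in record.ions():
            theoretical = ion_mz(ion)
            shift_ppm = rng.uniform(-spec.ppm_jitter, spec.ppm_jitter)
            observed = theoretical * (1.0 + shift_ppm * 1e-6)
            peaks.append(Peak(mz=observed, intensity=intensity))
            truth.append(
                SpectrumTruth(record.name, ion.mode.value, theoretical, observed)
            )
    lod = 3.0 * spec.baseline_noise
    for _ in range(spec.n_noise_peaks):
        mz = rng.uniform(*spec.mz_range)
        peaks.append(Peak(mz=mz, intensity=rng.uniform(0.1, 0.99) * lod))
    peaks.sort(key=lambda p: p.mz)
    return peaks, truth


def _sine_arc_points(amplitude: float, length: float, n_points: int) -> np.ndarray:
    x = np.linspace(0.0, length, n_points)
    y = amplitude * np.sin(math.pi * x / length)
    return np.column_stack([x, y])


def _polyline_tau(points: np.ndarray) -> float:
    arc = float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())
    chord = float(np.linalg.norm(points[-1] - points[0]))
    return arc / chord


def gen_contour(
    target_tau: float, n_points: int = 200, length: float = 1000.0
) -> Contour:
    """A sine-arc polyline whose discrete arc-chord ratio hits `target_tau`.

    The amplitude is solved by bisection on the discrete arc length; the
    measured tortuosity of the returned contour is within 1e-3 of the target.
    """
    if target_tau < 1:
        raise ValueError("tortuosity target must be >= 1")
    if n_points < 20:
        raise ValueError("need >= 20 points for a faithful arc")
    if target_tau == 1.0:
        return Contour(_sine_arc_points(0.0, length, n_points))
    lo, hi = 0.0, length
    while _polyline_tau(_sine_arc_points(hi, length, n_points)) < target_tau:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _polyline_tau(_sine_arc_points(mid, length, n_points)) < target_tau:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * length:
            break
    return Contour(_sine_arc_points(0.5 * (lo + hi), length, n_points))


def gen_tracks(
    velocity: float, duration: float, dt: float, seed: int = 0
) -> VesicleTrack:
    """A constant-speed vesicle track with seeded random direction changes.

    The path speed (total path length over duration) equals `velocity`
    exactly up to rounding; a zero velocity yields a stationary track and a
    warning (the streaming velocity of such a track is degenerate).
    """
    if velocity < 0 or duration <= 0 or dt <= 0:
        raise ValueError("velocity must be >= 0 and duration, dt positive")
    if dt >= duration:
        raise ValueError("dt must be smaller than the duration")
    if velocity == 0:
        warnings.warn("zero velocity: stationary (degenerate) track", stacklevel=2)
    rng = np.random.default_rng([seed % (2**31), 23])
    n_steps = int(round(duration / dt))
    times = dt * np.arange(n_steps + 1)
    headings = rng.uniform(0.0, 2.0 * math.pi, size=n_steps)
    steps = velocity * dt * np.column_stack([np.cos(headings), np.sin(headings)])
    positions = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return VesicleTrack(times=times, positions=positions)


def gen_hysteresis_path(
    area: float, n_points: int = 20, seed: int = 0
) -> HysteresisPath:
    """A seeded star-convex loop whose signed shoelace area equals `area`.

    Random radii at equally spaced angles are scaled so the enclosed area
    matches; a negative request reverses the orientation (clockwise,
    "inverse" hysteresis).
    """
    if n_points < 4:
        raise ValueError("need >= 4 points")
    if area == 0:
        raise ValueError("requested area must be nonzero")
    rng = np.random.default_rng([seed % (2**31), 31])
    angles = 2.0 * math.pi * np.arange(n_points) / n_points
    radii = rng.uniform(0.5, 1.5, size=n_points)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    x, y = pts[:, 0], pts[:, 1]
    raw = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    pts = pts * math.sqrt(abs(area) / raw)  # raw > 0: CCW star-convex loop
    if area < 0:
        pts = pts[::-1]
    return HysteresisPath(points=pts)


def scaled_scenario(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    """The same scenario with a different seed (convenience for sweeps)."""
    return replace(config, seed=seed)
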