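"""Cell pressure-probe water relations.

Calculators for the standard cell water-status quantities — water potential
composition (psi_w = psi_p + psi_s), volumetric elastic modulus
(eps = V*dP/dV), hydraulic conductivity from pressure-relaxation half-times
(Lp = ln2 * V / (A * T_half * (eps + pi))) — plus a single-exponential forward
simulator for relaxation traces, the van't Hoff concentration conversion and
small sampling/transpiration helpers.

Units are part of every signature: potentials and pressures in MPa, cell
volumes in pL for geometry bookkeeping and m^3 inside the Lp formula,
surface area in m^2, times in seconds.  Turgor is a gauge pressure and is
therefore clamped non-negative: negative inputs are domain errors, not
warnings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterStatus",
    "PressureStep",
    "CellGeometry",
    "RelaxationTrace",
    "MediaCondition",
    "GAS_CONSTANT",
    "compose_water_potential",
    "turgor_from_tissue",
    "media_potential_difference",
    "elastic_modulus",
    "hydraulic_conductivity",
    "half_time_from_lp",
    "simulate_pressure_relaxation",
    "measure_half_time",
    "vant_hoff_concentration",
    "sampled_volume_fraction",
    "meniscus_volume",
    "transpiration_rate",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314462

_ZERO_CELSIUS = 273.15


@dataclass(frozen=True)
class WaterStatus:
    """Turgor, osmotic and total water potential of one cell, MPa.

    The additive constraint psi_w = psi_p + psi_s is enforced at construction;
    osmotic pressure pi = -psi_s is exposed as a property.
    """

    psi_p: float
    psi_s: float
    psi_w: float

    def __post_init__(self) -> None:
        if self.psi_p < 0:
            raise ValueError(f"turgor pressure must be >= 0 MPa, got {self.psi_p}")
        if self.psi_s > 0:
            raise ValueError(f"osmotic potential must be <= 0 MPa, got {self.psi_s}")
        if abs(self.psi_w - (self.psi_p + self.psi_s)) > 1e-9:
            raise ValueError(
                "water potential must equal psi_p + psi_s: "
                f"{self.psi_w} != {self.psi_p} + {self.psi_s}"
            )

    @property
    def osmotic_pressure(self) -> float:
        """pi = -psi_s, MPa, >= 0."""
        return -self.psi_s


@dataclass(frozen=True)
class PressureStep:
    """An applied pressure pulse and the resulting volume change.

    volume: cell volume V (same volume unit as delta_v); delta_p: MPa;
    delta_v: nonzero, same sign as delta_p (pressurizing swells the cell).
    """

    volume: float
    delta_p: float
    delta_v: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")
        if self.delta_v == 0:
            raise ValueError("volume change must be nonzero")
        if self.delta_p * self.delta_v < 0:
            raise ValueError("delta_p and delta_v must have the same sign")


@dataclass(frozen=True)
class CellGeometry:
    """Cell dimensions: length/width in um, volume in pL, surface area in m^2."""

    length: float
    width: float
    volume_pl: float
    surface_area: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "volume_pl", "surface_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def volume_m3(self) -> float:
        return self.volume_pl * 1e-15


@dataclass(frozen=True)
class MediaCondition:
    """Water potential of the root medium, MPa, <= 0."""

    psi_o: float

    def __post_init__(self) -> None:
        if self.psi_o > 0:
            raise ValueError(f"media water potential must be <= 0 MPa, got {self.psi_o}")


@dataclass(frozen=True)
class RelaxationTrace:
    """A pressure-relaxation time course with its half-time.

    times in s, strictly increasing; pressures in MPa converging monotonically
    toward the equilibrium value; t_half > 0.
    """

    times: tuple[float, ...]
    pressures: tuple[float, ...]
    t_half: float

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("half-time must be positive")
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        if t.size != p.size or t.size < 2:
            raise ValueError("times and pressures must be equal length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        gap = np.abs(p - p[-1])
        if np.any(np.diff(gap) > 1e-12 * max(1.0, gap[0])):
            raise ValueError("pressures must converge monotonically to equilibrium")


def compose_water_potential(psi_p: float, psi_s: float) -> WaterStatus:
    """Combine turgor and osmotic potential into a full water status.

    psi_w = psi_p + psi_s.  The rearranged form for tissue data (turgor from
    psychrometer psi_w and osmometer psi_s) is `turgor_from_tissue`.
    """
    if psi_p < 0:
        raise ValueError(f"turgor pressure must be >= 0 MPa, got {psi_p}")
    if psi_s > 0:
        raise ValueError(f"osmotic potential must be <= 0 MPa, got {psi_s}")
    return WaterStatus(psi_p=psi_p, psi_s=psi_s, psi_w=psi_p + psi_s)


def turgor_from_tissue(psi_w: float, psi_s: float) -> float:
    """Turgor by subtraction, psi_p = psi_w - psi_s (tissue-level form)."""
    psi_p = psi_w - psi_s
    if psi_p < 0:
        raise ValueError(
            f"derived turgor is negative ({psi_p} MPa); psi_w below psi_s"
        )
    return psi_p


def media_potential_difference(control: MediaCondition, stress: MediaCondition) -> float:
    """Absolute treatment difference in media water potential, MPa."""
    return abs(stress.psi_o - control.psi_o)


def elastic_modulus(step: PressureStep) -> float:
    """Volumetric elastic modulus eps = V * dP / dV, MPa."""
    return step.volume * step.delta_p / step.delta_v


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


def hydraulic_conductivity(
    geometry: CellGeometry, t_half: float, epsilon: float, osmotic_pressure: float
) -> float:
    """Cell hydraulic conductivity Lp = ln2 * V / (A * T_half * (eps + pi)).

    Returns m s^-1 MPa^-1.  pi is the cell osmotic pressure (-psi_s), MPa.
    """
    _check_positive(t_half=t_half, epsilon=epsilon, osmotic_pressure=osmotic_pressure)
    return math.log(2.0) * geometry.volume_m3 / (
        geometry.surface_area * t_half * (epsilon + osmotic_pressure)
    )


def half_time_from_lp(
    geometry: CellGeometry, lp: float, epsilon: float, osmotic_pressure: float
) -> float:
    """Relaxation half-time implied by a hydraulic conductivity (inverse of Lp)."""
    _check_positive(lp=lp, epsilon=epsilon, osmotic_pressure=osmotic_pressure)
    return math.log(2.0) * geometry.volume_m3 / (
        geometry.surface_area * lp * (epsilon + osmotic_pressure)
    )


def simulate_pressure_relaxation(
    p0: float, p_eq: float, t_half: float, times
) -> RelaxationTrace:
    """Single-exponential pressure relaxation P(t) = p_eq + (p0-p_eq)*2^(-t/T_half).

    At t = T_half the pressure is exactly midway between p0 and p_eq.
    """
    if t_half <= 0:
        raise ValueError("half-time must be positive")
    t = np.asarray(list(times), dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(t < 0) or not np.all(np.diff(t) > 0):
        raise ValueError("times must be nonnegative and strictly increasing")
    p = p_eq + (p0 - p_eq) * np.exp(-math.log(2.0) * t / t_half)
    return RelaxationTrace(tuple(t.tolist()), tuple(p.tolist()), t_half)


def measure_half_time(trace: RelaxationTrace, p_eq: float | None = None) -> float:
    """Read the half-time off a trace: first time the gap to equilibrium halves.

    Linear interpolation between samples; `p_eq` defaults to the last sample.
    Used as the empirical counterpart of the stored `t_half`.
    """
    t = np.asarray(trace.times, dtype=float)
    p = np.asarray(trace.pressures, dtype=float)
    if p_eq is None:
        p_eq = float(p[-1])
    gap = np.abs(p - p_eq)
    if gap[0] == 0:
        raise ValueError("trace starts at equilibrium; no half-time to measure")
    target = gap[0] / 2.0
    below = np.nonzero(gap <= target)[0]
    if below.size == 0:
        raise ValueError("trace never reaches half its initial gap")
    i = int(below[0])
    if i == 0 or gap[i] == target:
        return float(t[i])
    # linear interpolation on the gap between samples i-1 and i
    frac = (gap[i - 1] - target) / (gap[i - 1] - gap[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def vant_hoff_concentration(delta_osmotic_pressure: float, temperature_c: float) -> float:
    """Solute concentration change implied by an osmotic-pressure change.

    c = dPsi_s * 1e6 / (R * T) in mol m^-3 == mM, with dPsi_s in MPa and
    T = temperature_c + 273.15 K.  Linear in the pressure difference.
    """
    if delta_osmotic_pressure < 0:
        raise ValueError("osmotic pressure difference must be >= 0")
    if temperature_c <= -_ZERO_CELSIUS:
        raise ValueError("temperature below absolute zero")
    kelvin = temperature_c + _ZERO_CELSIUS
    return delta_osmotic_pressure * 1e6 / (GAS_CONSTANT * kelvin)


def sampled_volume_fraction(sample_volume_pl: float, cell_volume_pl: float) -> float:
    """Sampled sap volume as a percentage of cell volume, in (0, 100]."""
    _check_positive(sample_volume_pl=sample_volume_pl, cell_volume_pl=cell_volume_pl)
    if sample_volume_pl > cell_volume_pl:
        raise ValueError("sample volume exceeds cell volume")
    return 100.0 * sample_volume_pl / cell_volume_pl


def meniscus_volume(distance_um: float, calibration) -> float:
    """Sap volume (pL) from the tip-to-meniscus distance via a calibration table.

    `calibration` is a sequence of (distance_um, volume_pl) pairs, monotone
    increasing and starting at (0, 0); interpolation is piecewise linear and
    extrapolation beyond the table is refused.  The anchor point used in
    practice is (500 um, 200 pL).
    """
    if distance_um < 0:
        raise ValueError("distance must be >= 0")
    table = sorted((float(d), float(v)) for d, v in calibration)
    if not table or table[0] != (0.0, 0.0):
        raise ValueError("calibration table must start at (0, 0)")
    d = np.array([row[0] for row in table])
    v = np.array([row[1] for row in table])
    if not (np.all(np.diff(d) > 0) and np.all(np.diff(v) > 0)):
        raise ValueError("calibration table must be strictly increasing")
    if distance_um > d[-1]:
        raise ValueError(
            f"distance {distance_um} um beyond calibration range (max {d[-1]} um); "
            "extrapolation refused"
        )
    return float(np.interp(distance_um, d, v))


def transpiration_rate(mass_loss_g: float, leaf_area_m2: float, duration_h: float) -> float:
    """Whole-plant transpiration rate, g m^-2 h^-1."""
    _check_positive(leaf_area_m2=leaf_area_m2, duration_h=duration_h)
    if mass_loss_g < 0:
        raise ValueError("mass loss must be >= 0")
    return mass_loss_g / (leaf_area_m2 * duration_h)
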