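"""Geometry of segmented TEM contours and cytoplasmic-streaming kinematics.

Crista shape is summarized by two scalars: tortuosity (arc-chord ratio of an
open crista contour, >= 1) and apex angle (mean opening angle at the two ends
of the long diameter of an intracrista space).  Section-level mitochondrial
volume uses a prolate-spheroid rule, organelle censuses are reduced to
percent-of-cell and percent-of-cytosol fractions, and vesicle tracks yield
the cytoplasmic streaming velocity.  TEM geometry is in nm, light-microscopy
geometry in um; no unit conversion happens inside these operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "Contour",
    "IntracristaRegion",
    "MitoSection",
    "OrganelleCensus",
    "VesicleTrack",
    "densify_polygon",
    "tortuosity",
    "apex_angle",
    "spheroid_volume",
    "census_fractions",
    "streaming_velocity",
    "rectangle_perimeter",
    "circuit_time",
]

ORGANELLE_CLASSES = ("vacuole", "nucleus", "mitochondria", "plastid", "peroxisome")


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    return arr


@dataclass(frozen=True)
class Contour:
    """An open polyline (ordered 2-D points, nm) traced along one crista."""

    points: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_points(self.points)
        object.__setattr__(self, "points", arr)
        if arr.shape[0] < 2:
            raise ValueError("contour needs at least 2 points")
        steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive contour points must be distinct")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass(frozen=True)
class IntracristaRegion:
    """A simple closed polygon (nm) bounding one intracrista space.

    `long_diameter` holds the indices of the two boundary vertices realizing
    the maximal pairwise distance; computed on construction when omitted.
    """

    points: np.ndarray
    long_diameter: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = _as_points(self.points)
        if arr.shape[0] >= 2 and np.allclose(arr[0], arr[-1]):
            arr = arr[:-1]  # drop an explicit closing vertex
        object.__setattr__(self, "points", arr)
        if arr.shape[0] < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        poly = Polygon(arr)
        if not poly.is_simple or poly.area <= 0:
            raise ValueError("polygon must be simple with positive area")
        if self.long_diameter is None:
            object.__setattr__(self, "long_diameter", self._max_pair(arr))
        else:
            i, j = self.long_diameter
            if not (0 <= i < arr.shape[0] and 0 <= j < arr.shape[0] and i != j):
                raise ValueError("long-diameter indices must be distinct boundary vertices")
            best = self._max_pair(arr)
            d_best = np.linalg.norm(arr[best[0]] - arr[best[1]])
            d_given = np.linalg.norm(arr[i] - arr[j])
            if not math.isclose(d_given, d_best, rel_tol=1e-9):
                raise ValueError("long-diameter endpoints must realize the maximal distance")

    @staticmethod
    def _max_pair(arr: np.ndarray) -> tuple[int, int]:
        d = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        return (int(min(i, j)), int(max(i, j)))

    @property
    def long_diameter_length(self) -> float:
        i, j = self.long_diameter
        return float(np.linalg.norm(self.points[i] - self.points[j]))

    @property
    def area(self) -> float:
        return float(Polygon(self.points).area)


@dataclass(frozen=True)
class MitoSection:
    """One sectioned mitochondrion: outline axes (nm) plus crista geometry."""

    major_axis: float
    minor_axis: float
    cristae: tuple[Contour, ...] = ()
    intracrista: tuple[IntracristaRegion, ...] = ()

    def __post_init__(self) -> None:
        if not self.major_axis >= self.minor_axis > 0:
            raise ValueError("require major_axis >= minor_axis > 0")

    @property
    def volume(self) -> float:
        return spheroid_volume(self.major_axis, self.minor_axis)


@dataclass(frozen=True)
class OrganelleCensus:
    """Per-class volume (or area) totals for one cell, shared units.

    `cell` is the whole-cell total; `cytosol` defaults to cell minus vacuole
    (everything outside the central vacuole).
    """

    cell: float
    vacuole: float = 0.0
    nucleus: float = 0.0
    mitochondria: float = 0.0
    plastid: float = 0.0
    peroxisome: float = 0.0
    cytosol: float | None = None

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell total must be positive")
        if self.cytosol is None:
            object.__setattr__(self, "cytosol", self.cell - self.vacuole)
        for name in ORGANELLE_CLASSES + ("cytosol",):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} total must be >= 0")
            if value > self.cell * (1 + 1e-12):
                raise ValueError(f"{name} total exceeds the cell total")


@dataclass(frozen=True)
class VesicleTrack:
    """Timestamped vesicle positions: times in s (strictly increasing), xy in um."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        xy = _as_points(self.positions)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", xy)
        if t.size < 2 or xy.shape[0] != t.size:
            raise ValueError("need >= 2 samples with matching times and positions")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def path_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.positions, axis=0), axis=1).sum())


def densify_polygon(points, max_step: float) -> np.ndarray:
    """Insert vertices along polygon edges so no edge exceeds `max_step`.

    Angle estimation needs several boundary samples near each apex; segmented
    polygons with long straight edges are densified before analysis.
    """
    arr = _as_points(points)
    out: list[np.ndarray] = []
    n = arr.shape[0]
    for i in range(n):
        a, b = arr[i], arr[(i + 1) % n]
        length = float(np.linalg.norm(b - a))
        pieces = max(1, int(math.ceil(length / max_step)))
        for k in range(pieces):
            out.append(a + (b - a) * (k / pieces))
    return np.array(out)


def tortuosity(contour: Contour) -> float:
    """Arc-chord ratio of an open crista contour: curve length over the
    end-to-end distance.  Always >= 1; equals 1 only for collinear points.
    Closed contours (coincident endpoints) have no chord and are rejected."""
    chord = contour.chord_length
    if chord == 0:
        raise ValueError("contour endpoints coincide; closed curve has no chord")
    return contour.arc_length / chord


def _direction_from_side(apex: np.ndarray, side: np.ndarray) -> np.ndarray:
    """Least-squares direction of the boundary leaving an apex.

    Principal component of the apex-anchored point cloud, oriented toward the
    side points' centroid.  Exact for points along a straight edge.
    """
    rel = side - apex
    # include the apex itself (the zero vector) in the fit
    cloud = np.vstack([np.zeros(2), rel])
    _, _, vt = np.linalg.svd(cloud - cloud.mean(axis=0), full_matrices=False)
    direction = vt[0]
    if direction @ rel.mean(axis=0) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def apex_angle(region: IntracristaRegion, window: float | None = None) -> float:
    """Mean opening angle (degrees) at the two long-diameter endpoints.

    At each endpoint the two boundary branches leaving it are fitted with
    least-squares lines over the vertices within `window` arc distance
    (default: 10% of the long diameter); the apex angle is the angle between
    the two fitted directions, in (0, 180).  The result is the mean over the
    two endpoints.
    """
    long_d = region.long_diameter_length
    if window is None:
        window = 0.10 * long_d
    if not 0 < window < long_d:
        raise ValueError("window must be positive and smaller than the long diameter")
    pts = region.points
    n = pts.shape[0]
    angles = []
    for apex_idx in region.long_diameter:
        apex = pts[apex_idx]
        sides = []
        for step in (+1, -1):
            collected = []
            dist = 0.0
            prev = apex
            k = apex_idx
            for _ in range(n - 1):
                k = (k + step) % n
                dist += float(np.linalg.norm(pts[k] - prev))
                if dist > window:
                    break
                collected.append(pts[k])
                prev = pts[k]
            if len(collected) < 1:
                raise ValueError(
                    "fewer than 2 boundary points within the window on one side "
                    "of a long-diameter endpoint; densify the polygon or widen "
                    "the window"
                )
            sides.append(np.array(collected))
        d1 = _direction_from_side(apex, sides[0])
        d2 = _direction_from_side(apex, sides[1])
        cos = float(np.clip(d1 @ d2, -1.0, 1.0))
        angle = math.degrees(math.acos(cos))
        if not 0 < angle < 180:
            raise ValueError("degenerate apex: boundary branches are collinear")
        angles.append(angle)
    return float(np.mean(angles))


def spheroid_volume(major_l: float, minor_w: float) -> float:
    """Prolate-spheroid volume (pi/6) * L * W^2 from section axes.

    The section-to-volume rule for mitochondrial volume; isolated here so an
    alternative stereological rule can be swapped in.
    """
    if not major_l >= minor_w > 0:
        raise ValueError("require major_l >= minor_w > 0")
    return math.pi / 6.0 * major_l * minor_w * minor_w


def census_fractions(census: OrganelleCensus) -> dict[str, dict[str, float]]:
    """Per-class percentages of the cell and of the cytosol.

    Returns {class: {"of_cell": %, "of_cytosol": %}}; the cytosol percentage
    is NaN when the cytosol total is zero.
    """
    out: dict[str, dict[str, float]] = {}
    for name in ORGANELLE_CLASSES:
        value = getattr(census, name)
        of_cell = 100.0 * value / census.cell
        of_cytosol = (
            100.0 * value / census.cytosol if census.cytosol > 0 else float("nan")
        )
        out[name] = {"of_cell": of_cell, "of_cytosol": of_cytosol}
    return out


def streaming_velocity(track: VesicleTrack) -> float:
    """Cytoplasmic streaming velocity: vesicle path length over duration, um/s."""
    if track.duration <= 0:
        raise ValueError("track duration must be positive")
    return track.path_length / track.duration


def rectangle_perimeter(length: float, width: float) -> float:
    """Perimeter 2*(L + W); the circumference along a rectangular vacuole, um."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return 2.0 * (length + width)


def circuit_time(perimeter: float, velocity: float) -> float:
    """Minutes for one streaming circuit of a perimeter, reported to 2 decimals."""
    if perimeter <= 0 or velocity <= 0:
        raise ValueError("perimeter and velocity must be positive")
    return round(perimeter / velocity / 60.0, 2)
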