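"""Delimited-table dialects for every pipeline stage.

All inputs and intermediates are small plain-text tables with mandatory
headers.  Readers validate the header and the numeric content and raise
errors that name the file, the offending column or row, and the expected
dialect; writers emit exactly the dialect the readers accept, so any
write-then-read round trip is the identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationHit, Peak
from .kinetics import HysteresisPath, TimeSeries
from .morphometrics import Contour, VesicleTrack
from .water import RelaxationTrace

__all__ = [
    "DialectError",
    "read_peaks",
    "write_peaks",
    "read_time_series",
    "write_time_series",
    "mean_series",
    "read_contours",
    "write_contours",
    "read_tracks",
    "write_tracks",
    "read_hysteresis",
    "write_hysteresis",
    "read_relaxation",
    "write_relaxation",
    "write_annotation",
]

PEAK_COLUMNS = ["mz", "intensity"]
SERIES_COLUMNS = ["cell_id", "treatment", "parameter", "time_h", "value"]
CONTOUR_COLUMNS = ["structure_id", "point_index", "x_nm", "y_nm", "kind"]
TRACK_COLUMNS = ["track_id", "t_s", "x_um", "y_um"]
HYSTERESIS_COLUMNS = ["step", "x_gradient_mpa", "y_value"]
RELAXATION_COLUMNS = ["time_s", "pressure_mpa"]
ANNOTATION_COLUMNS = [
    "mz",
    "intensity",
    "name",
    "ion_mode",
    "theoretical_mz",
    "ppm_error",
    "pathway_group",
]
CONTOUR_KINDS = {"crista", "intracrista", "mito_outline"}
TREATMENTS = {"control", "salt"}


class DialectError(ValueError):
    """A table does not match its declared dialect."""


def _load(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DialectError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DialectError(
            f"{path}: missing column(s) {missing}; expected dialect {columns}"
        )
    return df[columns]


def _numeric(df: pd.DataFrame, path, columns: list[str]) -> pd.DataFrame:
    for column in columns:
        converted = pd.to_numeric(df[column], errors="coerce")
        bad = df.index[converted.isna() & df[column].notna()]
        if len(bad) > 0:
            raise DialectError(
                f"{path}: malformed numeric in column {column!r} at row {bad[0] + 2}"
            )
        if converted.isna().any():
            row = int(df.index[converted.isna()][0]) + 2
            raise DialectError(f"{path}: empty value in column {column!r} at row {row}")
        df = df.assign(**{column: converted})
    return df


def read_peaks(path) -> list[Peak]:
    """Peak table: CSV with columns mz, intensity (one spectrum per file)."""
    df = _numeric(_load(path, PEAK_COLUMNS), path, PEAK_COLUMNS)
    return [Peak(mz=row.mz, intensity=row.intensity) for row in df.itertuples()]


def write_peaks(path, peaks: list[Peak]) -> None:
    pd.DataFrame(
        {"mz": [p.mz for p in peaks], "intensity": [p.intensity for p in peaks]}
    ).to_csv(path, index=False)


def read_time_series(path) -> pd.DataFrame:
    """Long-format time courses: cell_id, treatment, parameter, time_h, value."""
    df = _numeric(_load(path, SERIES_COLUMNS), path, ["time_h", "value"])
    bad = set(df["treatment"]) - TREATMENTS
    if bad:
        raise DialectError(
            f"{path}: unknown treatment value(s) {sorted(bad)}; expected {sorted(TREATMENTS)}"
        )
    return df


def write_time_series(path, series: dict[str, TimeSeries], treatment: str = "salt",
                      cell_id: str = "mean") -> None:
    rows = []
    for label, ts in sorted(series.items()):
        for t, v in zip(ts.times, ts.values):
            rows.append((cell_id, treatment, label, t, v))
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def mean_series(df: pd.DataFrame, parameter: str, treatment: str = "salt") -> TimeSeries:
    """Average a parameter's trajectories across cells into one mean curve."""
    sub = df[(df["parameter"] == parameter) & (df["treatment"] == treatment)]
    if sub.empty:
        raise DialectError(f"no rows for parameter {parameter!r} / treatment {treatment!r}")
    grouped = sub.groupby("time_h", sort=True)["value"].mean()
    return TimeSeries(
        times=grouped.index.to_numpy(dtype=float),
        values=grouped.to_numpy(dtype=float),
        label=parameter,
    )


def read_contours(path) -> dict[str, tuple[str, np.ndarray]]:
    """Contour table -> {structure_id: (kind, (n, 2) points in nm)}."""
    df = _numeric(_load(path, CONTOUR_COLUMNS), path, ["point_index", "x_nm", "y_nm"])
    bad = set(df["kind"]) - CONTOUR_KINDS
    if bad:
        raise DialectError(
            f"{path}: unknown contour kind(s) {sorted(bad)}; expected {sorted(CONTOUR_KINDS)}"
        )
    out: dict[str, tuple[str, np.ndarray]] = {}
    for sid, group in df.groupby("structure_id", sort=True):
        group = group.sort_values("point_index")
        kinds = set(group["kind"])
        if len(kinds) != 1:
            raise DialectError(f"{path}: structure {sid!r} mixes kinds {sorted(kinds)}")
        out[str(sid)] = (kinds.pop(), group[["x_nm", "y_nm"]].to_numpy(dtype=float))
    return out


def write_contours(path, contours: dict[str, tuple[str, np.ndarray]]) -> None:
    rows = []
    for sid, (kind, points) in sorted(contours.items()):
        for index, (x, y) in enumerate(np.asarray(points, dtype=float)):
            rows.append((sid, index, x, y, kind))
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def read_tracks(path) -> dict[str, VesicleTrack]:
    """Track table -> {track_id: VesicleTrack} (times s, positions um)."""
    df = _numeric(_load(path, TRACK_COLUMNS), path, ["t_s", "x_um", "y_um"])
    out: dict[str, VesicleTrack] = {}
    for tid, group in df.groupby("track_id", sort=True):
        group = group.sort_values("t_s")
        out[str(tid)] = VesicleTrack(
            times=group["t_s"].to_numpy(dtype=float),
            positions=group[["x_um", "y_um"]].to_numpy(dtype=float),
        )
    return out


def write_tracks(path, tracks: dict[str, VesicleTrack]) -> None:
    rows = []
    for tid, track in sorted(tracks.items()):
        for t, (x, y) in zip(track.times, track.positions):
            rows.append((tid, t, x, y))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_hysteresis(path) -> HysteresisPath:
    """Hysteresis path: step, x_gradient_mpa, y_value, ordered by step."""
    df = _numeric(
        _load(path, HYSTERESIS_COLUMNS), path, ["step", "x_gradient_mpa", "y_value"]
    )
    df = df.sort_values("step")
    return HysteresisPath(points=df[["x_gradient_mpa", "y_value"]].to_numpy(dtype=float))


def write_hysteresis(path, hyst: HysteresisPath) -> None:
    pts = hyst.points
    pd.DataFrame(
        {
            "step": np.arange(pts.shape[0]),
            "x_gradient_mpa": pts[:, 0],
            "y_value": pts[:, 1],
        }
    ).to_csv(path, index=False)


def read_relaxation(path) -> tuple[np.ndarray, np.ndarray]:
    """Relaxation trace columns time_s, pressure_mpa -> (times, pressures)."""
    df = _numeric(_load(path, RELAXATION_COLUMNS), path, RELAXATION_COLUMNS)
    return df["time_s"].to_numpy(dtype=float), df["pressure_mpa"].to_numpy(dtype=float)


def write_relaxation(path, trace: RelaxationTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "pressure_mpa": trace.pressures}
    ).to_csv(path, index=False)


def write_annotation(path, hits: list[AnnotationHit]) -> None:
    """Annotation output: mz, intensity, name, ion_mode, theoretical_mz,
    ppm_error, pathway_group."""
    rows = [
        (
            h.peak.mz,
            h.peak.intensity,
            h.record.name,
            h.ion.mode.value,
            h.theoretical_mz,
            h.ppm_error,
            h.record.pathway_group,
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
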