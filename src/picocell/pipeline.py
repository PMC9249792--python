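"""Orchestration: one reproducible run from synthetic inputs to stage tables.

`run_pipeline` executes simulate -> annotate -> kinetics -> morphometrics ->
water relations, writing one CSV per stage plus a JSON manifest (config echo,
seed, version, row counts).  Identical config and seed give byte-identical
outputs; any stage failure aborts with the stage name and the offending
input.  No stage mutates another stage's inputs — every intermediate is a
file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, annotation, io, kinetics, morphometrics, synthetic, water

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline", "simulate_inputs"]


@dataclass(frozen=True)
class RunConfig:
    """Run-wide knobs; the defaults are the study's stated rules.

    tolerance_ppm: annotation match tolerance (< 5 ppm identification rule).
    lod_multiplier: limit of detection as a multiple of baseline noise (3x).
    grid_step_h: dense grid step for derivative curves.
    apex_window_frac: apex-angle fit window as a fraction of the long diameter.
    baseline_noise: baseline noise level of the simulated spectra.
    """

    tolerance_ppm: float = 5.0
    lod_multiplier: float = 3.0
    grid_step_h: float = 0.01
    apex_window_frac: float = 0.10
    baseline_noise: float = 10.0
    seed: int = 0
    out_dir: str = "picocell_run"

    def __post_init__(self) -> None:
        for name in (
            "tolerance_ppm",
            "lod_multiplier",
            "grid_step_h",
            "apex_window_frac",
            "baseline_noise",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def load_config(path) -> RunConfig:
    """Read a flat key-value config file (one `key = value` per line)."""
    values: dict[str, object] = {}
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (part.strip() for part in line.partition("="))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key == "out_dir":
            values[key] = value
        elif key == "seed":
            values[key] = int(value)
        else:
            values[key] = float(value)
    return RunConfig(**values)


def simulate_inputs(seed: int, out_dir, baseline_noise: float = 10.0) -> dict[str, Path]:
    """Write the four synthetic input tables for a run (the `simulate` stage)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "time_series": out / "time_series.csv",
        "peaks": out / "peaks.csv",
        "contours": out / "contours.csv",
        "tracks": out / "tracks.csv",
    }

    scenario = synthetic.default_scenario(seed=seed)
    io.write_time_series(paths["time_series"], synthetic.gen_time_courses(scenario))

    db = annotation.load_metabolite_db()
    spec = synthetic.SpectrumSpec(
        records=tuple((record, 1000.0) for record in db),
        baseline_noise=baseline_noise,
        seed=seed,
    )
    peaks, _ = synthetic.gen_spectrum(spec)
    io.write_peaks(paths["peaks"], peaks)

    rng_targets = [1.1 + 0.05 * k for k in range(8)]
    contours = {
        f"crista_{k:02d}": ("crista", synthetic.gen_contour(tau).points)
        for k, tau in enumerate(rng_targets)
    }
    io.write_contours(paths["contours"], contours)

    tracks = {
        f"vesicle_{k}": synthetic.gen_tracks(4.57, duration=6.0, dt=0.2, seed=seed + k)
        for k in range(5)
    }
    io.write_tracks(paths["tracks"], tracks)
    return paths


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    inputs_dir = out / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    paths = _stage(
        "simulate", simulate_inputs, config.seed, inputs_dir, config.baseline_noise
    )

    # annotate: LOD filter then ppm matching against the bundled table
    def annotate_stage() -> int:
        peaks = io.read_peaks(paths["peaks"])
        detectable = annotation.lod_filter(
            peaks, baseline_noise=3.0 * config.baseline_noise / config.lod_multiplier
        )
        hits = annotation.annotate_peaks(
            detectable, annotation.load_metabolite_db(), config.tolerance_ppm
        )
        io.write_annotation(out / "annotation.csv", hits)
        groups = sorted(annotation.PATHWAY_GROUPS)
        pd.DataFrame(
            {
                "pathway_group": groups,
                "cumulative_intensity": [
                    annotation.group_cumulative_intensity(hits, g) for g in groups
                ],
            }
        ).to_csv(out / "group_intensity.csv", index=False)
        return len(hits)

    counts["annotation"] = _stage("annotate", annotate_stage)

    # kinetics: dT_df per parameter, tau-vs-CL regression, hysteresis loops
    def kinetics_stage() -> int:
        df = io.read_time_series(paths["time_series"])
        labels = sorted(df["parameter"].unique())
        curves = [
            (
                label,
                kinetics.derivative_curve(
                    io.mean_series(df, label),
                    config.grid_step_h,
                    steady_state_start=True,
                ),
            )
            for label in labels
        ]
        ordered, flagged = kinetics.rank_delta_t_df(curves)
        pd.DataFrame(
            {
                "parameter": [label for label, _ in ordered] + flagged,
                "delta_t_df_h": [round(d.time, 2) for _, d in ordered]
                + [float("nan")] * len(flagged),
                "sign": [d.sign for _, d in ordered] + [0] * len(flagged),
            }
        ).to_csv(out / "delta_t_df.csv", index=False)

        tau = io.mean_series(df, "tau")
        cl = io.mean_series(df, "CL")
        fit = kinetics.linear_regression(cl.values, tau.values)
        pd.DataFrame(
            [{"x": "CL", "y": "tau", "slope": fit.slope,
              "intercept": fit.intercept, "r_squared": fit.r_squared}]
        ).to_csv(out / "regression.csv", index=False)

        rows = []
        for label, area in (("V_o", 1.0), ("V_Mito_over_V_o", -1.0)):
            path = synthetic.gen_hysteresis_path(area, seed=config.seed)
            measured, orientation = kinetics.hysteresis_area(path)
            io.write_hysteresis(out / f"hysteresis_{label}.csv", path)
            rows.append((label, measured, orientation))
        pd.DataFrame(rows, columns=["quantity", "signed_area", "orientation"]).to_csv(
            out / "hysteresis.csv", index=False
        )
        return len(ordered)

    counts["delta_t_df"] = _stage("kinetics", kinetics_stage)

    # morphometrics: crista tortuosity, streaming velocity, vacuole circuit
    def morpho_stage() -> int:
        contours = io.read_contours(paths["contours"])
        rows = [
            (sid, morphometrics.tortuosity(morphometrics.Contour(points)))
            for sid, (kind, points) in sorted(contours.items())
            if kind == "crista"
        ]
        pd.DataFrame(rows, columns=["structure_id", "tortuosity"]).to_csv(
            out / "tortuosity.csv", index=False
        )
        tracks = io.read_tracks(paths["tracks"])
        velocities = {
            tid: morphometrics.streaming_velocity(track)
            for tid, track in sorted(tracks.items())
        }
        mean_velocity = sum(velocities.values()) / len(velocities)
        perimeter = morphometrics.rectangle_perimeter(298.0, 37.0)
        pd.DataFrame(
            [
                {
                    "mean_velocity_um_s": mean_velocity,
                    "vacuole_perimeter_um": perimeter,
                    "circuit_time_min": morphometrics.circuit_time(
                        perimeter, mean_velocity
                    ),
                }
            ]
        ).to_csv(out / "streaming.csv", index=False)
        return len(rows)

    counts["tortuosity"] = _stage("morphometrics", morpho_stage)

    # water relations: compose potentials from the simulated trajectories
    def water_stage() -> int:
        df = io.read_time_series(paths["time_series"])
        psi_p = io.mean_series(df, "psi_p")
        psi_s = io.mean_series(df, "psi_s")
        rows = []
        for t, p, s in zip(psi_p.times, psi_p.values, psi_s.values):
            status = water.compose_water_potential(max(p, 0.0), min(s, 0.0))
            rows.append((t, status.psi_p, status.psi_s, status.psi_w))
        pd.DataFrame(rows, columns=["time_h", "psi_p", "psi_s", "psi_w"]).to_csv(
            out / "water_status.csv", index=False
        )
        delta_psi_s = float(abs(psi_s.values[-1] - psi_s.values[0]))
        pd.DataFrame(
            [
                {
                    "delta_psi_s_mpa": delta_psi_s,
                    "vant_hoff_mM_at_28C": water.vant_hoff_concentration(
                        delta_psi_s, 28.0
                    ),
                }
            ]
        ).to_csv(out / "vant_hoff.csv", index=False)
        return len(rows)

    counts["water_status"] = _stage("water_relations", water_stage)

    manifest = {
        "package": "picocell",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "row_counts": counts,
        "stages": [
            "simulate",
            "annotate",
            "kinetics",
            "morphometrics",
            "water_relations",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
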