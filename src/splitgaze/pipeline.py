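"""End-to-end orchestration: landmarks -> geometry -> map -> optics -> gaze,
and flight tracks -> kinematics, with persisted stage tables and a summary
report of the per-section statistics and their comparative ratios."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flight_kinematics as fk
from . import gaze_model as gm
from . import lens_optics as lo
from .landmarks_io import FlightTrack, read_flight_track, read_landmarks
from .lens_geometry import geometry_table, reconstruct_eye
from .ommatidial_map import build_eye_map

logger = logging.getLogger("splitgaze")

__all__ = ["RunConfig", "run_eye_pipeline", "run_flight_pipeline"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-loadable)."""

    landmarks_path: str | None = None
    track_path: str | None = None
    out_dir: str = "splitgaze_out"
    sphere_radius: float = 10.0  # mm
    refractive_index: float = 1.4
    focal_formula: str = "front_focal"
    ommatidium_length: float = 34.0  # um
    sweep_step: float = 1.0  # deg
    pitch_range: tuple[float, float] = (0.0, 150.0)
    yaw_range: tuple[float, float] = (-90.0, 90.0)
    roll_range: tuple[float, float] = (-50.0, 50.0)
    bin_width: float = 2.0  # cm/s
    frame_rate: float = 7000.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for key in ("pitch_range", "yaw_range", "roll_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (output location and logging
        verbosity excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _section_stats(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
        "n": int(len(v)),
    }


def run_eye_pipeline(config: RunConfig, lenses=None, head=None) -> dict:
    """Run the full eye analysis and return the summary report (dict).

    Inputs come from ``config.landmarks_path`` unless ``lenses`` (and
    optionally ``head``) are passed directly. Stage tables (geometry, map,
    gaze sweeps) are written under ``config.out_dir``; the report itself is
    written as ``summary.json``. Deterministic for fixed inputs and config.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("eye pipeline start (config %s)", config.config_hash())
    if lenses is None:
        if not config.landmarks_path or not Path(config.landmarks_path).exists():
            raise FileNotFoundError(
                f"landmark input not found: {config.landmarks_path!r}"
            )
        lenses, head = read_landmarks(config.landmarks_path)
    if not lenses:
        raise ValueError("no lenses in input")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geoms = reconstruct_eye(lenses)
    logger.info("reconstructed %d lenses", len(geoms))
    gtab = geometry_table(geoms)
    eye_map = build_eye_map(geoms)
    mtab = eye_map.to_frame()
    n_far = int(mtab["far_neighbor"].sum())
    if n_far:
        logger.warning("%d record(s) have a 6th neighbor beyond the cutoff", n_far)

    ocfg = lo.OpticsConfig(
        refractive_index=config.refractive_index,
        formula=config.focal_formula,
        ommatidium_length=config.ommatidium_length,
    )
    focal, depth = lo.optics_from_geometry(gtab["curvature_radius"].to_numpy(), ocfg)
    gtab["focal_length"] = focal
    gtab["focal_depth_fraction"] = depth
    gtab.to_csv(out / "lens_geometry.csv", index=False)
    mtab.to_csv(out / "eye_map.csv", index=False)

    report: dict = {"config_hash": config.config_hash(), "sections": {}, "focal_formula": ocfg.formula}
    axes_by_sec = {}
    for sec in ("dorsal", "ventral"):
        sel = gtab[gtab["section"] == sec]
        if sel.empty:
            continue
        axes_by_sec[sec] = sel[["axis_x", "axis_y", "axis_z"]].to_numpy()
        io = mtab.loc[mtab["section"] == sec, "interommatidial_angle"].to_numpy()
        report["sections"][sec] = {
            "count": int(len(sel)),
            "diameter_um": _section_stats(sel["diameter"].to_numpy()),
            "aperture_area_um2": _section_stats(sel["aperture_area"].to_numpy()),
            "curvature_radius_um": _section_stats(sel["curvature_radius"].to_numpy()),
            "focal_length_um": _section_stats(sel["focal_length"].to_numpy()),
            "focal_depth_fraction": _section_stats(sel["focal_depth_fraction"].to_numpy()),
            "interommatidial_angle_deg": _section_stats(io),
        }

    if len(axes_by_sec) == 2:
        report["section_gaze_separation_deg"] = gm.section_gaze_separation(
            axes_by_sec["dorsal"], axes_by_sec["ventral"]
        )
        sd, sv = report["sections"]["dorsal"], report["sections"]["ventral"]
        report["relative_differences_pct"] = {
            "diameter": lo.relative_difference(
                sd["diameter_um"]["mean"], sv["diameter_um"]["mean"]
            ),
            "interommatidial_angle": lo.relative_difference(
                sd["interommatidial_angle_deg"]["mean"],
                sv["interommatidial_angle_deg"]["mean"],
            ),
            "curvature_radius": lo.relative_difference(
                sd["curvature_radius_um"]["mean"], sv["curvature_radius_um"]["mean"]
            ),
            "focal_length": lo.relative_difference(
                sd["focal_length_um"]["mean"], sv["focal_length_um"]["mean"]
            ),
        }
        # gaze sweeps on the virtual sphere (eye coordinates are um; the
        # sphere lives in mm -> convert ray origins)
        centers = gtab[["center_x", "center_y", "center_z"]].to_numpy()
        axes = gtab[["axis_x", "axis_y", "axis_z"]].to_numpy()
        conv_right = gm.convergence_point(centers, axes) / 1000.0  # mm
        conv_left = gm.mirror_sagittal(conv_right)
        sphere = gm.SphereConfig(
            radius=config.sphere_radius, origin=0.5 * (conv_right + conv_left)
        )
        origins = {sec: conv_right for sec in axes_by_sec}
        sweeps = []
        for axis_name, rng in (
            ("pitch", config.pitch_range),
            ("yaw", config.yaw_range),
            ("roll", config.roll_range),
        ):
            sweeps.append(
                gm.gaze_sweep(
                    axes_by_sec, axis_name, rng, step=config.sweep_step,
                    sphere=sphere, ray_origins_by_section=origins,
                )
            )
        sweep_tab = pd.concat(sweeps, ignore_index=True)
        sweep_tab.to_csv(out / "gaze_sweeps.csv", index=False)
        report["sphere_origin_mm"] = sphere.origin.tolist()

    (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("eye pipeline done: %s", out / "summary.json")
    return report


def run_flight_pipeline(config: RunConfig, track: FlightTrack | None = None) -> dict:
    """Run the flight-kinematics analysis and return the summary (dict).

    Writes per-frame kinematics and the binned speed-pitch curve under
    ``config.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if track is None:
        if not config.track_path or not Path(config.track_path).exists():
            raise FileNotFoundError(f"track input not found: {config.track_path!r}")
        track = read_flight_track(config.track_path, config.frame_rate)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    speed = fk.forward_velocity(track)
    pitch = fk.track_pitch_series(track)
    per_frame = pd.DataFrame(
        {"t": track.times, "speed_cm_s": speed, "pitch_deg": pitch}
    )
    per_frame.to_csv(out / "flight_kinematics.csv", index=False)
    curve = fk.bin_pitch_by_speed(speed, pitch, bin_width=config.bin_width)
    curve.to_frame().to_csv(out / "binned_pitch.csv", index=False)

    # slope of binned pitch vs binned speed (descriptive; ordinary LS)
    import statsmodels.api as sm

    ok = np.isfinite(curve.mean) & (curve.n > 0)
    slope = float("nan")
    if ok.sum() >= 2:
        X = sm.add_constant(curve.bin_centers[ok])
        fit = sm.OLS(curve.mean[ok], X).fit()
        slope = float(fit.params[1])
    n_edge = max(2, min(10, track.n_frames // 10))
    summary = {
        "config_hash": config.config_hash(),
        "n_frames": track.n_frames,
        "duration_s": track.duration,
        "mean_speed_cm_s": float(np.mean(speed)),
        "max_speed_cm_s": float(np.max(speed)),
        "mean_pitch_start_deg": float(np.mean(pitch[:n_edge])),
        "mean_pitch_end_deg": float(np.mean(pitch[-n_edge:])),
        "binned_slope_deg_per_cm_s": slope,
    }
    if track.abdomen_tip is not None:
        bl = float(
            np.median(
                [fk.body_length(h, a) for h, a in zip(track.head, track.abdomen_tip)]
            )
        )
        summary["body_length_mm"] = bl
        summary["max_speed_body_lengths_s"] = fk.speed_in_body_lengths(
            summary["max_speed_cm_s"], bl
        )
    (out / "flight_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("flight pipeline done: %s", out / "flight_summary.json")
    return summary
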