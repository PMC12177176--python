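"""Flight and head kinematics from tracked points.

Body pitch is the angle between the thorax-to-head vector and the horizontal,
measured in the vertical plane spanned by the vertical axis and a horizontal
forward reference direction (by default the track's net horizontal
displacement): 0 deg = horizontal head-forward, 90 deg = vertical, >90 deg =
pitched past vertical (head behind the thorax). Forward speed is the
horizontal-plane speed of the tracked head point (total 3D speed available
via ``total=True``), central-differenced at interior frames.

Variable-length flight bouts are compared on a common normalized time base
via cubic-spline resampling, and the speed-pitch relation is summarized by
binning pitch against forward speed (bin width 2 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .landmarks_io import FlightTrack, HeadMarkerTrack

__all__ = [
    "BinnedPitchCurve",
    "body_pitch",
    "forward_velocity",
    "normalize_time",
    "bin_pitch_by_speed",
    "body_length",
    "speed_in_body_lengths",
    "head_angle",
    "track_pitch_series",
]


def body_pitch(
    head_pt: np.ndarray, thorax_pt: np.ndarray, forward: np.ndarray | None = None
) -> float:
    """Body pitch angle (degrees, [0, 180]) from head and thorax points.

    ``forward`` is the horizontal reference direction (default +x); only its
    horizontal components are used.
    """
    v = np.asarray(head_pt, dtype=float) - np.asarray(thorax_pt, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("head and thorax points coincide")
    if forward is None:
        f_dir = np.array([1.0, 0.0])
    else:
        f_dir = np.asarray(forward, dtype=float)[:2]
        nf = np.linalg.norm(f_dir)
        if nf == 0:
            raise ValueError("forward reference has no horizontal component")
        f_dir = f_dir / nf
    f = v[:2] @ f_dir
    hyp = np.hypot(f, v[2])
    if hyp == 0:
        raise ValueError("body axis has no extent in the pitch plane")
    return float(np.degrees(np.arccos(np.clip(f / hyp, -1.0, 1.0))))


def track_pitch_series(track: FlightTrack) -> np.ndarray:
    """Per-frame body pitch (degrees) using the track's net horizontal
    displacement as the forward reference."""
    disp = track.head[-1] - track.head[0]
    forward = disp if np.linalg.norm(disp[:2]) > 0 else np.array([1.0, 0.0, 0.0])
    return np.array(
        [body_pitch(h, t, forward) for h, t in zip(track.head, track.thorax)]
    )


def forward_velocity(
    track: FlightTrack, point: str = "head", total: bool = False
) -> np.ndarray:
    """Per-frame forward speed in cm/s.

    Horizontal-plane speed by default (``total=True`` includes the vertical
    component). Central differences at interior frames, one-sided at the
    ends. Track coordinates are mm; 1 mm/s = 0.1 cm/s.
    """
    if track.n_frames < 3:
        raise ValueError("need >=3 frames for velocity estimation")
    if point == "head":
        p = track.head
    elif point == "thorax":
        p = track.thorax
    elif point == "midpoint":
        p = 0.5 * (track.head + track.thorax)
    else:
        raise ValueError(f"unknown point {point!r}")
    dt = 1.0 / track.frame_rate
    vel = np.gradient(p, dt, axis=0)  # mm/s; central interior, one-sided ends
    comp = vel if total else vel[:, :2]
    return np.linalg.norm(comp, axis=1) / 10.0


def normalize_time(series: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a scalar series to ``n_out`` points on normalized time [0, 1]
    with a natural cubic spline; the endpoints are preserved exactly."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("need a 1D series of length >= 4 for cubic resampling")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    x = np.linspace(0.0, 1.0, len(y))
    cs = CubicSpline(x, y, bc_type="natural")
    xo = np.linspace(0.0, 1.0, n_out)
    out = cs(xo)
    out[0], out[-1] = y[0], y[-1]
    return out


@dataclass
class BinnedPitchCurve:
    """Body pitch binned by forward speed (contiguous bins of fixed width)."""

    bin_centers: np.ndarray  # cm/s
    mean: np.ndarray  # degrees; NaN for empty bins
    sd: np.ndarray  # degrees; NaN for bins with < 2 points
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "speed_bin_center": self.bin_centers,
                "pitch_mean": self.mean,
                "pitch_sd": self.sd,
                "n": self.n,
            }
        )


def bin_pitch_by_speed(
    speeds: np.ndarray, pitches: np.ndarray, bin_width: float = 2.0
) -> BinnedPitchCurve:
    """Per-speed-bin mean, SD and count of body pitch.

    Bins are contiguous [k*w, (k+1)*w) from zero to the maximum observed
    speed. Empty bins keep NaN mean; single-observation bins have NaN SD.
    """
    v = np.asarray(speeds, dtype=float)
    b = np.asarray(pitches, dtype=float)
    if v.shape != b.shape:
        raise ValueError("speed and pitch series must have equal length")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    n_bins = int(np.floor(v.max() / bin_width)) + 1
    idx = np.minimum((v / bin_width).astype(int), n_bins - 1)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        sel = b[idx == k]
        n[k] = len(sel)
        if len(sel) >= 1:
            mean[k] = sel.mean()
        if len(sel) >= 2:
            sd[k] = sel.std(ddof=1)
    return BinnedPitchCurve(bin_centers=centers, mean=mean, sd=sd, n=n)


def body_length(head_pt: np.ndarray, abdomen_tip_pt: np.ndarray) -> float:
    """Body length in mm: head tip to abdomen tip."""
    L = float(np.linalg.norm(np.asarray(head_pt) - np.asarray(abdomen_tip_pt)))
    if L <= 0:
        raise ValueError("zero body length")
    return L


def speed_in_body_lengths(speed: float, body_length_mm: float) -> float:
    """Convert a speed in cm/s to body lengths per second."""
    if body_length_mm <= 0:
        raise ValueError("body length must be > 0")
    return speed * 10.0 / body_length_mm


def head_angle(track: HeadMarkerTrack) -> dict:
    """Head roll/pitch wobble from a two-marker track.

    The per-frame angle of the line joining the two markers against the
    horizontal image axis is unwrapped and reported as the deviation (delta)
    from its series mean. Frames with coincident markers are flagged (NaN)
    and excluded from the summary statistics.

    Returns a dict with keys ``delta_deg`` (per-frame series),
    ``mean_abs_deg``, ``peak_to_peak_deg``, ``flagged_frames``.
    """
    d = track.marker_b[:, :2] - track.marker_a[:, :2]
    norms = np.linalg.norm(d, axis=1)
    flagged = np.flatnonzero(norms == 0)
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    ang[norms == 0] = np.nan
    valid = np.isfinite(ang)
    ang_v = np.degrees(np.unwrap(np.radians(ang[valid])))
    delta = np.full(len(ang), np.nan)
    delta[valid] = ang_v - ang_v.mean()
    return {
        "delta_deg": delta,
        "mean_abs_deg": float(np.nanmean(np.abs(delta))),
        "peak_to_peak_deg": float(np.nanmax(delta) - np.nanmin(delta)),
        "flagged_frames": flagged.tolist(),
    }
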