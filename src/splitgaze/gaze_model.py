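"""Mean gaze per eye section and its change under body rotation.

The mean visual gaze of an eye section is the normalized sum of the visual
axes of its ommatidia. To express gaze in panoramic coordinates, the mean
gaze ray is intersected with a virtual sphere (default radius 10 mm) fixed in
the lab frame; the intersection point gives azimuth and elevation about the
sphere origin. The sphere origin defaults to the midpoint between the left
and right convergence points of all visual axes (one eye mirrored across the
sagittal plane when only one side was digitized). Because the sphere radius
is three orders of magnitude larger than the head, azimuth and elevation are
nearly independent of the exact rotation point inside the animal.

Body rotations (yaw about z, pitch about y, roll about x; intrinsic z-y-x
composition) are applied about the center of mass in configurable steps,
rotating both the gaze directions and the ray origins while the sphere stays
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ommatidial_map import angular_difference

__all__ = [
    "BodyPose",
    "SphereConfig",
    "DegenerateGazeError",
    "mean_gaze",
    "convergence_point",
    "rotation_matrix",
    "project_to_sphere",
    "gaze_sweep",
    "section_gaze_separation",
]


class DegenerateGazeError(ValueError):
    """Raised when a set of axes has a (near-)zero resultant."""


@dataclass
class BodyPose:
    """Body orientation (degrees) and center of mass (mm, body frame)."""

    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        if not np.all(np.isfinite([self.yaw, self.pitch, self.roll])):
            raise ValueError("pose angles must be finite")


@dataclass
class SphereConfig:
    """Virtual projection sphere: radius in mm and origin in lab-frame mm."""

    radius: float = 10.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")


def mean_gaze(axes: np.ndarray) -> np.ndarray:
    """Normalized vector sum of a section's visual axes."""
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if len(axes) == 0:
        raise DegenerateGazeError("no axes")
    s = axes.sum(axis=0)
    n = np.linalg.norm(s)
    if n < 1e-9 * len(axes):
        raise DegenerateGazeError("axes cancel; mean gaze undefined")
    return s / n


def convergence_point(origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Least-squares point minimizing summed squared distances to a set of
    lines given by ``origins`` and ``directions``.

    Solves the normal equations sum(I - d d^T) x = sum((I - d d^T) o).
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if len(o) < 2 or len(o) != len(d):
        raise ValueError("need >=2 lines with matching origins/directions")
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for oi, di in zip(o, d):
        P = np.eye(3) - np.outer(di, di)
        A += P
        b += P @ oi
    if np.linalg.cond(A) > 1e12:
        raise ValueError("lines are (near-)parallel; convergence point undefined")
    return np.linalg.solve(A, b)


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry_pitch(a: float) -> np.ndarray:
    # sign chosen so positive pitch lifts the anterior (+x) tip toward +z
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]], dtype=float)


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotation_matrix(pose: BodyPose) -> np.ndarray:
    """Body rotation matrix, intrinsic z(yaw) . y(pitch) . x(roll).

    Right-handed; yaw +90 deg maps anterior (1,0,0) to (0,1,0); positive
    pitch lifts the anterior axis tip dorsally.
    """
    return (
        _rz(np.radians(pose.yaw))
        @ _ry_pitch(np.radians(pose.pitch))
        @ _rx(np.radians(pose.roll))
    )


def project_to_sphere(
    ray_origin: np.ndarray,
    direction: np.ndarray,
    sphere: SphereConfig = SphereConfig(),
) -> tuple[float, float]:
    """Azimuth/elevation (degrees) of the forward intersection of a gaze ray
    with the virtual sphere.

    The ray origin must lie inside the sphere (there is then exactly one
    forward intersection).
    """
    o = np.asarray(ray_origin, dtype=float) - sphere.origin
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    r2 = sphere.radius**2
    if o @ o >= r2:
        raise ValueError("ray origin lies outside the projection sphere")
    # |o + t d|^2 = r^2, take the positive root
    b = o @ d
    t = -b + np.sqrt(b * b - (o @ o - r2))
    q = o + t * d
    az = float(np.degrees(np.arctan2(q[1], q[0])))
    el = float(np.degrees(np.arcsin(np.clip(q[2] / sphere.radius, -1.0, 1.0))))
    if az <= -180.0:
        az += 360.0
    return az, el


def section_gaze_separation(dorsal_axes: np.ndarray, ventral_axes: np.ndarray) -> float:
    """Angle (degrees) between the mean gaze vectors of the two eye sections."""
    return angular_difference(mean_gaze(dorsal_axes), mean_gaze(ventral_axes))


def gaze_sweep(
    eye_axes_by_section: dict[str, np.ndarray],
    rotation_axis: str,
    angle_range: tuple[float, float],
    step: float = 1.0,
    sphere: SphereConfig | None = None,
    ray_origins_by_section: dict[str, np.ndarray] | None = None,
    com: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sweep one body rotation and tabulate per-section mean gaze.

    For every angle in ``angle_range`` (inclusive, ``step`` degrees apart) the
    body — gaze directions and their ray origins — is rotated about the
    center of mass ``com`` (default: the sphere origin), translation ignored,
    and each section's mean gaze is projected onto the fixed sphere.

    Returns a long-format DataFrame with columns section, axis, angle_deg,
    az_deg, el_deg, degenerate. Poses at which a section's mean gaze is
    degenerate are flagged, not dropped.
    """
    if rotation_axis not in ("yaw", "pitch", "roll"):
        raise ValueError(f"unknown rotation axis {rotation_axis!r}")
    if step <= 0:
        raise ValueError("step must be > 0")
    sphere = sphere or SphereConfig()
    com = sphere.origin.copy() if com is None else np.asarray(com, dtype=float)
    lo, hi = angle_range
    angles = np.arange(lo, hi + step / 2, step) if hi > lo else np.array([lo])
    rows = []
    for sec, axes in eye_axes_by_section.items():
        axes = np.atleast_2d(np.asarray(axes, dtype=float))
        if ray_origins_by_section is not None and sec in ray_origins_by_section:
            origin0 = np.asarray(ray_origins_by_section[sec], dtype=float)
        else:
            origin0 = com
        for ang in angles:
            pose = BodyPose(**{rotation_axis: float(ang)})
            R = rotation_matrix(pose)
            degenerate = False
            try:
                g = mean_gaze((R @ axes.T).T)
            except DegenerateGazeError:
                rows.append(
                    dict(section=sec, axis=rotation_axis, angle_deg=float(ang),
                         az_deg=np.nan, el_deg=np.nan, degenerate=True)
                )
                continue
            origin = com + R @ (origin0 - com)
            az, el = project_to_sphere(origin, g, sphere)
            rows.append(
                dict(section=sec, axis=rotation_axis, angle_deg=float(ang),
                     az_deg=az, el_deg=el, degenerate=degenerate)
            )
    return pd.DataFrame(rows)


def mirror_sagittal(points: np.ndarray) -> np.ndarray:
    """Mirror lab/head-frame points or vectors across the sagittal (x-z) plane."""
    out = np.array(points, dtype=float, copy=True)
    out[..., 1] *= -1.0
    return out
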