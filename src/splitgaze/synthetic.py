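"""Synthetic split compound eyes and flight trajectories with ground truth.

No raw landmark or video data accompany the measurements this package
models, so every analysis stage is exercised against generated data whose
true geometry is known exactly.

``generate_eye`` builds a two-section (dorsal/ventral) eye: visual-axis
directions are laid out on two spherical caps whose mean gazes subtend a
configurable separation (default 53 deg), with the local angular pitch
between facets increasing radially from ~1 deg at the cap center to ~30 deg
at the rim. Each facet is then realized as six base points on a circle of a
drawn diameter plus an apex at the spherical-cap height consistent with a
drawn outer curvature radius, and optional Gaussian digitization noise is
added to all seven landmarks. The zero-noise eye is exactly recoverable by
the reconstruction pipeline.

``generate_flight`` builds a straight flight bout whose forward speed decays
smoothly from a fast post-takeoff value toward a landing value, with body
pitch following the linear model beta = beta0 - k*v (plus per-frame jitter);
head/thorax/abdomen points are placed consistently with the pitch series.

All generators are pure functions of (spec, seed): the same seed reproduces
the output bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks_io import FlightTrack, HeadFrame, HeadMarkerTrack, LensLandmarks
from .lens_geometry import _plane_basis

__all__ = [
    "SyntheticEyeSpec",
    "SyntheticFlightSpec",
    "HeadWobbleSpec",
    "EyeGroundTruth",
    "FlightGroundTruth",
    "generate_eye",
    "generate_flight",
    "generate_head_wobble",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _direction(az_deg: float, el_deg: float) -> np.ndarray:
    az, el = np.radians(az_deg), np.radians(el_deg)
    return np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )


@dataclass
class SyntheticEyeSpec:
    """Study conditions for a synthetic split eye.

    Counts, diameter and curvature distributions, the section-gaze
    separation, the center-to-edge pitch gradient and the head width default
    to the measured whitefly values. ``cap_radius_*`` set the angular radius
    of each section's facet cap (section flatness); their defaults are a
    one-off calibration so that the per-section mean interommatidial angles
    land near the measured 12.5 deg (dorsal) and 16.2 deg (ventral).
    """

    n_dorsal: int = 42
    n_ventral: int = 31
    section_separation: float = 53.0  # deg between section mean gazes
    diameter_mean_dorsal: float = 6.35  # um
    diameter_sd_dorsal: float = 0.51
    diameter_mean_ventral: float = 7.67
    diameter_sd_ventral: float = 0.89
    curvature_mean_dorsal: float = 3.98  # um
    curvature_sd_dorsal: float = 0.72
    curvature_mean_ventral: float = 5.81
    curvature_sd_ventral: float = 0.92
    pitch_center: float = 1.0  # deg, interommatidial pitch at cap center
    pitch_edge: float = 30.0  # deg, at cap rim
    cap_radius_dorsal: float = 67.0  # deg, angular radius of the facet cap
    cap_radius_ventral: float = 85.0
    landmark_noise_sd: float = 0.0  # um, isotropic Gaussian on all landmarks
    head_width: float = 126.0  # um (female)
    eye_radius: float = 40.0  # um, distance of lens bases from the eye center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dorsal <= 0 or self.n_ventral <= 0:
            raise ValueError("facet counts must be positive")
        if not (0.0 < self.section_separation < 180.0):
            raise ValueError("section separation must be in (0, 180) deg")
        for name in (
            "diameter_sd_dorsal",
            "diameter_sd_ventral",
            "curvature_sd_dorsal",
            "curvature_sd_ventral",
            "landmark_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EyeGroundTruth:
    """Exact per-lens geometry used to build a synthetic eye."""

    axes: np.ndarray  # (n, 3) true visual axes
    diameters: np.ndarray  # um
    curvature_radii: np.ndarray  # um
    cap_heights: np.ndarray  # um
    base_centers: np.ndarray  # (n, 3) um
    sections: np.ndarray  # str array
    mean_gaze: dict  # section -> unit vector
    section_separation: float  # deg
    eye_center: np.ndarray  # common point all axes pass through, um
    n_redraws: int  # curvature draws rejected for R < a


def _cap_directions(
    n: int, center: np.ndarray, cap_radius_deg: float,
    pitch_center: float, pitch_edge: float, phase: float,
) -> np.ndarray:
    """Sunflower (golden-angle) layout on a spherical cap with a radially
    graded local pitch.

    The target local spacing g(theta) interpolates linearly from
    ``pitch_center`` at the cap center to ``pitch_edge`` at the rim; facet
    density is proportional to 1/g^2, so radial positions are drawn from the
    inverse of the cumulative count integral(sin(t) / g(t)^2 dt).
    """
    theta_max = np.radians(cap_radius_deg)
    tt = np.linspace(0.0, theta_max, 2001)
    g = np.radians(pitch_center) + (np.radians(pitch_edge) - np.radians(pitch_center)) * (
        tt / theta_max
    )
    dens = np.sin(tt) / g**2
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(tt))])
    cum /= cum[-1]
    q = (np.arange(n) + 0.5) / n
    theta = np.interp(q, cum, tt)
    phi = phase + np.arange(n) * GOLDEN_ANGLE
    e1, e2 = _plane_basis(center)
    c = center / np.linalg.norm(center)
    return (
        np.cos(theta)[:, None] * c
        + np.sin(theta)[:, None]
        * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (minimal angle)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        e1, _ = _plane_basis(a)
        return 2.0 * np.outer(e1, e1) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _section_centers(separation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Nominal section mean-gaze directions for the right eye.

    The dorsal section looks lateral-and-up; the ventral section sits near
    the sagittal plane (azimuth -20 deg) so that body pitch sweeps its gaze
    mainly in elevation and body roll mainly in azimuth, while the dorsal
    section behaves the opposite way. The ventral elevation is solved so the
    pair subtends exactly ``separation_deg``; if no solution exists at that
    azimuth, the ventral direction is walked along the great circle from the
    dorsal one instead.
    """
    c_d = _direction(-90.0, 50.0)
    az_v = -20.0
    # angle(c_d, dir(az_v, E)) = s  =>  A cos E + B sin E = cos s
    a_rad = np.radians(az_v)
    A = c_d[0] * np.cos(a_rad) + c_d[1] * np.sin(a_rad)
    B = c_d[2]
    s = np.radians(separation_deg)
    amp = np.hypot(A, B)
    if abs(np.cos(s)) <= amp:
        phase = np.arctan2(B, A)
        dev = np.arccos(np.cos(s) / amp)
        # of the two solutions pick the lower-elevation (more ventral) one
        el = np.degrees(min(phase - dev, phase + dev, key=abs))
        c_v = _direction(az_v, el)
    else:
        target = _direction(az_v, -15.0)
        w = target - (target @ c_d) * c_d
        w /= np.linalg.norm(w)
        c_v = np.cos(s) * c_d + np.sin(s) * w
    return c_d, c_v / np.linalg.norm(c_v)


def generate_eye(
    spec: SyntheticEyeSpec = SyntheticEyeSpec(),
) -> tuple[list[LensLandmarks], HeadFrame, EyeGroundTruth]:
    """Generate one synthetic right eye: landmarks, head frame, ground truth.

    Every lens's six base points lie exactly on a circle of the drawn
    diameter in the plane orthogonal to its true axis, and the apex sits at
    the spherical-cap height h = R - sqrt(R^2 - a^2) above the base plane, so
    the zero-noise eye is exactly recoverable. Curvature draws with R < a
    (no cap exists) are redrawn; the count is reported in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    c_d, c_v = _section_centers(spec.section_separation)
    sections_cfg = [
        ("dorsal", spec.n_dorsal, c_d, spec.cap_radius_dorsal,
         spec.diameter_mean_dorsal, spec.diameter_sd_dorsal,
         spec.curvature_mean_dorsal, spec.curvature_sd_dorsal),
        ("ventral", spec.n_ventral, c_v, spec.cap_radius_ventral,
         spec.diameter_mean_ventral, spec.diameter_sd_ventral,
         spec.curvature_mean_ventral, spec.curvature_sd_ventral),
    ]
    eye_center = np.array([20.0, -45.0, 0.0])
    lenses: list[LensLandmarks] = []
    axes_all, dia_all, R_all, h_all, centers_all, sec_all = [], [], [], [], [], []
    mean_gaze: dict[str, np.ndarray] = {}
    n_redraws = 0
    next_id = 1
    for (sec, n, c_sec, cap_r, d_mu, d_sd, R_mu, R_sd) in sections_cfg:
        phase = rng.uniform(0.0, 2 * np.pi)
        axes = _cap_directions(n, c_sec, cap_r, spec.pitch_center, spec.pitch_edge, phase)
        # align the section's exact mean gaze with its nominal direction so
        # the generated separation equals the spec value exactly
        m = axes.sum(axis=0)
        m /= np.linalg.norm(m)
        axes = (_rotation_between(m, c_sec) @ axes.T).T
        mean_gaze[sec] = c_sec
        for u in axes:
            d = -1.0
            while d < 1.0:  # truncate unphysically small diameters
                d = rng.normal(d_mu, d_sd)
            a = d / 2.0
            R = -1.0
            while R < a:  # spherical cap requires R >= base radius
                R_try = rng.normal(R_mu, R_sd)
                if R_try < a:
                    n_redraws += 1
                    continue
                R = R_try
            h = R - np.sqrt(R * R - a * a)
            b = eye_center + spec.eye_radius * u
            e1, e2 = _plane_basis(u)
            ph0 = rng.uniform(0.0, 2 * np.pi)
            ang = ph0 + np.arange(6) * (np.pi / 3.0)
            base = b + a * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
            apex = b + h * u
            if spec.landmark_noise_sd > 0:
                base = base + rng.normal(0.0, spec.landmark_noise_sd, base.shape)
                apex = apex + rng.normal(0.0, spec.landmark_noise_sd, 3)
            lenses.append(
                LensLandmarks(
                    ommatidium_id=next_id,
                    animal_id="synthetic",
                    sex="female",
                    side="right",
                    section=sec,
                    base_points=base,
                    apex_point=apex,
                )
            )
            axes_all.append(u)
            dia_all.append(d)
            R_all.append(R)
            h_all.append(h)
            centers_all.append(b)
            sec_all.append(sec)
            next_id += 1
    half = spec.head_width / 2.0
    head = HeadFrame(
        ocellus_left=np.array([10.0, half, 25.0]),
        ocellus_right=np.array([10.0, -half, 25.0]),
    )
    gt = EyeGroundTruth(
        axes=np.array(axes_all),
        diameters=np.array(dia_all),
        curvature_radii=np.array(R_all),
        cap_heights=np.array(h_all),
        base_centers=np.array(centers_all),
        sections=np.array(sec_all),
        mean_gaze=mean_gaze,
        section_separation=spec.section_separation,
        eye_center=eye_center,
        n_redraws=n_redraws,
    )
    return lenses, head, gt


# ---------------------------------------------------------------------------
# Flight


@dataclass
class SyntheticFlightSpec:
    """Study conditions for a synthetic straight flight bout.

    Speed decays smoothly from the post-takeoff value to the landing value
    (measured means 27.5 and 17.8 cm/s); body pitch follows the linear model
    beta = beta0 - k*v fixed by the measured (speed, pitch) endpoints
    (27.5 cm/s, 48.1 deg) and (17.8 cm/s, 113 deg), plus per-frame Gaussian
    jitter representing within-bout posture variability.
    """

    n_frames: int = 260  # ~37 ms at 7000 fps, the mean bout duration
    fps: float = 7000.0
    speed_start: float = 27.5  # cm/s
    speed_end: float = 17.8  # cm/s
    pitch_at_start_speed: float = 48.1  # deg at speed_start
    pitch_at_end_speed: float = 113.0  # deg at speed_end
    pitch_jitter_sd: float = 5.0  # deg per frame
    tracking_noise_sd: float = 0.0  # mm on every tracked point
    body_length: float = 0.92  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames")
        if self.speed_start == self.speed_end:
            raise ValueError("speed endpoints must differ (pitch model slope)")

    @property
    def pitch_slope(self) -> float:
        """k in beta = beta0 - k*v (deg per cm/s); positive k means pitch
        falls as speed rises."""
        return (self.pitch_at_end_speed - self.pitch_at_start_speed) / (
            self.speed_start - self.speed_end
        )

    @property
    def pitch_intercept(self) -> float:
        return self.pitch_at_start_speed + self.pitch_slope * self.speed_start


@dataclass
class FlightGroundTruth:
    speed: np.ndarray  # cm/s, true horizontal speed of the head point
    pitch: np.ndarray  # deg, true pitch used to place the thorax
    pitch_slope: float  # k of the generating model (deg per cm/s)
    pitch_intercept: float  # beta0
    body_length: float  # mm


def generate_flight(
    spec: SyntheticFlightSpec = SyntheticFlightSpec(),
) -> tuple[FlightTrack, FlightGroundTruth]:
    """Generate a straight flight bout along +x with known speed and pitch."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, 1.0, spec.n_frames)
    s = t * t * (3.0 - 2.0 * t)  # smoothstep
    speed = spec.speed_start + (spec.speed_end - spec.speed_start) * s
    pitch_model = spec.pitch_intercept - spec.pitch_slope * speed
    pitch = pitch_model + rng.normal(0.0, spec.pitch_jitter_sd, spec.n_frames)
    dt = 1.0 / spec.fps
    # head point integrates the horizontal speed profile (cm/s -> mm/frame)
    x = np.concatenate([[0.0], np.cumsum(speed[:-1] * 10.0 * dt)])
    head = np.column_stack([x, np.zeros_like(x), np.full_like(x, 10.0)])
    b = np.radians(pitch)
    axis = np.column_stack([np.cos(b), np.zeros_like(b), np.sin(b)])
    thorax = head - 0.6 * spec.body_length * axis
    abdomen = head - spec.body_length * axis
    if spec.tracking_noise_sd > 0:
        head = head + rng.normal(0.0, spec.tracking_noise_sd, head.shape)
        thorax = thorax + rng.normal(0.0, spec.tracking_noise_sd, thorax.shape)
        abdomen = abdomen + rng.normal(0.0, spec.tracking_noise_sd, abdomen.shape)
    track = FlightTrack(
        frame_rate=spec.fps, head=head, thorax=thorax, abdomen_tip=abdomen
    )
    gt = FlightGroundTruth(
        speed=speed,
        pitch=pitch,
        pitch_slope=spec.pitch_slope,
        pitch_intercept=spec.pitch_intercept,
        body_length=spec.body_length,
    )
    return track, gt


@dataclass
class HeadWobbleSpec:
    """Tethered head-wobble conditions: two markers rotating sinusoidally
    about their midpoint. Default amplitudes follow the measured mean angular
    changes (0.95 deg roll, 1.88 deg pitch)."""

    view: str = "frontal"  # frontal -> roll, side -> pitch
    amplitude: float | None = None  # deg; None -> view default
    frequency: float = 170.0  # Hz, near the wingbeat frequency
    n_frames: int = 700
    fps: float = 7000.0
    marker_separation: float = 0.3  # mm
    marker_noise_sd: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude is None:
            self.amplitude = 0.95 if self.view == "frontal" else 1.88


def generate_head_wobble(
    spec: HeadWobbleSpec = HeadWobbleSpec(),
) -> tuple[HeadMarkerTrack, dict]:
    """Two-marker track with sinusoidal line-angle wobble of known amplitude."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) / spec.fps
    ang = np.radians(spec.amplitude) * np.sin(2 * np.pi * spec.frequency * t)
    r = spec.marker_separation / 2.0
    mid = np.zeros((spec.n_frames, 2))
    offs = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    a = mid - offs
    b = mid + offs
    if spec.marker_noise_sd > 0:
        a = a + rng.normal(0.0, spec.marker_noise_sd, a.shape)
        b = b + rng.normal(0.0, spec.marker_noise_sd, b.shape)
    track = HeadMarkerTrack(
        view=spec.view, marker_a=a, marker_b=b, frame_rate=spec.fps
    )
    gt = {"amplitude_deg": spec.amplitude, "peak_to_peak_deg": 2.0 * spec.amplitude}
    return track, gt
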