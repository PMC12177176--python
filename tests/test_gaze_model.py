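"""Mean gaze, convergence point, body rotations and sphere projection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from splitgaze.gaze_model import (
    BodyPose,
    DegenerateGazeError,
    SphereConfig,
    convergence_point,
    gaze_sweep,
    mean_gaze,
    project_to_sphere,
    rotation_matrix,
    section_gaze_separation,
)
from tests.conftest import stable_angle_deg


# --- mean gaze --------------------------------------------------------------


def test_mean_gaze_cases():
    v = np.array([0.6, 0.8, 0.0])
    np.testing.assert_allclose(mean_gaze(v[None, :]), v)
    eps = 1e-3
    pair = np.array([[1, 0, eps], [1, 0, -eps]])
    np.testing.assert_allclose(mean_gaze(pair), [1, 0, 0], atol=1e-15)
    with pytest.raises(DegenerateGazeError):
        mean_gaze(np.array([[0, 0, 1.0], [0, 0, -1.0]]))


# --- convergence point ------------------------------------------------------


def test_lines_through_common_point():
    rng = np.random.default_rng(0)
    P = np.array([1.0, -2.0, 3.0])
    dirs = rng.normal(size=(10, 3))
    origins = P + rng.uniform(1, 5, (10, 1)) * dirs
    np.testing.assert_allclose(convergence_point(origins, dirs), P, atol=1e-9)


def test_skew_perpendicular_lines_give_midpoint():
    # line 1 along x at z=0; line 2 along y at z=d -> midpoint at z=d/2
    d = 2.0
    origins = np.array([[0, 0, 0], [0, 0, d]], dtype=float)
    dirs = np.array([[1, 0, 0], [0, 1, 0]], dtype=float)
    np.testing.assert_allclose(convergence_point(origins, dirs), [0, 0, d / 2], atol=1e-12)


def test_noisy_lines_match_scipy_oracle():
    """Normal-equations solution matches an independent numerical
    minimization of the summed squared line distances to 1e-9."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(4)
    P = np.array([0.5, 1.5, -0.7])
    dirs = rng.normal(size=(20, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    origins = P + rng.uniform(1, 4, (20, 1)) * dirs + rng.normal(0, 0.05, (20, 3))
    x = convergence_point(origins, dirs)

    def cost(p):
        r = origins - p
        perp = r - (np.sum(r * dirs, axis=1, keepdims=True)) * dirs
        return np.sum(perp**2)

    res = minimize(cost, x0=np.zeros(3), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 10000})
    np.testing.assert_allclose(x, res.x, atol=1e-6)
    assert cost(x) <= cost(res.x) + 1e-9
    # recovered point within a noise-scaled bound of the true source
    assert np.linalg.norm(x - P) < 3 * 0.05


def test_parallel_lines_error():
    origins = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0]], dtype=float)
    dirs = np.tile([1.0, 0, 0], (3, 1))
    with pytest.raises(ValueError):
        convergence_point(origins, dirs)


# --- rotations --------------------------------------------------------------


def test_rotation_conventions():
    np.testing.assert_allclose(rotation_matrix(BodyPose()), np.eye(3), atol=1e-15)
    R = rotation_matrix(BodyPose(yaw=90.0))
    np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)
    Rp = rotation_matrix(BodyPose(pitch=90.0))
    np.testing.assert_allclose(Rp @ [1, 0, 0], [0, 0, 1], atol=1e-12)  # tip lifts


def test_rotation_matches_quaternion_oracle():
    """Intrinsic z-y-x composition agrees with scipy quaternion rotations to
    1e-12 (pitch sign flipped: positive pitch lifts the anterior tip)."""
    rng = np.random.default_rng(8)
    for _ in range(50):
        yaw, pitch, roll = rng.uniform(-180, 180, 3)
        R = rotation_matrix(BodyPose(yaw=yaw, pitch=pitch, roll=roll))
        q = Rotation.from_euler("ZYX", [yaw, -pitch, roll], degrees=True)
        np.testing.assert_allclose(R, q.as_matrix(), atol=1e-12)


def test_rotation_orthonormal():
    rng = np.random.default_rng(9)
    for _ in range(100):
        R = rotation_matrix(BodyPose(*rng.uniform(-180, 180, 3)))
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


# --- sphere projection ------------------------------------------------------


def test_projection_from_center():
    assert project_to_sphere(np.zeros(3), np.array([1.0, 0, 0])) == pytest.approx((0, 0))
    az, el = project_to_sphere(np.zeros(3), np.array([0.0, 0, 1]))
    assert el == pytest.approx(90.0)


def test_projection_offset_origin():
    az, el = project_to_sphere(
        np.array([0.0, 1.0, 0.0]), np.array([1.0, 0, 0]), SphereConfig(radius=10.0)
    )
    assert az == pytest.approx(np.degrees(np.arctan2(1, np.sqrt(99))), abs=1e-9)
    assert el == pytest.approx(0.0, abs=1e-12)


def test_projection_origin_outside_sphere():
    with pytest.raises(ValueError):
        project_to_sphere(np.array([11.0, 0, 0]), np.array([1.0, 0, 0]))


def test_origin_offset_bounded_on_10mm_sphere():
    """Shifting the ray origin by <= 1 mm moves (Az, EL) by <= arcsin(1/10)
    over 1000 random configurations."""
    rng = np.random.default_rng(10)
    bound = np.degrees(np.arcsin(1.0 / 10.0)) + 1e-9
    sphere = SphereConfig(radius=10.0)
    for _ in range(1000):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        o = rng.normal(size=3)
        o = o / np.linalg.norm(o) * rng.uniform(0, 1.0)
        az0, el0 = project_to_sphere(np.zeros(3), d, sphere)
        az1, el1 = project_to_sphere(o, d, sphere)
        p0 = np.array(
            [np.cos(np.radians(el0)) * np.cos(np.radians(az0)),
             np.cos(np.radians(el0)) * np.sin(np.radians(az0)),
             np.sin(np.radians(el0))]
        )
        p1 = np.array(
            [np.cos(np.radians(el1)) * np.cos(np.radians(az1)),
             np.cos(np.radians(el1)) * np.sin(np.radians(az1)),
             np.sin(np.radians(el1))]
        )
        assert stable_angle_deg(p0, p1) <= bound


# --- sweeps -----------------------------------------------------------------


def _axes_by_section(gt):
    return {s: gt.axes[gt.sections == s] for s in ("dorsal", "ventral")}


def test_yaw_sweep_leaves_elevation_constant(clean_geoms):
    """With the sphere origin on the yaw axis, yaw produces purely horizontal
    gaze shifts: elevation constant to 1e-6 deg, azimuth degree-for-degree."""
    _, gt = clean_geoms
    df = gaze_sweep(_axes_by_section(gt), "yaw", (-90, 90), step=1.0)
    for sec, sub in df.groupby("section"):
        assert sub.el_deg.max() - sub.el_deg.min() < 1e-6
        daz = np.diff(np.unwrap(np.radians(sub.az_deg.to_numpy())))
        np.testing.assert_allclose(np.degrees(daz), 1.0, atol=1e-9)


def test_pitch_sweep_of_sagittal_gaze_is_degree_for_degree():
    axes = {"dorsal": np.array([[1.0, 0.0, 0.0]])}
    df = gaze_sweep(axes, "pitch", (0, 60), step=1.0)
    np.testing.assert_allclose(np.diff(df.el_deg), 1.0, atol=1e-9)
    np.testing.assert_allclose(df.az_deg, 0.0, atol=1e-9)


def test_zero_width_range_returns_static_gaze(clean_geoms):
    _, gt = clean_geoms
    df = gaze_sweep(_axes_by_section(gt), "pitch", (0, 0), step=1.0)
    assert len(df) == 2  # one row per section
    assert (df.angle_deg == 0).all()


def test_sweep_continuity(clean_geoms):
    """Consecutive 1-degree samples move < 3 degrees in great-circle terms."""
    _, gt = clean_geoms
    for axis in ("yaw", "pitch", "roll"):
        df = gaze_sweep(_axes_by_section(gt), axis, (-50, 50), step=1.0)
        for _, sub in df.groupby("section"):
            az = np.radians(sub.az_deg.to_numpy())
            el = np.radians(sub.el_deg.to_numpy())
            p = np.column_stack(
                [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
            )
            steps = stable_angle_deg(p[:-1], p[1:])
            assert np.max(np.atleast_1d(steps)) < 3.0


def test_pitch_roll_complementarity(clean_geoms):
    """Over matched +-30 degree sweeps, the section with the wider azimuth
    range under pitch has the wider elevation range under roll, and vice
    versa (the split-eye division of labor)."""
    _, gt = clean_geoms
    axes = _axes_by_section(gt)
    ranges = {}
    for axis in ("pitch", "roll"):
        df = gaze_sweep(axes, axis, (-30, 30), step=1.0)
        for sec, sub in df.groupby("section"):
            ranges[axis, sec, "az"] = sub.az_deg.max() - sub.az_deg.min()
            ranges[axis, sec, "el"] = sub.el_deg.max() - sub.el_deg.min()
    # dorsal: azimuth-dominant under pitch, elevation-dominant under roll
    assert ranges["pitch", "dorsal", "az"] > ranges["pitch", "ventral", "az"]
    assert ranges["roll", "dorsal", "el"] > ranges["roll", "ventral", "el"]
    # ventral: the complementary pattern
    assert ranges["pitch", "ventral", "el"] > ranges["pitch", "dorsal", "el"]
    assert ranges["roll", "ventral", "az"] > ranges["roll", "dorsal", "az"]


# --- separation -------------------------------------------------------------


def test_section_separation_cases(clean_geoms):
    _, gt = clean_geoms
    d = gt.axes[gt.sections == "dorsal"]
    v = gt.axes[gt.sections == "ventral"]
    assert section_gaze_separation(d, d) == pytest.approx(0.0, abs=1e-9)
    assert section_gaze_separation(d, v) == pytest.approx(53.0, abs=1e-6)
    assert section_gaze_separation(
        np.array([[1.0, 0, 0]]), np.array([[0.0, 1, 0]])
    ) == pytest.approx(90.0)
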