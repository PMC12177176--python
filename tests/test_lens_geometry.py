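"""Per-lens geometry: plane/circle fits, visual axis, spherical-cap radius."""

import numpy as np
import pytest

from splitgaze.landmarks_io import HeadFrame, LensLandmarks
from splitgaze.lens_geometry import (
    DegenerateGeometryError,
    curvature_radius,
    fit_basis_plane,
    fit_circle,
    normalize_to_head_width,
    projected_polygon_area,
    reconstruct_eye,
    reconstruct_lens,
    visual_axis,
)
from splitgaze.ommatidial_map import angular_difference
from splitgaze.synthetic import SyntheticEyeSpec, generate_eye
from tests.conftest import random_rotation, regular_hexagon, stable_angle_deg


def _lens(base, apex, oid=1):
    return LensLandmarks(oid, "a", "female", "right", "dorsal", base, apex)


# --- normalization ----------------------------------------------------------


def test_normalize_divides_by_head_width():
    base = regular_hexagon(radius=1.0)
    lm = _lens(base + [1, 0, 0], np.array([1.0, 0.0, 1.0]))
    head = HeadFrame(np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0]))  # width 2
    (out,) = normalize_to_head_width([lm], head)
    np.testing.assert_allclose(out.apex_point, [0.5, 0.0, 0.5])
    np.testing.assert_allclose(out.base_points, (base + [1, 0, 0]) / 2.0)


def test_normalize_with_unit_head_width_is_identity():
    lm = _lens(regular_hexagon(), np.array([0.0, 0.0, 1.0]))
    head = HeadFrame(np.array([0.0, 0.5, 0.0]), np.array([0.0, -0.5, 0.0]))
    (out,) = normalize_to_head_width([lm], head)
    np.testing.assert_array_equal(out.base_points, lm.base_points)


def test_angles_invariant_under_normalization(clean_eye):
    """Interommatidial angles are scale-free: identical before/after
    normalization to head width, to 1e-9 degrees."""
    lenses, head, _ = clean_eye
    sub = lenses[:12]
    axes_raw = np.array([reconstruct_lens(lm).visual_axis for lm in sub])
    axes_norm = np.array(
        [reconstruct_lens(lm).visual_axis for lm in normalize_to_head_width(sub, head)]
    )
    for i in range(len(sub) - 1):
        a1 = angular_difference(axes_raw[i], axes_raw[i + 1])
        a2 = angular_difference(axes_norm[i], axes_norm[i + 1])
        assert a1 == pytest.approx(a2, abs=1e-9)


# --- basis plane ------------------------------------------------------------


def test_plane_of_flat_hexagon():
    normal, pts2d, area = fit_basis_plane(regular_hexagon(radius=1.0, z=3.0))
    assert abs(normal[2]) == pytest.approx(1.0, abs=1e-12)
    assert area == pytest.approx(3 * np.sqrt(3) / 2, rel=1e-12)
    assert pts2d.shape == (6, 2)


def test_plane_beats_every_grid_normal_with_jitter():
    """With out-of-plane jitter the returned plane's projected area is >= the
    projected area onto every normal of a 2-degree hemispheric grid."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        base = regular_hexagon(radius=1.0)
        base[:, 2] += rng.normal(0, 0.05, 6)
        R = random_rotation(rng)
        base = base @ R.T
        normal, _, area = fit_basis_plane(base)
        for el in np.arange(0.0, 90.1, 2.0):
            for az in np.arange(0.0, 360.0, 2.0):
                n = np.array(
                    [
                        np.cos(np.radians(el)) * np.cos(np.radians(az)),
                        np.cos(np.radians(el)) * np.sin(np.radians(az)),
                        np.sin(np.radians(el)),
                    ]
                )
                assert area >= projected_polygon_area(base, n) - 1e-12


@pytest.mark.parametrize(
    "points",
    [
        np.zeros((6, 3)),  # coincident
        np.column_stack([np.arange(6.0), np.arange(6.0), np.zeros(6)]),  # collinear
    ],
)
def test_degenerate_base_points_raise(points):
    with pytest.raises(DegenerateGeometryError):
        fit_basis_plane(points)


# --- circle fit -------------------------------------------------------------


@pytest.mark.parametrize("radius", [1.0, 3.175])
def test_exact_hexagon_circle(radius):
    pts = regular_hexagon(radius=radius)[:, :2]
    center, r, rms = fit_circle(pts)
    np.testing.assert_allclose(center, [0, 0], atol=1e-12 * radius)
    assert r == pytest.approx(radius, rel=1e-12)
    assert rms < 1e-12 * radius


def test_noisy_circle_matches_grid_search_oracle():
    """Geometric fit cost is within 1e-6 of a brute-force grid minimum."""
    rng = np.random.default_rng(7)
    pts = regular_hexagon(radius=1.0)[:, :2] + rng.normal(0, 0.1, (6, 2))

    def cost(cx, cy, r):
        return np.sum((np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r) ** 2)

    center, r, _ = fit_circle(pts)
    fitted = cost(center[0], center[1], r)
    grid = np.linspace(-0.3, 0.3, 61)
    rgrid = np.linspace(0.7, 1.3, 61)
    best = min(
        cost(cx, cy, rr) for cx in grid for cy in grid for rr in rgrid
    )
    assert fitted <= best + 1e-6


def test_collinear_points_circle_error():
    pts = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
    with pytest.raises(DegenerateGeometryError):
        fit_circle(pts)


# --- axis and curvature -----------------------------------------------------


def test_visual_axis_direction_and_error():
    np.testing.assert_allclose(
        visual_axis(np.array([0.0, 0.0, 1.0]), np.zeros(3)), [0, 0, 1]
    )
    with pytest.raises(DegenerateGeometryError):
        visual_axis(np.ones(3), np.ones(3))


@pytest.mark.parametrize(
    "a,h,expected", [(1.0, 1.0, 1.0), (3.0, 1.0, 5.0), (0.5, 0.1, 1.3)]
)
def test_curvature_radius_closed_form(a, h, expected):
    assert curvature_radius(a, h) == pytest.approx(expected, rel=1e-12)


def test_curvature_radius_requires_positive_height():
    with pytest.raises(DegenerateGeometryError):
        curvature_radius(1.0, 0.0)


def test_sphere_sampled_cap_recovers_sphere_radius():
    """Base circle + apex sampled exactly from a sphere of radius 3.98 um
    recover R = 3.98 through the full reconstruction."""
    R, a = 3.98, 2.8
    h = R - np.sqrt(R**2 - a**2)
    base = regular_hexagon(radius=a)
    apex = np.array([0.0, 0.0, h])
    geom = reconstruct_lens(_lens(base, apex))
    assert geom.curvature_radius == pytest.approx(R, rel=1e-12)
    assert geom.cap_height == pytest.approx(h, rel=1e-12)
    assert geom.diameter == pytest.approx(2 * a, rel=1e-12)


# --- invariances ------------------------------------------------------------


def test_rigid_motion_equivariance():
    """Rotation+translation rotates the axis and leaves scalars unchanged."""
    rng = np.random.default_rng(5)
    R0, a = 4.0, 2.5
    h = R0 - np.sqrt(R0**2 - a**2)
    base = regular_hexagon(radius=a)
    apex = np.array([0.0, 0.0, h])
    g0 = reconstruct_lens(_lens(base, apex))
    for _ in range(10):
        R = random_rotation(rng)
        t = rng.normal(0, 50, 3)
        g1 = reconstruct_lens(_lens(base @ R.T + t, R @ apex + t))
        assert stable_angle_deg(g1.visual_axis, R @ g0.visual_axis) < 1e-7
        for attr in ("diameter", "aperture_area", "cap_height", "curvature_radius"):
            assert getattr(g1, attr) == pytest.approx(getattr(g0, attr), rel=1e-9)


def test_scale_covariance():
    R0, a, s = 4.0, 2.5, 3.7
    h = R0 - np.sqrt(R0**2 - a**2)
    base = regular_hexagon(radius=a)
    apex = np.array([0.0, 0.0, h])
    g0 = reconstruct_lens(_lens(base, apex))
    g1 = reconstruct_lens(_lens(base * s, apex * s))
    assert g1.diameter == pytest.approx(s * g0.diameter, rel=1e-12)
    assert g1.cap_height == pytest.approx(s * g0.cap_height, rel=1e-12)
    assert g1.curvature_radius == pytest.approx(s * g0.curvature_radius, rel=1e-12)
    assert g1.aperture_area == pytest.approx(s**2 * g0.aperture_area, rel=1e-12)
    assert stable_angle_deg(g1.visual_axis, g0.visual_axis) < 1e-9


def test_zero_noise_synthetic_eye_recovered_exactly(clean_geoms):
    geoms, gt = clean_geoms
    axes = np.array([g.visual_axis for g in geoms])
    assert np.max(stable_angle_deg(axes, gt.axes)) < 1e-6
    np.testing.assert_allclose(
        [g.diameter for g in geoms], gt.diameters, rtol=1e-6
    )
    np.testing.assert_allclose(
        [g.curvature_radius for g in geoms], gt.curvature_radii, rtol=1e-6
    )
    np.testing.assert_allclose(
        [g.cap_height for g in geoms], gt.cap_heights, rtol=1e-6
    )


def test_axis_error_grows_monotonically_with_noise():
    """Median axis error increases with landmark noise sigma in {0, .1, .3} um."""
    medians = []
    for sigma in (0.0, 0.1, 0.3):
        errs = []
        for seed in range(3):
            lenses, _, gt = generate_eye(
                SyntheticEyeSpec(seed=100 + seed, landmark_noise_sd=sigma)
            )
            axes = np.array([g.visual_axis for g in reconstruct_eye(lenses)])
            errs.extend(np.atleast_1d(stable_angle_deg(axes, gt.axes)))
        medians.append(np.median(errs))
    assert medians[0] < medians[1] < medians[2]
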