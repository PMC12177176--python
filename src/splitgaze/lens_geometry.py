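"""Per-lens optical geometry from digitized landmarks.

Each corneal lens is reconstructed from its six base points and apex point:

1. (optionally) normalize coordinates to head width;
2. find the plane onto which the projected area of the lens base polygon is
   maximal, and express the base points in an in-plane orthonormal basis;
3. fit a circle to the projected base points (lens diameter and aperture);
4. take the visual axis as the unit vector from the 3D circle center through
   the apex;
5. model the outer lens surface as a spherical cap through the base circle
   and apex, giving the outer curvature radius R = (a^2 + h^2) / (2 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .landmarks_io import HeadFrame, LensLandmarks

__all__ = [
    "LensGeometry",
    "DegenerateGeometryError",
    "normalize_to_head_width",
    "fit_basis_plane",
    "fit_circle",
    "visual_axis",
    "curvature_radius",
    "reconstruct_lens",
    "reconstruct_eye",
]


class DegenerateGeometryError(ValueError):
    """Raised for degenerate landmark configurations (collinear/coincident)."""


@dataclass
class LensGeometry:
    """Fitted geometry of one corneal lens (lengths in the input units)."""

    ommatidium_id: int
    circle_center: np.ndarray  # 3D midpoint of the fitted base circle
    diameter: float
    aperture_area: float
    cap_height: float
    curvature_radius: float
    visual_axis: np.ndarray  # unit vector, points out of the eye
    residual_rms: float  # circle-fit residual (same units as input)
    section: str = "dorsal"


def normalize_to_head_width(
    lenses: list[LensLandmarks], head: HeadFrame
) -> list[LensLandmarks]:
    """Divide all landmark coordinates by head width (ocellus distance).

    Scaling is a similarity transform, so all angular quantities computed
    downstream are unchanged; lengths become dimensionless fractions of head
    width.
    """
    w = head.head_width
    if w <= 0:
        raise ValueError("head width must be positive")
    out = []
    for lm in lenses:
        out.append(
            LensLandmarks(
                ommatidium_id=lm.ommatidium_id,
                animal_id=lm.animal_id,
                sex=lm.sex,
                side=lm.side,
                section=lm.section,
                base_points=lm.base_points / w,
                apex_point=lm.apex_point / w,
            )
        )
    return out


def _order_by_angle(points3d: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Indices ordering points by angle about their centroid in the plane
    orthogonal to ``normal``."""
    c = points3d.mean(axis=0)
    e1, e2 = _plane_basis(normal)
    rel = points3d - c
    ang = np.arctan2(rel @ e2, rel @ e1)
    return np.argsort(ang, kind="stable")


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal basis (e1, e2) of the plane with ``normal``."""
    n = normal / np.linalg.norm(normal)
    # pick the coordinate axis least aligned with n for a stable cross product
    a = np.zeros(3)
    a[np.argmin(np.abs(n))] = 1.0
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def projected_polygon_area(points3d: np.ndarray, normal: np.ndarray) -> float:
    """Area of the polygon projected onto the plane orthogonal to ``normal``,
    with vertices ordered by angle about their centroid in that plane."""
    order = _order_by_angle(points3d, normal)
    p = points3d[order] - points3d.mean(axis=0)
    s = 0.5 * np.cross(p, np.roll(p, -1, axis=0)).sum(axis=0)
    n = normal / np.linalg.norm(normal)
    return float(abs(s @ n))


def fit_basis_plane(
    base_points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Plane maximizing the projected area of the lens base polygon.

    For a fixed vertex ordering the projected area onto a plane with unit
    normal n is abs(S . n) where S is the polygon vector area
    0.5 * sum(p_i x p_{i+1}); the maximizer is n = S/norm(S). The vertex
    ordering itself depends on the plane, so the solve alternates angular
    re-ordering (initialized at the total-least-squares plane) with the
    closed-form normal until the ordering is stable.

    Returns ``(normal, points2d, area)`` with ``points2d`` the base points
    expressed in a deterministic orthonormal in-plane basis centered on the
    centroid, in the stabilized angular order.
    """
    p = np.asarray(base_points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("base_points must be (n, 3)")
    c = p.mean(axis=0)
    rel = p - c
    # total-least-squares plane: normal = smallest right singular vector
    _, sv, vt = np.linalg.svd(rel)
    if sv[1] < 1e-12 * max(sv[0], 1e-300) or sv[0] == 0:
        raise DegenerateGeometryError("base points are collinear or coincident")
    normal = vt[2]
    order = _order_by_angle(p, normal)
    for _ in range(20):
        q = rel[order]
        s = 0.5 * np.cross(q, np.roll(q, -1, axis=0)).sum(axis=0)
        ns = np.linalg.norm(s)
        if ns < 1e-14 * np.max(np.abs(sv)) ** 2:
            raise DegenerateGeometryError("degenerate polygon (zero vector area)")
        normal = s / ns
        new_order = _order_by_angle(p, normal)
        if np.array_equal(new_order, order):
            break
        order = new_order
    e1, e2 = _plane_basis(normal)
    pts2d = np.column_stack([rel[order] @ e1, rel[order] @ e2])
    area = projected_polygon_area(p, normal)
    return normal, pts2d, area


def fit_circle(points2d: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through 2D points.

    Algebraic (Kasa) fit solved as a linear system, followed by a geometric
    refinement of sum((dist_i - r)^2) with ``scipy.optimize.least_squares``
    (tolerance 1e-10). Returns ``(center, radius, residual_rms)``.
    """
    p = np.asarray(points2d, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
        raise ValueError("need >=3 2D points")
    x, y = p[:, 0], p[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(p))])
    b = x**2 + y**2
    try:
        sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateGeometryError(str(exc)) from exc
    if rank < 3:
        raise DegenerateGeometryError("points are collinear; circle fit undefined")
    cx, cy, k = sol
    r0 = float(np.sqrt(max(k + cx**2 + cy**2, 0.0)))
    if r0 <= 0:
        raise DegenerateGeometryError("degenerate circle (zero radius)")

    def resid(params):
        px, py, r = params
        return np.hypot(x - px, y - py) - r

    fit = least_squares(resid, x0=[cx, cy, r0], xtol=1e-10, ftol=1e-10, gtol=1e-10)
    center = fit.x[:2]
    radius = float(fit.x[2])
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return center, radius, rms


def visual_axis(apex_point: np.ndarray, circle_center_3d: np.ndarray) -> np.ndarray:
    """Unit vector from the fitted base-circle center toward the lens apex
    (pointing out of the eye)."""
    d = np.asarray(apex_point, dtype=float) - np.asarray(circle_center_3d, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateGeometryError("apex coincides with circle center")
    return d / n


def curvature_radius(circle_radius: float, cap_height: float) -> float:
    """Outer curvature radius of a spherical cap with base radius ``a`` and
    height ``h``: R = (a^2 + h^2) / (2 h) — the radius of the unique sphere
    through the base circle and the apex."""
    a, h = float(circle_radius), float(cap_height)
    if h <= 0:
        raise DegenerateGeometryError("cap height must be > 0 (apex on/below plane)")
    return (a * a + h * h) / (2.0 * h)


def reconstruct_lens(lm: LensLandmarks) -> LensGeometry:
    """Full per-lens reconstruction: plane, circle, axis, cap, curvature."""
    normal, pts2d, _ = fit_basis_plane(lm.base_points)
    center2d, radius, rms = fit_circle(pts2d)
    centroid = lm.base_points.mean(axis=0)
    e1, e2 = _plane_basis(normal)
    center3d = centroid + center2d[0] * e1 + center2d[1] * e2
    # cap height: orthogonal distance of the apex from the basis plane
    h = float(abs((lm.apex_point - centroid) @ normal))
    axis = visual_axis(lm.apex_point, center3d)
    R = curvature_radius(radius, h) if h > 0 else float("nan")
    return LensGeometry(
        ommatidium_id=lm.ommatidium_id,
        circle_center=center3d,
        diameter=2.0 * radius,
        aperture_area=float(np.pi * radius**2),
        cap_height=h,
        curvature_radius=R,
        visual_axis=axis,
        residual_rms=rms,
        section=lm.section,
    )


def reconstruct_eye(lenses: list[LensLandmarks]) -> list[LensGeometry]:
    """Reconstruct every lens of an eye; errors name the offending record."""
    out = []
    for lm in lenses:
        try:
            out.append(reconstruct_lens(lm))
        except (DegenerateGeometryError, ValueError) as exc:
            raise DegenerateGeometryError(
                f"ommatidium {lm.ommatidium_id}: {exc}"
            ) from exc
    return out


def geometry_table(geoms: list[LensGeometry]):
    """Per-lens geometry as a pandas DataFrame (one row per ommatidium)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "ommatidium_id": [g.ommatidium_id for g in geoms],
            "section": [g.section for g in geoms],
            "diameter": [g.diameter for g in geoms],
            "aperture_area": [g.aperture_area for g in geoms],
            "cap_height": [g.cap_height for g in geoms],
            "curvature_radius": [g.curvature_radius for g in geoms],
            "axis_x": [g.visual_axis[0] for g in geoms],
            "axis_y": [g.visual_axis[1] for g in geoms],
            "axis_z": [g.visual_axis[2] for g in geoms],
            "center_x": [g.circle_center[0] for g in geoms],
            "center_y": [g.circle_center[1] for g in geoms],
            "center_z": [g.circle_center[2] for g in geoms],
            "residual_rms": [g.residual_rms for g in geoms],
        }
    )
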