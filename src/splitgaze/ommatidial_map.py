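"""Per-eye map of visual axes and interommatidial angles.

Each ommatidium's local optical resolution is summarized by its mean
interommatidial angle: the average angular difference between its own visual
axis and those of the six angularly nearest facets of the same eye (both
dorsal and ventral sections pooled, since facets at the section border may
have neighbors across the divide). Visual axes are also expressed in
spherical body coordinates as azimuth (from anterior, positive toward the
animal's left) and elevation (positive dorsal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lens_geometry import LensGeometry

__all__ = [
    "OmmatidiumRecord",
    "EyeMap",
    "angular_difference",
    "find_neighbors",
    "mean_interommatidial_angle",
    "average_eyes",
    "axis_to_azel",
    "build_eye_map",
]


def angular_difference(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two direction vectors, in [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _pairwise_angles(axes: np.ndarray) -> np.ndarray:
    """(n, n) matrix of angular differences in degrees between unit axes."""
    u = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    c = np.clip(u @ u.T, -1.0, 1.0)
    return np.degrees(np.arccos(c))


def find_neighbors(axes: np.ndarray, index: int, k: int = 6) -> np.ndarray:
    """Indices of the ``min(k, n-1)`` axes angularly nearest to ``axes[index]``.

    Ties are broken toward the lower index. The relation is not symmetric in
    general (i nearest to j does not imply j nearest to i) and callers must
    not assume it is.
    """
    axes = np.asarray(axes, dtype=float)
    n = len(axes)
    if n < 2:
        raise ValueError("need at least 2 axes")
    if not (0 <= index < n):
        raise IndexError(f"index {index} out of range for {n} axes")
    u = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    c = np.clip(u @ u[index], -1.0, 1.0)
    ang = np.degrees(np.arccos(c))
    ang[index] = np.inf
    # stable sort on (angle, id) -> ties broken by lower id
    order = np.lexsort((np.arange(n), ang))
    return order[: min(k, n - 1)]


def mean_interommatidial_angle(
    center_axis: np.ndarray, neighbor_axes: np.ndarray
) -> float:
    """Arithmetic mean of the angles between a facet's axis and each
    neighbor's axis, in degrees."""
    neighbor_axes = np.atleast_2d(np.asarray(neighbor_axes, dtype=float))
    if len(neighbor_axes) == 0:
        raise ValueError("empty neighbor set")
    return float(
        np.mean([angular_difference(center_axis, v) for v in neighbor_axes])
    )


def average_eyes(
    landmark_sets: list[np.ndarray], ids: list[np.ndarray] | None = None
) -> np.ndarray:
    """Per-landmark arithmetic mean of normalized coordinates across
    individuals.

    ``landmark_sets`` — one (n_points, 3) array per individual, already
    normalized to head width. Correspondence is by position (digitization
    order) unless per-individual ``ids`` are given, in which case the
    intersection must be complete: a landmark id missing from any individual
    raises, listing the absent ids.
    """
    if not landmark_sets:
        raise ValueError("no landmark sets given")
    if ids is None:
        shapes = {a.shape for a in map(np.asarray, landmark_sets)}
        if len(shapes) != 1:
            raise ValueError(
                f"landmark sets have mismatched shapes {sorted(shapes)}; "
                "supply explicit correspondence ids"
            )
        return np.mean([np.asarray(a, dtype=float) for a in landmark_sets], axis=0)
    def _as_py(seq):
        return {x.item() if hasattr(x, "item") else x for x in seq}

    common = _as_py(ids[0])
    union: set = set()
    for idv in ids:
        common &= _as_py(idv)
        union |= _as_py(idv)
    missing = sorted(union - common)
    if missing:
        raise ValueError(f"landmarks missing from some individuals: {missing}")
    key = sorted(common)
    stacked = []
    for a, idv in zip(landmark_sets, ids):
        lookup = {i: row for i, row in zip(idv, np.asarray(a, dtype=float))}
        stacked.append(np.array([lookup[i] for i in key]))
    return np.mean(stacked, axis=0)


def axis_to_azel(visual_axis: np.ndarray, body_pitch: float = 0.0) -> tuple[float, float]:
    """Azimuth/elevation (degrees) of a gaze direction in the body frame
    pitched by ``body_pitch``.

    Azimuth is measured from anterior (+x), positive toward +y (the animal's
    left); elevation is positive dorsal. A positive body pitch lifts the
    anterior body axis, so the same head-frame axis appears at lower
    elevation in the pitched frame.
    """
    v = np.asarray(visual_axis, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    v = v / n
    if body_pitch != 0.0:
        b = np.radians(body_pitch)
        # pitch rotation mapping body x to (cos b, 0, sin b); expressing a
        # fixed axis in the pitched frame applies the transpose
        rot = np.array(
            [
                [np.cos(b), 0.0, -np.sin(b)],
                [0.0, 1.0, 0.0],
                [np.sin(b), 0.0, np.cos(b)],
            ]
        )
        v = rot.T @ v
    az = np.degrees(np.arctan2(v[1], v[0]))
    el = np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    if az <= -180.0:
        az += 360.0
    return float(az), float(el)


@dataclass
class OmmatidiumRecord:
    ommatidium_id: int
    section: str
    visual_axis: np.ndarray
    azimuth: float
    elevation: float
    neighbor_ids: list[int]
    interommatidial_angle: float
    far_neighbor: bool = False  # 6th neighbor beyond the angular cutoff


@dataclass
class EyeMap:
    """Per-ommatidium records plus recomputable per-section summaries."""

    records: list[OmmatidiumRecord]
    section_summary: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ommatidium_id": [r.ommatidium_id for r in self.records],
                "section": [r.section for r in self.records],
                "azimuth": [r.azimuth for r in self.records],
                "elevation": [r.elevation for r in self.records],
                "interommatidial_angle": [r.interommatidial_angle for r in self.records],
                "neighbor_ids": [";".join(map(str, r.neighbor_ids)) for r in self.records],
                "far_neighbor": [r.far_neighbor for r in self.records],
            }
        )


def build_eye_map(
    geoms: list[LensGeometry],
    k: int = 6,
    far_cutoff: float = 45.0,
    pool_sections: bool = True,
) -> EyeMap:
    """Assemble the per-eye map: azimuth/elevation, neighbor graph and mean
    interommatidial angle per ommatidium, with per-section summaries.

    Neighbors are the ``k`` angularly nearest facets, pooled across both
    sections by default (``pool_sections=False`` restricts the search to the
    facet's own section). Records whose k-th neighbor lies beyond
    ``far_cutoff`` degrees are flagged rather than dropped.
    """
    axes = np.array([g.visual_axis for g in geoms])
    sections = np.array([g.section for g in geoms])
    ids = np.array([g.ommatidium_id for g in geoms])
    records = []
    for i, g in enumerate(geoms):
        if pool_sections:
            pool = np.arange(len(geoms))
        else:
            pool = np.flatnonzero(sections == g.section)
        local = int(np.flatnonzero(pool == i)[0])
        nb_local = find_neighbors(axes[pool], local, k=k)
        nb = pool[nb_local]
        angles = [angular_difference(axes[i], axes[j]) for j in nb]
        az, el = axis_to_azel(g.visual_axis)
        records.append(
            OmmatidiumRecord(
                ommatidium_id=int(ids[i]),
                section=g.section,
                visual_axis=axes[i],
                azimuth=az,
                elevation=el,
                neighbor_ids=[int(ids[j]) for j in nb],
                interommatidial_angle=float(np.mean(angles)),
                far_neighbor=bool(max(angles) > far_cutoff),
            )
        )
    summary = {}
    for sec in ("dorsal", "ventral"):
        sel = [r for r in records if r.section == sec]
        gsel = [g for g in geoms if g.section == sec]
        if not sel:
            continue
        io = np.array([r.interommatidial_angle for r in sel])
        dia = np.array([g.diameter for g in gsel])
        summary[sec] = {
            "count": len(sel),
            "diameter_mean": float(dia.mean()),
            "diameter_sd": float(dia.std(ddof=1)) if len(dia) > 1 else float("nan"),
            "interommatidial_mean": float(io.mean()),
            "interommatidial_sd": float(io.std(ddof=1)) if len(io) > 1 else float("nan"),
        }
    return EyeMap(records=records, section_summary=summary)
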