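"""Data model and I/O for digitized eye landmarks and tracked flight points.

Coordinate conventions
----------------------
Head frame (eye landmarks): right-handed, x anterior, y toward the animal's
left, z dorsal; units are micrometres (um). Lab frame (flight tracks):
z vertical-up; units are millimetres (mm). All angles in the package are
degrees.

Landmark CSV schema (one row per corneal lens)::

    ommatidium_id, animal_id, sex, side, section,
    p1x, p1y, p1z, ..., p6x, p6y, p6z, apex_x, apex_y, apex_z

Head landmarks travel in a companion header block (JSON) or a separate CSV
with columns ``ocellus_left_x..z, ocellus_right_x..z``. Flight-track CSV
columns: ``frame, head_x, head_y, head_z, thorax_x, thorax_y, thorax_z``
with optional ``abd_x, abd_y, abd_z``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LensLandmarks",
    "HeadFrame",
    "FlightTrack",
    "HeadMarkerTrack",
    "SchemaError",
    "read_landmarks",
    "write_landmarks",
    "read_head_frame",
    "write_head_frame",
    "read_flight_track",
    "write_flight_track",
]

SEXES = ("male", "female", "unknown")
SIDES = ("left", "right")
SECTIONS = ("dorsal", "ventral")

_LANDMARK_COORD_COLS = [f"p{i}{ax}" for i in range(1, 7) for ax in "xyz"] + [
    "apex_x",
    "apex_y",
    "apex_z",
]
_LANDMARK_META_COLS = ["ommatidium_id", "animal_id", "sex", "side", "section"]
LANDMARK_COLUMNS = _LANDMARK_META_COLS + _LANDMARK_COORD_COLS


class SchemaError(ValueError):
    """Raised when an input file violates the documented schema."""


@dataclass
class LensLandmarks:
    """Digitized landmarks of one ommatidium: six base points plus apex.

    Coordinates are head-frame micrometres. ``base_points`` has shape (6, 3);
    ``apex_point`` shape (3,).
    """

    ommatidium_id: int
    animal_id: str
    sex: str
    side: str
    section: str
    base_points: np.ndarray
    apex_point: np.ndarray

    def __post_init__(self) -> None:
        self.base_points = np.asarray(self.base_points, dtype=float)
        self.apex_point = np.asarray(self.apex_point, dtype=float)
        if self.base_points.shape != (6, 3):
            raise SchemaError(
                f"ommatidium {self.ommatidium_id}: expected 6 base points, "
                f"got array of shape {self.base_points.shape}"
            )
        if self.apex_point.shape != (3,):
            raise SchemaError(
                f"ommatidium {self.ommatidium_id}: apex must be a 3D point"
            )
        if not (np.all(np.isfinite(self.base_points)) and np.all(np.isfinite(self.apex_point))):
            raise SchemaError(
                f"ommatidium {self.ommatidium_id}: non-finite coordinate"
            )
        if self.sex not in SEXES:
            raise SchemaError(f"ommatidium {self.ommatidium_id}: bad sex {self.sex!r}")
        if self.side not in SIDES:
            raise SchemaError(f"ommatidium {self.ommatidium_id}: bad side {self.side!r}")
        if self.section not in SECTIONS:
            raise SchemaError(
                f"ommatidium {self.ommatidium_id}: bad section {self.section!r}"
            )
        centroid = self.base_points.mean(axis=0)
        if np.allclose(self.apex_point, centroid):
            raise SchemaError(
                f"ommatidium {self.ommatidium_id}: apex coincides with base centroid"
            )

    def all_points(self) -> np.ndarray:
        """All seven landmarks as a (7, 3) array (base points first)."""
        return np.vstack([self.base_points, self.apex_point])


@dataclass
class HeadFrame:
    """Head reference landmarks: the two ocelli, in head-frame um.

    ``head_width`` — the distance between the ocelli — is the normalization
    length for eye coordinates.
    """

    ocellus_left: np.ndarray
    ocellus_right: np.ndarray

    def __post_init__(self) -> None:
        self.ocellus_left = np.asarray(self.ocellus_left, dtype=float)
        self.ocellus_right = np.asarray(self.ocellus_right, dtype=float)
        if self.head_width <= 0:
            raise SchemaError("head_width must be > 0 (coincident ocelli?)")

    @property
    def head_width(self) -> float:
        return float(np.linalg.norm(self.ocellus_left - self.ocellus_right))


@dataclass
class FlightTrack:
    """Frame-indexed 3D head/thorax points from free flight, lab-frame mm."""

    frame_rate: float
    head: np.ndarray
    thorax: np.ndarray
    abdomen_tip: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float)
        self.thorax = np.asarray(self.thorax, dtype=float)
        if self.abdomen_tip is not None:
            self.abdomen_tip = np.asarray(self.abdomen_tip, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.head.ndim != 2 or self.head.shape[1] != 3:
            raise ValueError("head must be (n_frames, 3)")
        if self.head.shape != self.thorax.shape:
            raise ValueError("head and thorax must have the same shape")
        if len(self.head) < 2:
            raise ValueError("a flight track requires at least 2 frames")

    @property
    def n_frames(self) -> int:
        return len(self.head)

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class HeadMarkerTrack:
    """Two tracked markers per frame from a tethered-flight video view."""

    view: str
    marker_a: np.ndarray
    marker_b: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        if self.view not in ("frontal", "side"):
            raise ValueError(f"bad view {self.view!r}")
        self.marker_a = np.asarray(self.marker_a, dtype=float)
        self.marker_b = np.asarray(self.marker_b, dtype=float)
        if self.marker_a.shape != self.marker_b.shape:
            raise ValueError("marker arrays must have the same shape")
        if self.marker_a.ndim != 2 or len(self.marker_a) < 2:
            raise ValueError("need >=2 frames of 2D/3D markers")
        if not (np.all(np.isfinite(self.marker_a)) and np.all(np.isfinite(self.marker_b))):
            raise ValueError("markers must be present (finite) in every frame")


# ---------------------------------------------------------------------------
# Landmark I/O


def _lens_from_row(row: pd.Series, row_no: int) -> LensLandmarks:
    try:
        base = np.array(
            [[row[f"p{i}{ax}"] for ax in "xyz"] for i in range(1, 7)], dtype=float
        )
        apex = np.array([row["apex_x"], row["apex_y"], row["apex_z"]], dtype=float)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"row {row_no}: non-numeric coordinate ({exc})") from exc
    try:
        return LensLandmarks(
            ommatidium_id=int(row["ommatidium_id"]),
            animal_id=str(row["animal_id"]),
            sex=str(row["sex"]),
            side=str(row["side"]),
            section=str(row["section"]),
            base_points=base,
            apex_point=apex,
        )
    except SchemaError as exc:
        raise SchemaError(f"row {row_no}: {exc}") from exc


def read_landmarks(
    path: str | Path, format: str | None = None
) -> tuple[list[LensLandmarks], HeadFrame | None]:
    """Read a landmark table (CSV or JSON) into LensLandmarks records.

    CSV carries only lens rows (head landmarks, if any, come from a separate
    file via :func:`read_head_frame`); the JSON representation bundles an
    optional ``head`` object with the ``lenses`` list.

    Returns ``(lenses, head_frame_or_None)``. Raises :class:`SchemaError`
    naming the offending row/record on any validation failure.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing columns {missing}")
        lenses = [_lens_from_row(row, i + 2) for i, (_, row) in enumerate(df.iterrows())]
        return lenses, None
    if format == "json":
        obj = json.loads(Path(path).read_text())
        lenses = []
        for i, rec in enumerate(obj.get("lenses", [])):
            base = np.asarray(rec.get("base_points", []), dtype=float)
            if base.shape != (6, 3):
                raise SchemaError(
                    f"record {i} (ommatidium_id {rec.get('ommatidium_id')}): "
                    f"expected 6 base points, got shape {base.shape}"
                )
            lenses.append(
                LensLandmarks(
                    ommatidium_id=int(rec["ommatidium_id"]),
                    animal_id=str(rec["animal_id"]),
                    sex=str(rec["sex"]),
                    side=str(rec["side"]),
                    section=str(rec["section"]),
                    base_points=base,
                    apex_point=np.asarray(rec["apex_point"], dtype=float),
                )
            )
        head = None
        if "head" in obj and obj["head"] is not None:
            head = HeadFrame(
                ocellus_left=np.asarray(obj["head"]["ocellus_left"], dtype=float),
                ocellus_right=np.asarray(obj["head"]["ocellus_right"], dtype=float),
            )
        return lenses, head
    raise ValueError(f"unknown format {format!r}")


def write_landmarks(
    path: str | Path,
    lenses: Iterable[LensLandmarks],
    head: HeadFrame | None = None,
    format: str | None = None,
) -> None:
    """Write lenses (and optionally head landmarks) to CSV or JSON.

    The CSV route uses a fixed float format (17 significant digits) so that a
    write/read round trip reproduces coordinates bit-identically.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    lenses = list(lenses)
    if format == "csv":
        rows = []
        for lm in lenses:
            row: dict = {
                "ommatidium_id": lm.ommatidium_id,
                "animal_id": lm.animal_id,
                "sex": lm.sex,
                "side": lm.side,
                "section": lm.section,
            }
            for i in range(6):
                for j, ax in enumerate("xyz"):
                    row[f"p{i + 1}{ax}"] = lm.base_points[i, j]
            for j, ax in enumerate("xyz"):
                row[f"apex_{ax}"] = lm.apex_point[j]
            rows.append(row)
        pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(
            path, index=False, float_format="%.17g"
        )
        return
    if format == "json":
        obj = {
            "lenses": [
                {
                    "ommatidium_id": lm.ommatidium_id,
                    "animal_id": lm.animal_id,
                    "sex": lm.sex,
                    "side": lm.side,
                    "section": lm.section,
                    "base_points": lm.base_points.tolist(),
                    "apex_point": lm.apex_point.tolist(),
                }
                for lm in lenses
            ]
        }
        if head is not None:
            obj["head"] = {
                "ocellus_left": head.ocellus_left.tolist(),
                "ocellus_right": head.ocellus_right.tolist(),
            }
        Path(path).write_text(json.dumps(obj, indent=1))
        return
    raise ValueError(f"unknown format {format!r}")


_HEAD_COLS = [f"ocellus_{side}_{ax}" for side in ("left", "right") for ax in "xyz"]


def read_head_frame(path: str | Path) -> HeadFrame:
    """Read head landmarks (the two ocelli) from a one-row CSV with columns
    ``ocellus_left_x..z, ocellus_right_x..z``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _HEAD_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"head-frame file missing columns {missing}")
    if len(df) != 1:
        raise SchemaError(f"head-frame file must have exactly 1 row, got {len(df)}")
    row = df.iloc[0]
    return HeadFrame(
        ocellus_left=row[_HEAD_COLS[:3]].to_numpy(dtype=float),
        ocellus_right=row[_HEAD_COLS[3:]].to_numpy(dtype=float),
    )


def write_head_frame(path: str | Path, head: HeadFrame) -> None:
    values = np.concatenate([head.ocellus_left, head.ocellus_right])
    pd.DataFrame([values], columns=_HEAD_COLS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Flight-track I/O

_TRACK_COLS = ["frame", "head_x", "head_y", "head_z", "thorax_x", "thorax_y", "thorax_z"]
_ABD_COLS = ["abd_x", "abd_y", "abd_z"]


def read_flight_track(path: str | Path, frame_rate: float) -> FlightTrack:
    """Read a flight-track CSV recorded at ``frame_rate`` frames per second.

    Frame indices must be strictly increasing; gaps are tolerated but
    reported via a ``UserWarning``-free return (missing frames are NOT
    interpolated — the index is compacted and the caller decides).
    """
    import warnings

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACK_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"flight track missing columns {missing}")
    frames = df["frame"].to_numpy()
    if len(frames) < 2:
        raise SchemaError("flight track requires at least 2 frames")
    d = np.diff(frames)
    if np.any(d <= 0):
        bad = frames[1:][d <= 0][0]
        raise SchemaError(f"non-monotonic frame index at frame {bad}")
    if np.any(d > 1):
        warnings.warn(
            f"flight track has {int(np.sum(d - 1))} missing frame(s)", stacklevel=2
        )
    head = df[["head_x", "head_y", "head_z"]].to_numpy(dtype=float)
    thorax = df[["thorax_x", "thorax_y", "thorax_z"]].to_numpy(dtype=float)
    abd = None
    if all(c in df.columns for c in _ABD_COLS):
        abd = df[_ABD_COLS].to_numpy(dtype=float)
    return FlightTrack(frame_rate=frame_rate, head=head, thorax=thorax, abdomen_tip=abd)


def write_flight_track(path: str | Path, track: FlightTrack) -> None:
    data = {
        "frame": np.arange(track.n_frames),
        "head_x": track.head[:, 0],
        "head_y": track.head[:, 1],
        "head_z": track.head[:, 2],
        "thorax_x": track.thorax[:, 0],
        "thorax_y": track.thorax[:, 1],
        "thorax_z": track.thorax[:, 2],
    }
    if track.abdomen_tip is not None:
        for j, c in enumerate(_ABD_COLS):
            data[c] = track.abdomen_tip[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
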