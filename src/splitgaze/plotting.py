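"""Basic plots: azimuth-elevation eye map and gaze-sweep traces."""

from __future__ import annotations

import numpy as np


def plot_eye_map(eye_map, ax=None):
    """Azimuth-elevation scatter of all ommatidia, colored by the local
    interommatidial angle (dorsal as triangles, ventral as circles)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = eye_map.to_frame()
    markers = {"dorsal": "^", "ventral": "o"}
    for sec, sub in df.groupby("section"):
        sc = ax.scatter(
            sub.azimuth, sub.elevation, c=sub.interommatidial_angle,
            marker=markers.get(sec, "s"), cmap="viridis", label=sec,
            vmin=0, vmax=max(df.interommatidial_angle.max(), 1e-9),
        )
    ax.figure.colorbar(sc, ax=ax, label="interommatidial angle (deg)")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("elevation (deg)")
    ax.legend()
    return ax


def plot_gaze_sweep(sweep_df, ax=None):
    """Mean-gaze traces on the sphere (Az vs EL), one line per section and
    rotation axis, rotation angle encoded as color."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (sec, axis), sub in sweep_df.groupby(["section", "axis"]):
        sub = sub[~sub.degenerate]
        sc = ax.scatter(
            sub.az_deg, sub.el_deg, c=sub.angle_deg, s=8, cmap="plasma",
            label=f"{sec} ({axis})",
        )
    ax.figure.colorbar(sc, ax=ax, label="rotation angle (deg)")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("elevation (deg)")
    ax.legend(fontsize=8)
    return ax
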