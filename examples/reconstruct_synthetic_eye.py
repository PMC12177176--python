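"""Reconstruct lens geometry and interommatidial angles from a synthetic eye.

Generates a 73-facet split eye (42 dorsal / 31 ventral) with known ground
truth, runs the landmark -> geometry -> eye-map pipeline, and compares the
recovered per-section statistics with the generator's truth.
"""

import numpy as np

from splitgaze import (
    SyntheticEyeSpec,
    build_eye_map,
    generate_eye,
    reconstruct_eye,
    section_gaze_separation,
)

lenses, head, gt = generate_eye(SyntheticEyeSpec(seed=0, landmark_noise_sd=0.1))
geoms = reconstruct_eye(lenses)
eye_map = build_eye_map(geoms)

print(f"lenses: {len(geoms)}   head width: {head.head_width:.0f} um")
for sec, s in eye_map.section_summary.items():
    print(
        f"{sec:>8}: n={s['count']:3d}  diameter {s['diameter_mean']:.2f}"
        f" +- {s['diameter_sd']:.2f} um  interommatidial angle"
        f" {s['interommatidial_mean']:.1f} +- {s['interommatidial_sd']:.1f} deg"
    )

axes = np.array([g.visual_axis for g in geoms])
sections = np.array([g.section for g in geoms])
sep = section_gaze_separation(axes[sections == "dorsal"], axes[sections == "ventral"])
print(f"section mean-gaze separation: {sep:.1f} deg (generated with {gt.section_separation:.0f})")
# The per-section counts, diameters and the ~53 deg separation mirror the
# split-eye morphology; with 0.1 um digitization noise the recovered values
# scatter narrowly around the generator's truth.
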