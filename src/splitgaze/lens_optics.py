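"""Single-surface lens optics: focal length, focal depth, and section ratios.

The corneal lens of a miniature compound eye is treated as a single
refracting spherical surface between air and the lens material (refractive
index n, default 1.4). For a surface of curvature radius R:

* front focal length  f = R / (n - 1)
* back focal length   f' = n R / (n - 1)

The depth of the focal point is expressed as the fraction f / L of the mean
ommatidium length L (default 34 um). Differences between dorsal and ventral
eye sections are reported as the relative difference
|a - b| / max(a, b) * 100 (percent of the larger value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticsConfig",
    "LensOptics",
    "focal_length",
    "focal_depth_fraction",
    "relative_difference",
    "mean_aperture_area",
]


@dataclass
class OpticsConfig:
    refractive_index: float = 1.4
    formula: str = "front_focal"  # or "back_focal"
    ommatidium_length: float = 34.0  # um

    def __post_init__(self) -> None:
        if self.refractive_index <= 1:
            raise ValueError("refractive index must be > 1")
        if self.formula not in ("front_focal", "back_focal"):
            raise ValueError(f"unknown formula {self.formula!r}")
        if self.ommatidium_length <= 0:
            raise ValueError("ommatidium length must be > 0")


@dataclass
class LensOptics:
    focal_length: float  # um
    focal_depth_fraction: float  # f / L, dimensionless
    formula: str


def focal_length(R, config: OpticsConfig = OpticsConfig()):
    """Focal length (um) of a single refracting surface of radius ``R`` (um).

    Accepts scalars or arrays. The formula used (front vs back focal
    distance) is recorded in ``config.formula``.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("curvature radius must be > 0")
    n = config.refractive_index
    f = R / (n - 1.0)
    if config.formula == "back_focal":
        f = n * f
    return float(f) if f.ndim == 0 else f


def focal_depth_fraction(f, L: float = 34.0):
    """Depth of the focal point as a fraction of ommatidium length L."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or L <= 0:
        raise ValueError("focal length and ommatidium length must be > 0")
    out = f / L
    return float(out) if out.ndim == 0 else out


def relative_difference(a: float, b: float) -> float:
    """Relative difference of two positive scalars, percent of the larger:
    |a - b| / max(a, b) * 100."""
    if a <= 0 or b <= 0:
        raise ValueError("inputs must be positive")
    return abs(a - b) / max(a, b) * 100.0


def mean_aperture_area(diameter_mean: float, diameter_sd: float) -> float:
    """Population mean lens base area (optical aperture) implied by a
    diameter distribution with mean ``mu`` and SD ``sigma``.

    E[pi d^2 / 4] = pi/4 * (mu^2 + sigma^2), regardless of the diameter
    distribution's shape.
    """
    mu, sd = float(diameter_mean), float(diameter_sd)
    if mu <= 0:
        raise ValueError("mean diameter must be > 0")
    if sd < 0:
        raise ValueError("diameter SD must be >= 0")
    return float(np.pi / 4.0 * (mu * mu + sd * sd))


def optics_from_geometry(curvature_radii, config: OpticsConfig = OpticsConfig()):
    """Per-lens focal lengths and focal-depth fractions from curvature radii."""
    f = focal_length(np.asarray(curvature_radii, dtype=float), config)
    return f, focal_depth_fraction(f, config.ommatidium_length)
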