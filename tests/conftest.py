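import numpy as np
import pytest

from splitgaze.synthetic import SyntheticEyeSpec, generate_eye


def stable_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle between unit vectors, accurate for tiny angles (chord formula)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    d = np.linalg.norm(a - b, axis=-1)
    return np.squeeze(2.0 * np.degrees(np.arcsin(np.clip(d / 2.0, 0.0, 1.0))))


def regular_hexagon(radius: float = 1.0, z: float = 0.0, phase: float = 0.0) -> np.ndarray:
    ang = phase + np.arange(6) * np.pi / 3
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture(scope="session")
def clean_eye():
    """Default synthetic eye with zero landmark noise, plus ground truth."""
    lenses, head, gt = generate_eye(SyntheticEyeSpec(seed=11, landmark_noise_sd=0.0))
    return lenses, head, gt


@pytest.fixture(scope="session")
def clean_geoms(clean_eye):
    from splitgaze.lens_geometry import reconstruct_eye

    lenses, head, gt = clean_eye
    return reconstruct_eye(lenses), gt
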