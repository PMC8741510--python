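import numpy as np
import pytest

from compeye.synthetic import EyeStackSpec, make_eye_stack


@pytest.fixture(scope="session")
def eye_stack_default():
    """Rendered spherical-cap stack (R=250 um, 30-degree cap) with truth."""
    return make_eye_stack(EyeStackSpec(seed=7))


@pytest.fixture(scope="session")
def eye_surface_default(eye_stack_default):
    from compeye.stack import reconstruct_surface

    return reconstruct_surface(eye_stack_default["stack"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sphere_points(n: int, radius: float = 1.0, center=(0.0, 0.0, 0.0),
                  hemisphere: bool = False, noise_sd: float = 0.0,
                  seed: int = 0) -> np.ndarray:
    """Uniform points on a sphere (optionally upper hemisphere + noise)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    if hemisphere:
        u[:, 2] = np.abs(u[:, 2])
    pts = radius * u + np.asarray(center, dtype=float)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return pts
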