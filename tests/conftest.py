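import numpy as np
import pytest

from sphereflock.geometry import SphereConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_sphere():
    return SphereConfig(r=1.0)


def random_state_on_sphere(n, cfg, rng):
    """Valid (positions, directions) pair: uniform points, random tangents."""
    from sphereflock.geometry import random_sphere_points, random_tangent_directions

    p = random_sphere_points(n, cfg, rng)
    d = random_tangent_directions(p, cfg, rng)
    return p, d


def random_rotation(rng):
    """Haar-random 3x3 rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
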