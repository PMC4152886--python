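import numpy as np
import pytest

from pennatefem.fixtures import SMALL_RESOLUTION
from pennatefem.geometry import GeometryParams, Resolution, generate_hex_mesh


@pytest.fixture(scope="session")
def default_params():
    return GeometryParams()


@pytest.fixture(scope="session")
def small_mesh(default_params):
    """Coarse belly mesh (2 x 1+3+1 x 6 cells) for fast solver tests."""
    return generate_hex_mesh(default_params, SMALL_RESOLUTION)


@pytest.fixture(scope="session")
def tiny_mesh(default_params):
    """Three-cell column (one cell per tissue layer)."""
    return generate_hex_mesh(default_params, Resolution(1, 1, 1, 1))


def random_admissible_F(rng, amplitude):
    """Deformation gradient near identity with det > 0.3."""
    while True:
        F = np.eye(3) + amplitude * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            return F
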