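import numpy as np
import pytest

from actinshape.forcefield import build_fiber_chain, build_monomer_chain
from actinshape.geometry import HelixGeometry, generate_parametric_shape


@pytest.fixture(scope="session")
def monomer_chain():
    """Default chiral chain (~100 nm) with its calibrated force field."""
    return build_monomer_chain(HelixGeometry.for_length(100.0))


@pytest.fixture(scope="session")
def fiber_chain():
    """Default achiral fiber chain (10 segments of 10 nm)."""
    return build_fiber_chain(n_segments=10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def right_coil():
    return generate_parametric_shape("helical_coil", length_nm=350.0,
                                     coil_radius_nm=40.0, winding_deg=60.0,
                                     n_points=50)


@pytest.fixture
def planar_arc():
    return generate_parametric_shape("planar_arc", end_to_end_nm=350.0,
                                     height_nm=80.0, n_points=50)


@pytest.fixture
def straight_rod():
    return generate_parametric_shape("straight", length_nm=500.0,
                                     n_points=50)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
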