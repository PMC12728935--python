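import numpy as np
import pytest

from halopi.geomgen import ComplexGeometry, GridSpec
from halopi.surrogate import SurrogateParams


def reference_pose(halogen="I", d=3.0, **overrides):
    """Sigma-hole-optimal grid pose straight above the ring centroid."""
    meta = {"x": 0.0, "z": 0.0, "d": d, "y_rot": 0.0, "tilt_axis": "x", "tilt_dev": 0.0}
    meta.update(overrides)
    return ComplexGeometry(halogen=halogen, meta=meta)


@pytest.fixture
def generic_pose():
    """An asymmetric pose with no distance ties in the halogen block."""
    return ComplexGeometry(
        halogen="Br",
        meta={"x": 1.1, "z": 0.7, "d": 3.25, "y_rot": 45.0, "tilt_axis": "c45", "tilt_dev": 20.0},
    )


@pytest.fixture(scope="session")
def reduced_grid_spec():
    vals = tuple(round(i * 1.25, 10) for i in range(5))
    return GridSpec(
        x_values=vals,
        z_values=vals,
        tilt_axes=("x", "z"),
        tilt_deviations=(-40.0, -20.0, 0.0, 20.0, 40.0),
    )


@pytest.fixture(scope="session")
def noiseless_params():
    return SurrogateParams(noise_sd=0.0)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
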