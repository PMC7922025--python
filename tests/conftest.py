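import numpy as np
import pytest

from chlorosim import CouplingModel, RunConfig, make_toy_monomer


@pytest.fixture
def planar_monomer():
    """Ideal planar chlorin skeleton, dipole 5.0 D along +y."""
    return make_toy_monomer(2.0, 2.0, 180.0)


@pytest.fixture
def vacuum_model():
    return CouplingModel(screening_mode="off")


@pytest.fixture
def solvent_model():
    return CouplingModel(screening_mode="additive")


@pytest.fixture(scope="session")
def default_config():
    return RunConfig.from_dict({})


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
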