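import numpy as np
import pytest

from gaitcal import GaitProfileConfig, generate_true_angles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_cycle_cfg():
    return GaitProfileConfig(n_cycles=2, seed=7)


@pytest.fixture(scope="session")
def two_cycle_angles(two_cycle_cfg):
    return generate_true_angles(two_cycle_cfg)


@pytest.fixture
def random_rotation(rng):
    """A uniformly random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(42)).as_matrix()
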