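import numpy as np
import pytest

from edgegan.physics import NoiseSpec, SamplingMask
from edgegan.synthetic import PhantomSpec, make_coilset, make_phantom
from edgegan.trajectories import TrajectorySpec, gaussian2d_mask


@pytest.fixture(scope="session")
def coils64():
    return make_coilset(64, 64, 4, seed=0)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomSpec(shape=(64, 64), seed=7))


@pytest.fixture(scope="session")
def mask30():
    return gaussian2d_mask(TrajectorySpec("gaussian2d", 0.3, (64, 64), seed=3))


@pytest.fixture(scope="session")
def full_mask():
    return SamplingMask(np.ones((64, 64), dtype=np.uint8), 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
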