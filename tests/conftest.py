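import numpy as np
import pytest

from pelvimetry import (
    LandmarkSet,
    PhantomConfig,
    RunConfig,
    VolumeGrid,
    sample_landmark_geometry,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def landmarks():
    """A fixed, plausible landmark arrangement (mm)."""
    return LandmarkSet.from_points(
        A=(40.0, 110.0, 32.0),
        B=(25.0, 75.0, 33.5),
        C=(18.0, 25.0, 32.5),
        D=(95.0, 30.0, 31.0),
        E=(120.0, 42.0, 32.0),
    )


@pytest.fixture
def random_landmark_sets(rng):
    """50 seeded random landmark sets spread over a 200 mm cube."""
    sets = []
    for _ in range(50):
        pts = rng.uniform(-100.0, 100.0, size=(5, 3))
        sets.append(LandmarkSet.from_points(*pts))
    return sets


@pytest.fixture
def phantom_config():
    return PhantomConfig()


@pytest.fixture
def tiny_run():
    return RunConfig.tiny(seed=7)


@pytest.fixture
def small_volume(rng):
    data = rng.normal(0.0, 1.0, size=(24, 24, 8)).astype(np.float32)
    return VolumeGrid(data=data, spacing=(1.5, 1.5, 4.3))
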