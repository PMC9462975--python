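import numpy as np
import pytest

from scseseg.phantom import PhantomConfig, generate_phantom
from scseseg.types import LabeledPair, LabelMap, Volume


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic default phantom (volume, labels)."""
    return generate_phantom(PhantomConfig(seed=7), id="fixture-phantom")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.random((8, 8, 8)), spacing=(1.0, 1.0, 1.0), id="rand8")


def random_mask(rng, shape=(12, 12, 12), p=0.3):
    """Non-empty random binary mask."""
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


@pytest.fixture
def labeled_pair(default_phantom):
    vol, lm = default_phantom
    return LabeledPair(vol, lm)
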