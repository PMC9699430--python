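import numpy as np
import pytest

from flossguard import detector, fluorospec, scenegen


@pytest.fixture(scope="session")
def criterion():
    return fluorospec.SpectralCriterion()


@pytest.fixture(scope="session")
def bandpass():
    return fluorospec.BandpassFilterModel()


@pytest.fixture(scope="session")
def materials():
    return fluorospec.load_fluorophores()


@pytest.fixture(scope="session")
def fixture_suite():
    """Canonical synthetic scenes, rendered once per session."""
    return scenegen.make_fixture_suite(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, shape=(32, 32), bit_depth=8):
    max_value = (1 << bit_depth) - 1
    px = rng.integers(0, max_value + 1, size=shape)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return detector.Frame(px.astype(dtype), bit_depth=bit_depth)
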