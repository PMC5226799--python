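import numpy as np
import pytest
from hypothesis import settings

import stainwave as sw

settings.register_profile("repeatable", deadline=None, derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def phantom0():
    """Default independent, noiseless 256x256 phantom (seed 0)."""
    return sw.render(sw.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom0_result(phantom0):
    """Full pipeline output for the default phantom."""
    return sw.deconvolve_tile(phantom0.image, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
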