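import numpy as np
import pytest

from phshock import simulate


@pytest.fixture
def truth():
    return simulate.SimTruth(seed=7)


@pytest.fixture
def small_config():
    return simulate.SimConfig(n_events=2000)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
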