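import numpy as np
import pytest

from resmini.architecture import ResMiniConfig
from resmini.synthetic import default_phantom_spec, phantom_arrays


@pytest.fixture(scope="session")
def small_config():
    """A narrow ResMini (f=2) for fast mechanical tests."""
    return ResMiniConfig(base_width=2)


@pytest.fixture(scope="session")
def tiny_phantom_set():
    """40 phantoms (rounded per-class), high separation, for smoke training."""
    spec = default_phantom_spec(samples_per_class=(14, 13, 13),
                                noise_sd=0.05, separation=1.5, seed=7)
    return phantom_arrays(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
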