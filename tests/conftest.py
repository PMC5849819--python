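import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sdrmon import AlgorithmParams, BackgroundModel, TransducerProfile

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_profile():
    """A toy linear array: 64 elements, short resize depth, fast to simulate."""
    return TransducerProfile("SIM-64", element_count=64, resized_height=60)


@pytest.fixture
def fast_params():
    """Reduced stack/repetition sizes for cheap end-to-end runs."""
    return AlgorithmParams(n_stack=20, n_select=8, n_rep=25, seed=3)


@pytest.fixture
def quiet_background():
    """Noise-free, structure-free background (constant gray level 100)."""
    return BackgroundModel(mean_level=100, blob_count=0, blob_amplitude=0,
                           speckle_sigma=0.0, seed=0)
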