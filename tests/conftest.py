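import numpy as np
import pytest

from lso_ssl import ExperimentConfig, NetworkSpec, build_network
from lso_ssl.neurons import RateNeuronParams, SpikingNeuronParams


@pytest.fixture
def rate_params():
    return RateNeuronParams()


@pytest.fixture
def spiking_params():
    return SpikingNeuronParams()


@pytest.fixture
def small_spec():
    """A 4-band, 3-tuning network — big enough for every structural motif."""
    return NetworkSpec(n_freq=4, n_tunings=3, mode="rate")


@pytest.fixture
def small_network(small_spec):
    return build_network(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
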