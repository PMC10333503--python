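import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from spikerls import NetworkConfig, TrainConfig, sinusoid_targets
from spikerls.model import SpikingRLSModel


@pytest.fixture
def tiny_model():
    """Small trainable model: quick enough for smoke tests."""
    cfg = NetworkConfig(n_neurons=64, n_plastic=8, k_static=0,
                        seed_graph=11, seed_stimulus=12, seed_noise=13, seed_rls=14)
    tgt = sinusoid_targets(64, period=500.0, amplitude=0.4, offset=0.0,
                           duration=500.0, bin_ms=10.0, seed=14)
    tc = TrainConfig(n_iterations=2, duration=500.0)
    return SpikingRLSModel(tgt, cfg, tc)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
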