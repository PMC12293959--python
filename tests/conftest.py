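import logging

import numpy as np
import pytest

from betadyn.embedding import average_mutual_information, delay_embed, select_delay
from betadyn.synthetic import SyntheticSpec, gen_lorenz, lorenz_states

logging.getLogger("betadyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def lorenz_signal():
    """Lorenz x-coordinate: 20 000 samples at dt=0.01 (fs=100 per model time)."""
    return gen_lorenz(SyntheticSpec("lorenz", fs=100.0, duration=200.0))


@pytest.fixture(scope="session")
def lorenz_full_states():
    return lorenz_states(20000)


@pytest.fixture(scope="session")
def lorenz_traj(lorenz_signal):
    """Delay embedding of the Lorenz x-coordinate (AMI delay, m=3)."""
    tau = select_delay(average_mutual_information(lorenz_signal.samples,
                                                  max_lag=100))
    return delay_embed(lorenz_signal.samples, tau, 3, fs=lorenz_signal.fs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
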