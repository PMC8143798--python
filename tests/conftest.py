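import numpy as np
import pytest

from sacspike.simulate import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A small but complete synthetic session (traces, spikes, movements)."""
    cfg = SimConfig(seed=7, n_trials=40, trial_length=900.0, stimulus_onset=500.0)
    return simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
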