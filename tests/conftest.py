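import numpy as np
import pytest

from ctmotor import synth


@pytest.fixture(scope="session")
def session_small():
    """120 s noiseless session with 30 embedded pulls."""
    cfg = synth.SessionConfig(duration=120, n_trials=30, seed=1, velocity_noise_sd=0.0)
    return synth.generate_session(cfg)


@pytest.fixture(scope="session")
def session_noisy():
    cfg = synth.SessionConfig(duration=300, n_trials=60, seed=2)
    return synth.generate_session(cfg)


@pytest.fixture(scope="session")
def population(session_noisy):
    """Mixed down/up/no-mod population with ground truth."""
    act, gt = synth.generate_activity(
        session_noisy, synth.PopulationConfig(n_units=200), seed=3
    )
    return act, gt


@pytest.fixture(scope="session")
def pull_peaks(session_noisy):
    cfg = session_noisy.config
    return session_noisy.pulls.onset_s.to_numpy() + cfg.pull_width / 2


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
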