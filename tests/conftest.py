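import numpy as np
import pytest

from tissuecorr import synthetic
from tissuecorr.profiles import StepProfile, SwitchProfileSet


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A light tissue/imaging configuration for fast end-to-end tests."""
    return synthetic.SynthConfig(
        seed=7, n_cells=30, field_side=50.0, duration_hours=12.0, dt_minutes=15.0
    )


@pytest.fixture(scope="session")
def small_tracks(small_config):
    """Two-channel tracks driven by bell-shaped signals of varying amplitude."""
    cfg = small_config
    rng = np.random.default_rng(cfg.seed)
    amps = rng.uniform(200.0, 1500.0, size=cfg.n_cells)
    signal = synthetic.bell_profile(cfg.times_h, 1.0)[:, None] * amps[None, :]
    return synthetic.generate_two_channel_tracks(signal, cfg, rng=rng)


def step(levels, times, weight=1.0):
    return StepProfile(np.asarray(times, float), np.asarray(levels, float), weight)


@pytest.fixture()
def single_switch_profiles():
    """Two one-candidate sets: an up-switch and a down-switch at t=10 h."""
    up = SwitchProfileSet([step([0.0, 1.0], [10.0])])
    down = SwitchProfileSet([step([1.0, 0.0], [10.0])])
    return up, down
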