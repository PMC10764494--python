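import numpy as np
import pytest

from myotrack.simulate import SimulationConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_session():
    """A 10-min simulated session with several injected jerks (shared)."""
    cfg = SimulationConfig(
        duration_s=600.0, seed=42, initial_explore_s=30.0,
        explore_bout_mean_s=20.0, sleep_bout_mean_s=300.0,
        groom_bout_mean_s=15.0, jerk_rate_per_h=40.0,
    )
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def quiet_session():
    """A 10-min mostly-sleeping session with zero injected jerks (shared)."""
    cfg = SimulationConfig(
        duration_s=600.0, seed=7, initial_explore_s=30.0,
        explore_bout_mean_s=15.0, sleep_bout_mean_s=400.0,
        groom_bout_mean_s=15.0, jerk_rate_per_h=0.0,
    )
    return simulate_session(cfg)
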