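import numpy as np
import pytest

from neuroglyc.io_timebase import align
from neuroglyc.synthetic import SyntheticConfig, simulate

STEP_H = 1.0 / 12.0  # 5-min glucose grid in hours


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated study, shared across read-only tests."""
    return simulate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def clean_sim():
    """Spectrally clean construction: shared sinusoids + noise, no meal events."""
    cfg = SyntheticConfig(seed=7, meal_response_mg_dl=0.0, hyperglycemia_episodes=0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def aligned_default(default_sim):
    env, glu, states, _ = default_sim
    return align(env, glu, states)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
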