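import numpy as np
import pytest

from chromdiv import synthetic_data as sd

SMALL_CONFIG = dict(
    n_autosomes=2,
    autosome_length=120_000,
    x_length=60_000,
    par_length=20_000,
    draft_n50=30_000,
    depth_noise="none",
)


@pytest.fixture
def small_config():
    """Tiny but complete simulation config (fast to generate)."""
    return sd.SimulationConfig(seed=11, **SMALL_CONFIG)


@pytest.fixture(scope="session")
def sim_genome():
    """One mid-size simulated genome shared across read-only tests."""
    cfg = sd.SimulationConfig(seed=7, sex="male")
    return cfg, sd.simulate_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
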