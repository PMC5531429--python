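import numpy as np
import pytest

from paleoweave import simdata
from helpers import two_source_config


@pytest.fixture(scope="session")
def two_source_panel():
    """Two moderately diverged source populations, shared across tests."""
    cfg = two_source_config(seed=11)
    return cfg, simdata.simulate_sources(cfg)


@pytest.fixture(scope="session")
def admixed_panel():
    """Panel with an admixed population X (30% A / 70% B)."""
    cfg = two_source_config(seed=7, n_sites=2000)
    panel = simdata.simulate_sources(cfg)
    event = simdata.AdmixtureEvent("X", "A", "B", alpha=0.3, generations_g=30, n_samples=12)
    simdata.simulate_admixed(panel, event, cfg.seed)
    return cfg, panel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
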