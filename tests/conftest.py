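import numpy as np
import pytest

from netrai.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 4×4-subject cohort shared by read-only tests."""
    cfg = SimulationConfig(n_per_group=4, seed=42)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth
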