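import numpy as np
import pytest

from econunpred.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-family cohort with ground truth, shared across tests."""
    cfg = SimConfig(n_families=60, n_outcome=40, seed=123)
    tables, truth = simulate_cohort(cfg)
    return cfg, tables, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
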