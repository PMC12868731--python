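import numpy as np
import pandas as pd
import pytest

from nbtsig import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort that still exercises every stage."""
    return SimulationConfig(
        n_patients=60, n_genes=400, n_signature=12, n_genera=40,
        seq_depth=5000, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def random_counts(rng):
    """20x4 NB-distributed count matrix (no zeros rows guaranteed)."""
    counts = rng.negative_binomial(5, 0.05, size=(20, 4)) + 1
    return pd.DataFrame(
        counts,
        index=[f"G{i:03d}" for i in range(20)],
        columns=[f"S{j}" for j in range(4)],
    )
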