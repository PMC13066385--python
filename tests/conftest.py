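import numpy as np
import pandas as pd
import pytest

from ccdeconv.synthetic import SimulationConfig, simulate_cohort


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort: 3 groups of 10/10/4 samples, 80 genes, no CNA region."""
    defaults = dict(n_in=10, n_mm=10, n_sm=4, n_genes=80, cna_region=None, seed=0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_survival():
    """Six patients, two groups, distinct event times (hand-checkable log-rank)."""
    return pd.DataFrame(
        {
            "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 0, 1],
            "group": ["A", "A", "A", "B", "B", "B"],
        },
        index=[f"P{i}" for i in range(6)],
    )
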