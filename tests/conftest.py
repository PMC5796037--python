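import numpy as np
import pytest

from mirmint.synthetic_cohort import (
    SimulationConfig,
    simulate_cohorts,
    simulate_utrs,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, fully planted study used by several integration tests."""
    return SimulationConfig(
        n_mirnas=60,
        n_mrnas=120,
        frac_de_mirna=0.4,
        frac_de_mrna=0.3,
        n_planted_pairs=8,
        targets_per_mirna=4,
        samples_per_group=12,
        utr_length=300,
        rng_seed=1234,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(mirna_datasets, mrna_datasets, matched pair, truth, utrs)."""
    mirna_ds, mrna_ds, matched, truth = simulate_cohorts(small_config)
    utrs = simulate_utrs(small_config, truth)
    return mirna_ds, mrna_ds, matched, truth, utrs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
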