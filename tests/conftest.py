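import numpy as np
import pytest

from longimci.syndata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: small grid, few regions, strong planted decline."""
    return CohortConfig(
        n_smci=10, n_pmci=8, n_hc=8,
        grid_dims=(8, 8, 6), n_regions=30,
        n_affected_regions=6, n_reference_regions=4,
        decline_per_tp_pmci=0.06, decline_per_tp_smci=0.01,
        noise_sd=2.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
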