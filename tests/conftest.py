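import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crosstalknet import CohortConfig, OmicsBlock, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort: fast to generate and preprocess, still tri-omics."""
    return CohortConfig(
        n_subjects=47,
        n_genera_raw=40,
        n_core_genera=30,
        n_fecal_raw=30,
        n_plasma_raw=30,
        n_factors=3,
        loading_sparsity=0.1,
        missing_profile={
            "fecal": {"Fec_001": 0.45, "Fec_002": 0.08},
            "plasma": {"Pla_003": 0.08},
        },
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Planted-factor cohort used for end-to-end recovery checks."""
    config = CohortConfig(n_subjects=200, noise_sd=0.3, missing_profile={}, seed=11)
    return config, simulate_cohort(config)


def make_block(values, label="fecal", features=None, samples=None) -> OmicsBlock:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{j}" for j in range(values.shape[1])]
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return OmicsBlock(pd.DataFrame(values, index=samples, columns=features), label)
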