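import numpy as np
import pandas as pd
import pytest

from bayesdm.bayes import McmcConfig
from bayesdm.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default-condition cohort (338 participants, seed 7)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def fast_mcmc() -> McmcConfig:
    """Reduced sampler settings for test-speed fits."""
    return McmcConfig(burn_in=500, draws=10_000, thinning=2, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
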