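import warnings

import numpy as np
import pandas as pd
import pytest

from ssbtax import anthro, synthetic


@pytest.fixture(scope="session")
def households_small() -> pd.DataFrame:
    """3,000 synthetic households with the default embedded elasticities."""
    cfg = synthetic.HouseholdConfig(n_households=3000, seed=7)
    return synthetic.generate_households(cfg)


@pytest.fixture(scope="session")
def cohort_small() -> pd.DataFrame:
    """4,000 synthetic adults (default Brazilian study conditions)."""
    cfg = synthetic.IndividualConfig(n_individuals=4000, seed=11)
    return synthetic.generate_individuals(cfg)


@pytest.fixture(scope="session")
def corrected_cohort(cohort_small) -> pd.DataFrame:
    """Cohort with bias-corrected anthropometry (independent measured survey)."""
    ref = synthetic.generate_individuals(
        synthetic.IndividualConfig(n_individuals=4000, seed=12)
    )
    corrected, _ = anthro.correct_cohort(cohort_small, ref)
    return corrected


@pytest.fixture(autouse=True)
def _quiet_cluster_warning():
    """The default demand spec warns about 3 SES clusters; keep test logs clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* clusters")
        yield


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
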