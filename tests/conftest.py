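import numpy as np
import pytest

from r2sn import pipeline as pl
from r2sn import synthetic as syn


@pytest.fixture(scope="session")
def small_volume():
    """8-region labeled volume on a 24^3 grid."""
    return syn.generate_labeled_volume(8, (24, 24, 24), seed=2)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Cohort at the default study conditions with a planted AD pattern."""
    spec = syn.CohortSpec(
        n_nc=50,
        n_mci=60,
        n_ad=50,
        n_regions=60,
        n_features=47,
        effect_size=2.0,
        frac_mci_adlike=0.6,
        noise_sd=0.5,
        seed=7,
    )
    return syn.generate_cohort(spec)


@pytest.fixture(scope="session")
def recovery_result(recovery_cohort):
    """Full pipeline run on the recovery cohort."""
    return pl.run_pipeline(
        recovery_cohort.feature_matrices, recovery_cohort.phenotypes, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
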