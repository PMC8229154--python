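import numpy as np
import pytest

from cognet.reduction import concat_group_pca, reduce_subject
from cognet.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free 6-source, 10-subject cohort: the ICA recovery workhorse."""
    cfg = CohortConfig(n_pd=6, n_ctr=4, noise_sd=0.0, group_effect={})
    return simulate_cohort(cfg, seed=2)


@pytest.fixture(scope="session")
def clean_whitened(clean_cohort):
    """Whitened K=6 group data from the noise-free cohort."""
    mats = [reduce_subject(b, 6)[0] for b in clean_cohort.bolds]
    return concat_group_pca(mats, 6)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small noisy cohort for pipeline-level tests (cheap but realistic)."""
    cfg = CohortConfig(n_pd=12, n_ctr=6, noise_sd=0.1, group_effect={})
    return simulate_cohort(cfg, seed=5)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
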