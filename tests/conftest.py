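import numpy as np
import pytest

from pbsikit.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject, 24-region, 3-site cohort shared by read-only tests."""
    spec = CohortSpec(n_per_group=30, n_regions=24, n_sites=3,
                      het_sd_asd=8.0, het_sd_nc=4.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
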