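import numpy as np
import pytest

from ordgene import simulate_ordinal_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40-gene, 70-sample severity-graded cohort with 8 associated genes."""
    return simulate_ordinal_cohort(
        40, n_samples=70, pag_fraction=0.2, beta_range=(2.0, 3.0), seed=42
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
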