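import numpy as np
import pytest

from scafkan import (CohortConfig, apply_preprocessor, fit_preprocessor,
                     generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """124-patient synthetic cohort at the development prevalence."""
    return generate_cohort(CohortConfig(n_patients=124, prevalence=39 / 124,
                                        seed=11))


@pytest.fixture(scope="session")
def preprocessed_small(small_cohort):
    state = fit_preprocessor(small_cohort)
    X = apply_preprocessor(state, small_cohort)
    return X, small_cohort.labels, state


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
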