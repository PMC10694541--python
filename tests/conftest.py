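import numpy as np
import pytest

import diffgrowth as dg


@pytest.fixture(scope="session")
def small_params():
    return dg.default_params(n_families=1500, seed=123)


@pytest.fixture(scope="session")
def cohort_bundle(small_params):
    """Default-parameter cohort with missingness and registry contacts."""
    cohort, truth, contacts = dg.simulate_cohort(small_params)
    return cohort, truth, contacts


@pytest.fixture(scope="session")
def scored_small(cohort_bundle):
    cohort, _, _ = cohort_bundle
    scored, constants = dg.score_cohort(cohort)
    return scored, constants


@pytest.fixture(scope="session")
def complete_bundle():
    """Mid-sized cohort without attrition, for estimator checks."""
    params = dg.default_params(n_families=5000, seed=321)
    cohort, truth, _ = dg.simulate_cohort(params, missingness=False,
                                          contacts=False)
    scored, _ = dg.score_cohort(cohort)
    return scored, truth, params


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
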