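import numpy as np
import pytest

import lookaway as lk


@pytest.fixture(scope="session")
def exp1_session():
    return lk.generate_exp1_session(seed=11)


@pytest.fixture(scope="session")
def exp2_session():
    return lk.generate_exp2_session(seed=11)


@pytest.fixture(scope="session")
def small_cohort(exp2_session):
    """A 20-infant three-box cohort under the default U-shaped hazard."""
    records, traces = lk.simulate_cohort(
        exp2_session, n_infants=20, params=lk.HazardParams(), seed=5, mode="marginal"
    )
    return records, traces


@pytest.fixture(scope="session")
def event_rows(small_cohort, exp2_session):
    records, traces = small_cohort
    retained, _ = lk.apply_exclusions(records)
    rows = lk.build_rows(retained, traces, exp2_session)
    return lk.standardize(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
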