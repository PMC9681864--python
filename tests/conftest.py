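import pytest

from veicans import default_cohort_spec, default_table, default_vocabulary
from veicans.simulate import sample_cohort


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def cohort():
    """One synthetic cohort under study-condition defaults, shared read-only."""
    return sample_cohort(default_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def records(cohort):
    return cohort.records
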