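import pytest

from idhres.simulate import CohortConfig, generate_cohort


SMALL_CONFIG = CohortConfig(
    n_patients=24, n_probes=600, n_genes=120, seed=7
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across test modules."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 60-patient cohort (seed 1)."""
    return generate_cohort(CohortConfig(seed=1))
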