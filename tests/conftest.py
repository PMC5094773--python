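import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from cltriage import (
    SyntheticCohortConfig,
    apply_eligibility,
    cohort_to_frame,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-size synthetic cohort (725 records), fixed seed."""
    return generate_cohort(SyntheticCohortConfig(seed=20240901))


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    eligible, _ = apply_eligibility(default_cohort)
    return cohort_to_frame(eligible)
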