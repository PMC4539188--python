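import pytest

from tardivo import fixture_study_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """The deterministic 62-record study cohort."""
    return fixture_study_cohort()
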