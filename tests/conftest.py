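import pytest

from ventbox import ach_real, case_study_fixtures, load_guidelines


@pytest.fixture(scope="session")
def guidelines():
    return load_guidelines()


@pytest.fixture(scope="session")
def cases():
    return case_study_fixtures()


@pytest.fixture(scope="session")
def measured_ach(cases):
    """Full-precision real ACH per case-study space."""
    return {
        name: ach_real(c.occupancy.generation, c.space.volume, c.css, c.co).ach_real
        for name, c in cases.items()
    }
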