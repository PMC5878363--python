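from datetime import date

import pytest

from registrylink.synth import SimConfig
from registrylink.pipeline import run_pipeline
from registrylink.types import PersonIdentity, Sex


@pytest.fixture(scope="session")
def small_pipeline():
    """One end-to-end run on a small synthetic population, shared by tests
    that only need a realistic linked dataset."""
    return run_pipeline(SimConfig(n_persons=400, seed=3))


@pytest.fixture()
def identity():
    return PersonIdentity(
        first_name="William",
        last_name="O'Brien-Smith",
        dob=date(1970, 3, 7),
        sex_at_birth=Sex.MALE,
        ssn="123-45-6789",
    )
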