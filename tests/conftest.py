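import numpy as np
import pytest

from hemoconcord import SyntheticConfig, generate_study
from hemoconcord.core import StudyArm


@pytest.fixture(scope="session")
def study2_records():
    """Default second-arm scenario: 7 animals with a flow-probe reference."""
    return generate_study(SyntheticConfig(seed=0, n_animals=7, arm=StudyArm.STUDY2))


@pytest.fixture(scope="session")
def one_record(study2_records):
    return study2_records[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
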