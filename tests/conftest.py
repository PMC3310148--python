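import numpy as np
import pytest

from petvoi.frames import default_schedule
from petvoi.phantom import generate_cohort, generate_label_phantom


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def labels32():
    return generate_label_phantom((32, 32, 32))


@pytest.fixture(scope="session")
def cohort23():
    return generate_cohort(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
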