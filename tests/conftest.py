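import numpy as np
import pytest

from gwmci import cohort_to_frame, default_battery, default_norms, generate_fixture


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def norms():
    return default_norms()


@pytest.fixture(scope="session")
def fixture_records():
    return generate_fixture()


@pytest.fixture(scope="session")
def fixture_frame(fixture_records):
    return cohort_to_frame(fixture_records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
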