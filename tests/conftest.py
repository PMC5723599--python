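import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import spacerprime as sp  # noqa: E402


@pytest.fixture(scope="session")
def primers():
    return sp.load_its_primers()


@pytest.fixture(scope="session")
def its2_pair():
    return sp.its2_pair()


@pytest.fixture(scope="session")
def its_pair():
    return sp.its_pair()


@pytest.fixture(scope="session")
def cassette():
    """One unmutated default cassette with truth."""
    return sp.make_cassette(sp.CassetteSpec(seed=7))


@pytest.fixture(scope="session")
def small_panel():
    """10 target + 10 off-target cassettes."""
    return sp.make_panel(10, 10, seed=3)
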