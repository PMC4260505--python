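import pytest

from hetnet import fixture_networks


@pytest.fixture(scope="session")
def fixtures():
    """Named small networks with documented closed-form statistics."""
    return fixture_networks()


@pytest.fixture
def star5(fixtures):
    return fixtures["star5"][0]


@pytest.fixture
def path3(fixtures):
    return fixtures["path3"]


@pytest.fixture
def k4_pendant(fixtures):
    return fixtures["K4_pendant"][0]


@pytest.fixture
def k5_k6_bridge(fixtures):
    return fixtures["K5_K6_bridge"][0]


@pytest.fixture
def bbs_like(fixtures):
    return fixtures["bbs_like"]
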