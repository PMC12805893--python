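import pytest

from asoscan.fixtures import fixture_catalogue


@pytest.fixture(scope="session")
def catalogue():
    return fixture_catalogue()


@pytest.fixture(scope="session")
def f18moe(catalogue):
    return catalogue["asos"]["F18MOE"]


@pytest.fixture(scope="session")
def f18ome(catalogue):
    return catalogue["asos"]["F18OMe"]
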