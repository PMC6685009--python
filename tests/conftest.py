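import pytest

from fispo.model_core import load_fixture


@pytest.fixture(scope="session")
def c2m():
    return load_fixture("c2m")


@pytest.fixture(scope="session")
def c2m_k1e_known():
    return load_fixture("c2m_k1e_known")


@pytest.fixture(scope="session")
def c2m_original():
    return load_fixture("c2m_original")


@pytest.fixture(scope="session")
def toggle_switch():
    return load_fixture("toggle_switch")


@pytest.fixture(scope="session")
def toggle_switch_reformulated():
    return load_fixture("toggle_switch_reformulated")


@pytest.fixture(scope="session")
def hiv():
    return load_fixture("hiv")
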