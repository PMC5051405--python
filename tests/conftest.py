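import pytest

from ecea import build_income_model, load_country


@pytest.fixture(scope="session")
def india():
    return load_country("india")


@pytest.fixture(scope="session")
def niger():
    return load_country("niger")


@pytest.fixture(scope="session")
def india_income(india):
    return build_income_model(india)


@pytest.fixture(scope="session")
def niger_income(niger):
    return build_income_model(niger)
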