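import pytest

from panelmut import GeneratorConfig, generate, load_table2_fixture


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic cohort shared across tests."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def table2_cohort():
    return load_table2_fixture()
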