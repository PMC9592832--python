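import pytest

from palytable import (
    ModelConfig,
    ProductivityParams,
    SynthSpec,
    gen_dataset,
    gen_worked_fixture,
)


@pytest.fixture(scope="session")
def synth_ds():
    """Small synthetic panel used across integration-style tests."""
    return gen_dataset(SynthSpec(n_countries=6, seed=11))


@pytest.fixture(scope="session")
def fixture_ds():
    """The tiny hand-computable 3-country, 2-band dataset."""
    return gen_worked_fixture()


@pytest.fixture
def default_params():
    return ProductivityParams()


@pytest.fixture
def default_config():
    return ModelConfig()
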