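import pytest

from dicescore import RubricConfig, canonical_fixtures


@pytest.fixture(scope="session")
def default_config():
    return RubricConfig()


@pytest.fixture(scope="session")
def canonical():
    return canonical_fixtures()
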