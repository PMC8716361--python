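import pytest
from hypothesis import settings

from dsilink.country_norm import default_groups, default_table
from dsilink.synth_corpus import SynthConfig, generate

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def country_table():
    return default_table()


@pytest.fixture(scope="session")
def groups():
    return default_groups()


@pytest.fixture(scope="session")
def small_corpus():
    """A modest synthetic corpus reused across module tests."""
    return generate(SynthConfig(seed=11, n_records=300, n_articles=60))


@pytest.fixture(scope="session")
def study_corpus():
    """The corpus at the study conditions: seed 42, 1000 records, 200
    articles, pattern mix 0.5/0.2/0.2/0.1."""
    return generate(SynthConfig(seed=42, n_records=1000, n_articles=200))
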