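import pytest
from hypothesis import HealthCheck, settings

from painstream import GeneratorConfig, generate_corpus, load_default_lexicon

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """200-tweet synthetic corpus with ground truth, shared across tests."""
    return generate_corpus(GeneratorConfig(n_tweets=200, seed=42))
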