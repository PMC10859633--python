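import pytest
from hypothesis import settings

from glycanvas.corpus import CorpusSpec, fixture_set, generate_corpus

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

#: Fixed seed for every randomized fixture in the suite.
TEST_SEED = 7

TABLE1 = "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"


@pytest.fixture(scope="session")
def corpus_1000():
    """The seeded default 1000-glycan synthetic corpus."""
    return generate_corpus(CorpusSpec(seed=TEST_SEED, n_structures=1000))


@pytest.fixture(scope="session")
def corpus_100(corpus_1000):
    return corpus_1000[:100]


@pytest.fixture(scope="session")
def fixtures():
    return fixture_set()
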