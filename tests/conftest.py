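import importlib.resources
import warnings

import pytest
from hypothesis import settings

from phonorank import SyntheticCorpusSpec, gen_corpus, load_lexicon

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# Boundary-clamp warnings from deliberately hard fits are part of the API.
warnings.filterwarnings("ignore", message="beta optimum at search-interval boundary")


@pytest.fixture(scope="session")
def example_lexicon():
    path = importlib.resources.files("phonorank") / "data" / "example_lexicon.tsv"
    return load_lexicon(path)


@pytest.fixture(scope="session")
def small_corpus():
    """Down-scaled synthetic corpus shared by pipeline tests."""
    spec = SyntheticCorpusSpec(tokens_per_text=20_000, vocab_size=2000, seed=0)
    return gen_corpus(spec)
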