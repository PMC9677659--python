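import numpy as np
import pytest

from convner import (YIDU_SCHEME, GeneratorConfig, TaggedSentence,
                     default_lexicon, generate_corpus)


@pytest.fixture(scope="session")
def scheme():
    return YIDU_SCHEME


@pytest.fixture(scope="session")
def lexicon(scheme):
    return default_lexicon(scheme, seed=42)


@pytest.fixture(scope="session")
def small_corpus(scheme, lexicon):
    """200 synthetic sentences under the standard generator settings."""
    cfg = GeneratorConfig(scheme=scheme, n_sentences=200, seed=42)
    return generate_corpus(lexicon, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_sentences(scheme):
    return [
        TaggedSentence(tuple("头痛。"), ("B-position", "I-position", "O")),
        TaggedSentence(tuple("直肠癌者"), ("B-disease", "I-disease", "I-disease", "O")),
        TaggedSentence(tuple("无"), ("O",)),
    ]
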