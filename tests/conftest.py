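import pytest

from weiboemo.core import EmotionClassifier
from weiboemo.lexicon import (
    data_path,
    default_lexicon,
    default_modifiers,
    default_stopwords,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def modifiers():
    return default_modifiers()


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()


@pytest.fixture(scope="session")
def official_keywords():
    return [
        w.strip()
        for w in data_path("official_keywords.txt").read_text(encoding="utf-8").splitlines()
        if w.strip()
    ]


@pytest.fixture(scope="session")
def classifier(lexicon, modifiers):
    return EmotionClassifier(lexicon=lexicon, modifiers=modifiers)
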