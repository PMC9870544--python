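"""Fine-grained lexicon-based emotion scoring of microblog posts.

A post is split into sentences; sentences get position weights (first and
last sentences count double when there are more than two).  Inside each
sentence, every lexicon hit anchors an *emotion unit*: the emotion word plus
the negation words and degree adverbs attached to it.  A unit of category j
with intensity q, m negations and degree factors c_1..c_l scores

    e_j = (-1)^m * (prod_v c_v) * q

and 0 for every other category.  A negative score expresses the *reverse*
emotion: the unit is converted to the paired opposite category with the
absolute score (surprise converts to anticipate, the category that has no
lexicon words of its own).  Unit scores are summed per category into the
sentence vector E_i, sentence vectors are combined with the position weights
into the post vector, and the post is labeled with the arg-max category —
or neutral when the maximum falls below the threshold delta.

Modifier attachment is done by a pluggable :class:`ParserAdapter`; the
default is a dependency-free window rule: the up-to-``window`` tokens
immediately preceding the emotion word, not crossing a comma/顿号 boundary.
Tokenization is likewise pluggable, defaulting to greedy longest-match
against the lexicon and modifier vocabulary, which is exact on the synthetic
corpora this package generates and on lexicon-bearing spans in general.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import (
    CATEGORIES,
    NEUTRAL_LABEL,
    EmotionCategory,
    EmotionLexicon,
    ModifierLexicon,
    Sentiment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SEPARATORS",
    "SentenceSpan",
    "EmotionUnit",
    "PostEmotion",
    "sentence_weights",
    "split_sentences",
    "GreedyTokenizer",
    "extract_units",
    "score_unit",
    "convert_bidirectional",
    "sentence_vector",
    "post_vector",
    "classify_post",
    "EmotionClassifier",
]

#: Default sentence separators: Chinese/Western full stops, !, ?, semicolon, newline.
DEFAULT_SEPARATORS = frozenset("。！？!?；\n")

#: Clause boundaries the modifier window never crosses.
CLAUSE_BREAKS = frozenset("，、,:：;")


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence with its 1-based position and position weight."""

    index: int
    text: str
    weight: float


@dataclass(frozen=True)
class EmotionUnit:
    """Emotion word + attached negations and degree factors, the scoring atom."""

    emotion_word: str
    category: EmotionCategory
    intensity: float
    negation_count: int = 0
    factors: tuple[float, ...] = ()

    @property
    def score(self) -> float:
        """Signed unit score e_j = (-1)^m * prod(c_v) * q."""
        return score_unit(self)


@dataclass(frozen=True)
class PostEmotion:
    """Post-level result: 8-dim emotion vector, label, sentiment, threshold."""

    vector: np.ndarray
    label: str
    sentiment: str
    delta: float

    def as_dict(self) -> dict:
        return {
            "vector": [float(x) for x in self.vector],
            "label": self.label,
            "sentiment": self.sentiment,
        }


def sentence_weights(n: int) -> np.ndarray:
    """Position weights for n sentences.

    n <= 2: uniform 1/n.  n > 2: the first and last sentences get 2/(n+2),
    interior sentences 1/(n+2); the weights always sum to 1.
    """
    if n < 1:
        return np.zeros(0)
    if n <= 2:
        return np.full(n, 1.0 / n)
    w = np.full(n, 1.0 / (n + 2))
    w[0] = w[-1] = 2.0 / (n + 2)
    return w


def split_sentences(
    text: str, separators: Iterable[str] = DEFAULT_SEPARATORS
) -> list[SentenceSpan]:
    """Split a post into weighted sentences.

    Empty segments are dropped; a trailing unterminated segment is kept.
    """
    seps = set(separators)
    segments: list[str] = []
    buf: list[str] = []
    for ch in text or "":
        if ch in seps:
            seg = "".join(buf).strip()
            if seg:
                segments.append(seg)
            buf = []
        else:
            buf.append(ch)
    tail = "".join(buf).strip()
    if tail:
        segments.append(tail)
    weights = sentence_weights(len(segments))
    return [
        SentenceSpan(index=i + 1, text=seg, weight=float(w))
        for i, (seg, w) in enumerate(zip(segments, weights))
    ]


class GreedyTokenizer:
    """Greedy longest-match tokenizer over a fixed vocabulary.

    At each position the longest vocabulary word is consumed; characters that
    start no vocabulary word become single-character tokens.  Deterministic
    and segmenter-free, which keeps fixture tests exact; a trained word
    segmenter can be substituted via the classifier's ``tokenize`` hook.
    """

    def __init__(self, vocabulary: Iterable[str]):
        vocab = {w for w in vocabulary if w}
        self._vocab = vocab
        self._max_len = max((len(w) for w in vocab), default=1)

    def __call__(self, text: str) -> list[str]:
        tokens: list[str] = []
        i, n = 0, len(text)
        while i < n:
            for length in range(min(self._max_len, n - i), 1, -1):
                cand = text[i : i + length]
                if cand in self._vocab:
                    tokens.append(cand)
                    i += length
                    break
            else:
                tokens.append(text[i])
                i += 1
        return tokens


#: A parser adapter maps sentence text to (emotion_word, [modifier words]) pairs.
ParserAdapter = Callable[[str], Sequence[tuple[str, Sequence[str]]]]


def _window_units(
    tokens: Sequence[str],
    lexicon: EmotionLexicon,
    modifiers: ModifierLexicon,
    window: int,
) -> list[EmotionUnit]:
    units: list[EmotionUnit] = []
    for pos, tok in enumerate(tokens):
        entries = lexicon.lookup(tok)
        if not entries:
            continue
        m = 0
        factors: list[float] = []
        taken = 0
        j = pos - 1
        while j >= 0 and taken < window:
            prev = tokens[j]
            if prev in CLAUSE_BREAKS:
                break
            if prev in modifiers.negation_words:
                m += 1
            elif prev in modifiers.degree_factors:
                factors.append(modifiers.degree_factors[prev])
            j -= 1
            taken += 1
        factors.reverse()  # restore reading order
        for entry in entries:
            units.append(
                EmotionUnit(
                    emotion_word=tok,
                    category=entry.category,
                    intensity=entry.intensity,
                    negation_count=m,
                    factors=tuple(factors),
                )
            )
    return units


def extract_units(
    sentence: SentenceSpan | str,
    lexicon: EmotionLexicon,
    modifiers: ModifierLexicon,
    parser: ParserAdapter | None = None,
    *,
    tokenize: Callable[[str], list[str]] | None = None,
    window: int = 3,
) -> list[EmotionUnit]:
    """Extract emotion units from one sentence.

    With a parser adapter, each emotion word's modifiers are the words the
    parser attaches to it.  Without one (or on parser failure, which falls
    back with a warning), modifiers are collected from the up-to-``window``
    tokens immediately preceding the emotion word within the same clause.
    """
    text = sentence.text if isinstance(sentence, SentenceSpan) else sentence
    if parser is not None:
        try:
            pairs = parser(text)
        except Exception:  # fall back rather than lose the sentence
            logger.warning("parser adapter failed on %r; using window fallback", text)
            pairs = None
        if pairs is not None:
            units = []
            for word, mods in pairs:
                for entry in lexicon.lookup(word):
                    m = sum(1 for w in mods if w in modifiers.negation_words)
                    factors = tuple(
                        modifiers.degree_factors[w]
                        for w in mods
                        if w in modifiers.degree_factors
                    )
                    units.append(
                        EmotionUnit(word, entry.category, entry.intensity, m, factors)
                    )
            return units
    if tokenize is None:
        tokenize = GreedyTokenizer(lexicon.words | modifiers.words)
    return _window_units(tokenize(text), lexicon, modifiers, window)


def score_unit(unit: EmotionUnit) -> float:
    """Signed score e_j = (-1)^m * prod_v(c_v) * q of one emotion unit."""
    if unit.intensity <= 0:
        raise ValueError("unit intensity must be positive")
    if any(c <= 0 for c in unit.factors):
        raise ValueError("degree factors must be positive")
    return ((-1.0) ** unit.negation_count) * math.prod(unit.factors) * unit.intensity


def convert_bidirectional(
    category: EmotionCategory, score: float
) -> tuple[EmotionCategory, float]:
    """Map a signed category score to a nonnegative one via the paired emotion.

    Nonnegative scores keep their category; a negative score expresses the
    reverse emotion (e.g. negated joy is sadness, negated surprise is
    anticipation) and is re-assigned to the opposite category with |score|.
    """
    if score >= 0:
        return category, score
    return category.opposite(), -score


def sentence_vector(units: Iterable[EmotionUnit]) -> np.ndarray:
    """8-dim nonnegative sentence vector E_i: converted unit scores summed per category."""
    v = np.zeros(len(CATEGORIES))
    for unit in units:
        cat, s = convert_bidirectional(unit.category, score_unit(unit))
        v[cat.index] += s
    return v


def post_vector(
    sentences: Sequence[tuple[SentenceSpan, np.ndarray]]
) -> np.ndarray:
    """Weighted sum of sentence vectors: the post emotion vector."""
    v = np.zeros(len(CATEGORIES))
    for span, e_i in sentences:
        v += span.weight * np.asarray(e_i, dtype=float)
    return v


def classify_post(
    vector: np.ndarray, delta: float = 0.5
) -> tuple[str, str]:
    """Label a post vector: arg-max category, or neutral below the threshold.

    Ties break on the fixed category order (good, joy, surprise, anticipate,
    fear, disgust, sadness, anger).  Returns (label, sentiment).
    """
    if delta <= 0:
        raise ValueError("neutral threshold delta must be positive")
    v = np.asarray(vector, dtype=float)
    k = int(np.argmax(v))  # first max in canonical order
    if v[k] < delta:
        return NEUTRAL_LABEL, Sentiment.NEUTRAL.value
    cat = CATEGORIES[k]
    return cat.value, cat.sentiment.value


@dataclass
class EmotionClassifier:
    """End-to-end post annotator bundling lexicon, modifiers and configuration.

    Deterministic: identical input and configuration always yield identical
    vectors and labels.
    """

    lexicon: EmotionLexicon
    modifiers: ModifierLexicon
    delta: float = 0.5
    separators: frozenset[str] = DEFAULT_SEPARATORS
    window: int = 3
    parser: ParserAdapter | None = None
    tokenize: Callable[[str], list[str]] | None = None
    _tokenizer: Callable[[str], list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("neutral threshold delta must be positive")
        self._tokenizer = self.tokenize or GreedyTokenizer(
            self.lexicon.words | self.modifiers.words
        )

    def annotate(self, text: str) -> PostEmotion:
        """Score one post: sentence split, unit extraction, weighted aggregation."""
        spans = split_sentences(text or "", self.separators)
        pairs = []
        for span in spans:
            units = extract_units(
                span,
                self.lexicon,
                self.modifiers,
                self.parser,
                tokenize=self._tokenizer,
                window=self.window,
            )
            pairs.append((span, sentence_vector(units)))
        vec = post_vector(pairs)
        label, sentiment = classify_post(vec, self.delta)
        return PostEmotion(vector=vec, label=label, sentiment=sentiment, delta=self.delta)

    def annotate_posts(
        self, df: pd.DataFrame, text_col: str = "content_clean"
    ) -> pd.DataFrame:
        """Annotate a table of posts; adds label, sentiment and vector columns."""
        results = [self.annotate(t) for t in df[text_col].fillna("")]
        out = df.copy()
        out["label"] = [r.label for r in results]
        out["sentiment"] = [r.sentiment for r in results]
        out["vector"] = [r.vector.tolist() for r in results]
        return out
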