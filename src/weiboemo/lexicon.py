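"""Emotion lexicon, modifier lists, and the 8-category bidirectional scheme.

The classifier uses a DLUT-style affective lexicon: each Chinese word carries a
fine-grained category code (``PA``, ``NI``, ...), an intensity ``q`` (odd
integers 1-9 by convention) and a polarity flag.  The 20-odd fine codes are
mapped onto seven coarse emotions; the eighth category, *anticipate*, has no
lexicon entries of its own and is only reachable by negating a *surprise*
word (bidirectional conversion).

The four bidirectional pairs are good-disgust, joy-sadness, anger-fear and
surprise-anticipate; good/joy/surprise/anticipate roll up to positive
sentiment, the other four to negative.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "EmotionCategory",
    "Sentiment",
    "LexiconEntry",
    "EmotionLexicon",
    "ModifierLexicon",
    "LexiconFormatError",
    "LexiconValidationError",
    "DEGREE_LEVEL_FACTORS",
    "load_code_map",
    "load_lexicon",
    "load_modifiers",
    "load_stopwords",
    "default_code_map",
    "default_lexicon",
    "default_modifiers",
    "default_stopwords",
    "data_path",
]


class Sentiment(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"


class EmotionCategory(str, Enum):
    """The eight bidirectional emotion categories.

    Member order is the canonical vector index order and also the
    deterministic tie-break order used when classifying a post.
    """

    GOOD = "good"
    JOY = "joy"
    SURPRISE = "surprise"
    ANTICIPATE = "anticipate"
    FEAR = "fear"
    DISGUST = "disgust"
    SADNESS = "sadness"
    ANGER = "anger"

    @property
    def index(self) -> int:
        return _CATEGORY_INDEX[self]

    @property
    def sentiment(self) -> Sentiment:
        if self in (
            EmotionCategory.GOOD,
            EmotionCategory.JOY,
            EmotionCategory.SURPRISE,
            EmotionCategory.ANTICIPATE,
        ):
            return Sentiment.POSITIVE
        return Sentiment.NEGATIVE

    def opposite(self) -> "EmotionCategory":
        """The paired reverse emotion (an involution)."""
        return _OPPOSITE[self]


CATEGORIES: tuple[EmotionCategory, ...] = tuple(EmotionCategory)
_CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES)}

_OPPOSITE = {
    EmotionCategory.GOOD: EmotionCategory.DISGUST,
    EmotionCategory.DISGUST: EmotionCategory.GOOD,
    EmotionCategory.JOY: EmotionCategory.SADNESS,
    EmotionCategory.SADNESS: EmotionCategory.JOY,
    EmotionCategory.ANGER: EmotionCategory.FEAR,
    EmotionCategory.FEAR: EmotionCategory.ANGER,
    EmotionCategory.SURPRISE: EmotionCategory.ANTICIPATE,
    EmotionCategory.ANTICIPATE: EmotionCategory.SURPRISE,
}

NEUTRAL_LABEL = "neutral"

#: Default multiplicative factors for the six conventional degree-adverb
#: levels.  Used when a degree file gives level labels instead of numbers.
DEGREE_LEVEL_FACTORS: dict[str, float] = {
    "most": 2.0,
    "very": 1.75,
    "more": 1.5,
    "ish": 1.2,
    "insufficiently": 0.5,
    "over": 1.5,
}


class LexiconFormatError(ValueError):
    """Raised when a lexicon/modifier file does not have the expected columns."""


class LexiconValidationError(ValueError):
    """Raised when file contents violate a lexicon invariant."""


@dataclass(frozen=True)
class LexiconEntry:
    """One emotion word: surface form, DLUT code, mapped category, intensity q."""

    word: str
    dlut_code: str
    category: EmotionCategory
    intensity: float
    polarity: int = 0

    def __post_init__(self) -> None:
        if not self.word:
            raise LexiconValidationError("lexicon entry with empty word")
        if self.intensity <= 0:
            raise LexiconValidationError(
                f"non-positive intensity {self.intensity!r} for word {self.word!r}"
            )


class EmotionLexicon:
    """Word -> entries lookup with per-(word, category) polysemy resolution.

    Several DLUT senses of the same word within one category are collapsed to
    the maximum-intensity sense; distinct categories for the same surface form
    are all kept.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        by_key: dict[tuple[str, EmotionCategory], LexiconEntry] = {}
        for e in entries:
            key = (e.word, e.category)
            old = by_key.get(key)
            if old is None or e.intensity > old.intensity:
                by_key[key] = e
        self._by_word: dict[str, list[LexiconEntry]] = {}
        for (word, _), e in sorted(
            by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].index)
        ):
            self._by_word.setdefault(word, []).append(e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_word.values())

    def __contains__(self, word: str) -> bool:
        return word in self._by_word

    def __iter__(self):
        for entries in self._by_word.values():
            yield from entries

    @property
    def words(self) -> set[str]:
        return set(self._by_word)

    def lookup(self, word: str) -> list[LexiconEntry]:
        return list(self._by_word.get(word, ()))

    def scaled(self, factor: float) -> "EmotionLexicon":
        """A copy with every intensity multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return EmotionLexicon(
            LexiconEntry(e.word, e.dlut_code, e.category, e.intensity * factor, e.polarity)
            for e in self
        )


@dataclass
class ModifierLexicon:
    """Degree-adverb factors c_v and negation words.

    The two word sets must be disjoint: a word is either a multiplicative
    strength modifier or a polarity flip, never both.
    """

    degree_factors: dict[str, float] = field(default_factory=dict)
    negation_words: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = [w for w, f in self.degree_factors.items() if f <= 0]
        if bad:
            raise LexiconValidationError(f"non-positive degree factors for {bad!r}")
        overlap = set(self.degree_factors) & self.negation_words
        if overlap:
            raise LexiconValidationError(
                f"words present in both degree and negation lists: {sorted(overlap)!r}"
            )

    @property
    def words(self) -> set[str]:
        return set(self.degree_factors) | self.negation_words


def data_path(name: str) -> Path:
    """Path of a packaged data file (toy lexicon, word lists, code map)."""
    return Path(resources.files("weiboemo.data").joinpath(name))


def load_code_map(path: str | Path) -> dict[str, EmotionCategory]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {code: EmotionCategory(name) for code, name in raw.items()}


def default_code_map() -> dict[str, EmotionCategory]:
    """DLUT major-class code map (7 lexical classes -> 7 categories)."""
    return load_code_map(data_path("dlut_code_map.json"))


def _sniff_delimiter(sample: str) -> str:
    return "\t" if "\t" in sample.splitlines()[0] else ","


def load_lexicon(
    path: str | Path,
    code_map: Mapping[str, EmotionCategory] | None = None,
) -> EmotionLexicon:
    """Load a DLUT-style lexicon CSV/TSV with columns word, code, intensity, polarity.

    Rows whose code is absent from ``code_map`` are reported and skipped;
    duplicate senses keep the maximum intensity per (word, category).
    """
    if code_map is None:
        code_map = default_code_map()
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        warnings.warn(f"empty lexicon file: {path}", stacklevel=2)
        return EmotionLexicon([])
    reader = csv.DictReader(text.splitlines(), delimiter=_sniff_delimiter(text))
    required = {"word", "code", "intensity", "polarity"}
    have = {(f or "").strip().lower() for f in (reader.fieldnames or [])}
    if not required <= have:
        raise LexiconFormatError(
            f"{path}: missing columns {sorted(required - have)} (found {sorted(have)})"
        )
    entries: list[LexiconEntry] = []
    skipped: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
        code = row["code"]
        category = code_map.get(code)
        if category is None:
            skipped.append(code)
            continue
        try:
            q = float(row["intensity"])
        except ValueError as exc:
            raise LexiconValidationError(
                f"{path} line {lineno}: intensity {row['intensity']!r} is not a number"
            ) from exc
        if q <= 0:
            raise LexiconValidationError(
                f"{path} line {lineno}: non-positive intensity {q} for {row['word']!r}"
            )
        polarity = int(row["polarity"]) if row["polarity"] else 0
        entries.append(LexiconEntry(row["word"], code, category, q, polarity))
    if skipped:
        logger.warning(
            "skipped %d lexicon rows with unmapped codes: %s",
            len(skipped),
            sorted(set(skipped)),
        )
    if not entries:
        warnings.warn(f"lexicon file {path} produced no entries", stacklevel=2)
    return EmotionLexicon(entries)


def load_modifiers(
    degree_path: str | Path, negation_path: str | Path
) -> ModifierLexicon:
    """Load degree-adverb factors and negation words from plain-text files.

    Degree lines are ``word<TAB-or-comma>factor``; the factor may also be one
    of the six level labels (most/very/more/ish/insufficiently/over), which
    are resolved through :data:`DEGREE_LEVEL_FACTORS`.  Negation files are one
    word per line.
    """
    factors: dict[str, float] = {}
    for lineno, line in enumerate(
        Path(degree_path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", ",").split(",")
        if len(parts) != 2:
            raise LexiconFormatError(
                f"{degree_path} line {lineno}: expected 'word<sep>factor', got {line!r}"
            )
        word, value = parts[0].strip(), parts[1].strip()
        if value in DEGREE_LEVEL_FACTORS:
            factors[word] = DEGREE_LEVEL_FACTORS[value]
        else:
            try:
                factors[word] = float(value)
            except ValueError as exc:
                raise LexiconValidationError(
                    f"{degree_path} line {lineno}: factor {value!r} is neither a "
                    f"number nor a level label {sorted(DEGREE_LEVEL_FACTORS)}"
                ) from exc
    negations = {
        w.strip()
        for w in Path(negation_path).read_text(encoding="utf-8").splitlines()
        if w.strip() and not w.startswith("#")
    }
    return ModifierLexicon(degree_factors=factors, negation_words=negations)


def load_stopwords(path: str | Path) -> set[str]:
    return {
        w.strip()
        for w in Path(path).read_text(encoding="utf-8").splitlines()
        if w.strip()
    }


def default_lexicon() -> EmotionLexicon:
    """The packaged toy lexicon (~60 words across all 7 DLUT lexical classes)."""
    return load_lexicon(data_path("toy_lexicon.csv"))


def default_modifiers() -> ModifierLexicon:
    return load_modifiers(data_path("degree_adverbs.tsv"), data_path("negation_words.txt"))


def default_stopwords() -> set[str]:
    return load_stopwords(data_path("stopwords.txt"))
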