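"""Synthetic microblog corpora with known ground truth.

The generator emits a raw-crawl-shaped table (publisher, content, publisher
link, relative posting time, source, engagement counts, crawl timestamp)
plus a gold table (emotion label, sentiment, user type, calendar day), so
the whole pipeline — preprocessing, emotion scoring, evaluation,
aggregation, lead-lag — can be exercised without any real lexicon or crawl.

Post text is concatenated template fragments plus sampled lexicon words, not
natural Chinese: every non-neutral post carries exactly one seeded emotion
unit whose net (position-weighted) score is guaranteed to clear the neutral
threshold, so the classifier's gold recovery is exact by construction.
Negation is seeded on a word of the *opposite* category so the bidirectional
conversion lands on the gold label; *anticipate*, which has no lexicon words
of its own, is always expressed as a negated surprise word.  Filler
vocabulary is disjoint from the lexicon and modifier lists, so neutral posts
can never score.

Posts are allocated to calendar days by largest-remainder rounding of a
smooth daily intensity profile; the personal profile is the official profile
shifted by ``lead_lag_days``, so the configured lead-lag is present exactly,
not just in expectation.  Per-day emotion counts are likewise allocated by
largest remainder of the configured mixture, so corpus-level proportions
match the mixture to within rounding.  All remaining choices (word choice,
modifiers, time dialects, row order) are drawn from a single seeded RNG:
the same seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lexicon import (
    NEUTRAL_LABEL,
    EmotionCategory,
    EmotionLexicon,
    ModifierLexicon,
)
from .aggregate import label_sentiment

__all__ = [
    "TABLE_MIXTURE",
    "GeneratorConfig",
    "ConfigError",
    "generate_corpus",
    "generate_gold_eval_set",
    "generate_planted_topics",
    "allocate_largest_remainder",
]

#: Emotion mixture matching the reference corpus distribution of 32,698
#: COVID-19 posts (proportions of good/joy/surprise/anticipate/neutral/
#: fear/disgust/sadness/anger).
TABLE_MIXTURE: dict[str, float] = {
    "good": 12515 / 32698,
    "joy": 3965 / 32698,
    "surprise": 109 / 32698,
    "anticipate": 30 / 32698,
    "neutral": 8296 / 32698,
    "fear": 3633 / 32698,
    "disgust": 2635 / 32698,
    "sadness": 889 / 32698,
    "anger": 626 / 32698,
}

# filler fragments: no character overlaps the lexicon, degree or negation lists
FILLER_WORDS = (
    "天气", "晴朗", "出门", "散步", "吃饭", "喝茶", "看书", "上班",
    "路口", "风景", "照片", "记录", "日常", "街道", "公园", "窗外",
    "阳光", "清晨", "傍晚", "周末",
)

OFFICIAL_NAME_TEMPLATES = ("{}日报", "{}电视台", "{}发布", "{}融媒体")
PERSONAL_NAME_TEMPLATES = ("小{}", "{}同学", "爱拍照的{}", "{}的树洞")
NAME_STEMS = ("江", "河", "山", "海", "云", "星", "林", "雨")

SOURCES = ("微博 weibo.com", "iPhone客户端", "Android客户端", "微博网页版")


class ConfigError(ValueError):
    """Invalid generator configuration (mixture, rates, or lexicon coverage)."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_posts: int = 1000
    mixture: dict[str, float] = field(default_factory=lambda: dict(TABLE_MIXTURE))
    official_fraction: float = 6411 / 32698
    date_start: str = "2022-07-01"
    date_end: str = "2022-08-31"
    lead_lag_days: int = 1
    negation_rate: float = 0.2
    degree_rate: float = 0.3
    decoration_rate: float = 0.3
    max_sentences: int = 4
    min_intensity: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise ConfigError("n_posts must be >= 1")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ConfigError("emotion mixture must sum to 1")
        valid = {c.value for c in EmotionCategory} | {NEUTRAL_LABEL}
        unknown = set(self.mixture) - valid
        if unknown:
            raise ConfigError(f"unknown labels in mixture: {sorted(unknown)}")
        for name in ("official_fraction", "negation_rate", "degree_rate", "decoration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 1 <= self.max_sentences:
            raise ConfigError("max_sentences must be >= 1")
        span = pd.date_range(self.date_start, self.date_end, freq="D")
        if len(span) <= abs(self.lead_lag_days):
            raise ConfigError("date span must exceed the configured lead-lag")


def allocate_largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (largest remainder)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    quota = total * w / w.sum()
    alloc = np.floor(quota).astype(int)
    rem = total - alloc.sum()
    if rem > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:rem]] += 1
    return alloc


def _intensity(n_days: int, shift: int = 0) -> np.ndarray:
    """Smooth daily posting intensity: baseline plus one pronounced bump.

    The bump peaks on an integer day so that a shifted copy of the profile
    peaks exactly ``shift`` days later (no discretization smearing).
    """
    d = np.arange(n_days, dtype=float) - shift
    peak = float(n_days // 3)
    return 1.0 + 4.0 * np.exp(-0.5 * ((d - peak) / 3.0) ** 2)


def _category_words(
    lexicon: EmotionLexicon, category: EmotionCategory, min_q: float
) -> list:
    entries = [e for e in lexicon if e.category == category and e.intensity >= min_q]
    return sorted(entries, key=lambda e: (e.word, e.dlut_code))


def _check_coverage(config: GeneratorConfig, lexicon: EmotionLexicon) -> dict:
    """Per-label word pools; raises ConfigError when a requested label is unreachable."""
    pools: dict[str, dict] = {}
    for label, prob in config.mixture.items():
        if prob <= 0 or label == NEUTRAL_LABEL:
            continue
        cat = EmotionCategory(label)
        direct = _category_words(lexicon, cat, config.min_intensity)
        flip = _category_words(lexicon, cat.opposite(), config.min_intensity)
        if not direct and not flip:
            raise ConfigError(
                f"mixture requests {label!r} but the lexicon has no words of that "
                f"category nor of its opposite ({cat.opposite().value!r}) to negate"
            )
        pools[label] = {"direct": direct, "flip": flip}
    return pools


def _choice(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def _filler_sentence(rng: np.random.Generator) -> str:
    k = int(rng.integers(2, 5))
    return "".join(_choice(rng, FILLER_WORDS) for _ in range(k))


def _degree_words(modifiers: ModifierLexicon) -> list[str]:
    return sorted(modifiers.degree_factors)


def _emotional_sentence(
    rng: np.random.Generator,
    label: str,
    pools: dict,
    modifiers: ModifierLexicon,
    config: GeneratorConfig,
) -> str:
    pool = pools[label]
    use_flip = bool(pool["flip"]) and (
        not pool["direct"] or rng.random() < config.negation_rate
    )
    if use_flip:
        entry = _choice(rng, pool["flip"])
        negation = _choice(rng, sorted(modifiers.negation_words))
        unit = negation + entry.word
    else:
        entry = _choice(rng, pool["direct"])
        unit = entry.word
    if rng.random() < config.degree_rate:
        unit = _choice(rng, _degree_words(modifiers)) + unit
    prefix = _choice(rng, FILLER_WORDS) if rng.random() < 0.5 else ""
    return prefix + unit


def _decorate(rng: np.random.Generator, text: str, config: GeneratorConfig) -> str:
    if rng.random() < config.decoration_rate:
        text = "#疫情防控# " + text
    if rng.random() < config.decoration_rate / 2:
        text = "@健康小助手 " + text
    if rng.random() < config.decoration_rate / 2:
        text = text + " http://t.cn/A6x" + str(int(rng.integers(1000, 9999)))
    return text


def _posting_time_fields(
    rng: np.random.Generator, day: pd.Timestamp
) -> tuple[str, str]:
    """A (posting_time, current_time) pair that resolves back to ``day``."""
    hh = int(rng.integers(8, 22))
    mm = int(rng.integers(60))
    posted = day + pd.Timedelta(hours=hh, minutes=mm)
    dialect = int(rng.integers(3))
    if dialect == 0:
        minutes = int(rng.integers(1, 50))
        return f"{minutes}分钟前", str(posted + pd.Timedelta(minutes=minutes))
    if dialect == 1:
        return f"今天 {hh:02d}:{mm:02d}", str(posted + pd.Timedelta(hours=1))
    return str(posted), str(posted + pd.Timedelta(hours=2))


def generate_corpus(
    config: GeneratorConfig,
    lexicon: EmotionLexicon,
    modifiers: ModifierLexicon,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one corpus; returns (raw crawl table, gold table), row-aligned."""
    rng = np.random.default_rng(config.seed)
    pools = _check_coverage(config, lexicon)
    days = pd.date_range(config.date_start, config.date_end, freq="D")
    n_days = len(days)

    n_official = int(round(config.n_posts * config.official_fraction))
    n_personal = config.n_posts - n_official
    day_counts = {
        "official": allocate_largest_remainder(n_official, _intensity(n_days)),
        "personal": allocate_largest_remainder(
            n_personal, _intensity(n_days, shift=config.lead_lag_days)
        ),
    }
    labels = list(config.mixture)
    probs = np.array([config.mixture[l] for l in labels])

    raw_rows, gold_rows = [], []
    for user_type in ("official", "personal"):
        for di, day in enumerate(days):
            c = int(day_counts[user_type][di])
            if c == 0:
                continue
            label_alloc = allocate_largest_remainder(c, probs)
            for label, n_label in zip(labels, label_alloc):
                for _ in range(int(n_label)):
                    raw, gold = _one_post(
                        rng, label, user_type, day, pools, modifiers, config
                    )
                    raw_rows.append(raw)
                    gold_rows.append(gold)
    order = rng.permutation(len(raw_rows))
    raw = pd.DataFrame([raw_rows[i] for i in order]).reset_index(drop=True)
    gold = pd.DataFrame([gold_rows[i] for i in order]).reset_index(drop=True)
    gold.index.name = raw.index.name = "post_id"
    return raw, gold


def _one_post(
    rng: np.random.Generator,
    label: str,
    user_type: str,
    day: pd.Timestamp,
    pools: dict,
    modifiers: ModifierLexicon,
    config: GeneratorConfig,
) -> tuple[dict, dict]:
    n_sent = int(rng.integers(1, config.max_sentences + 1))
    sentences = [_filler_sentence(rng) for _ in range(n_sent)]
    if label != NEUTRAL_LABEL:
        # first or last position keeps the position weight >= 1/3, so the
        # seeded unit always clears the default neutral threshold
        pos = 0 if rng.random() < 0.5 else n_sent - 1
        sentences[pos] = _emotional_sentence(rng, label, pools, modifiers, config)
    enders = "。！？"
    content = "".join(s + _choice(rng, enders) for s in sentences)
    content = _decorate(rng, content, config)

    stem = _choice(rng, NAME_STEMS)
    if user_type == "official":
        publisher = _choice(rng, OFFICIAL_NAME_TEMPLATES).format(stem)
        description = "权威信息发布平台"
    else:
        publisher = _choice(rng, PERSONAL_NAME_TEMPLATES).format(stem)
        description = "记录生活点滴"
    uid = str(int(rng.integers(10**9, 10**10)))
    link_form = "https://weibo.com/u/{}" if rng.random() < 0.5 else "https://weibo.com/{}?refer_flag=1001030103"
    posting_time, current_time = _posting_time_fields(rng, day)
    raw = {
        "publisher": publisher,
        "content": content,
        "publisher_link": link_form.format(uid),
        "posting_time": posting_time,
        "source": _choice(rng, SOURCES),
        "comments": int(rng.poisson(5)),
        "retweets": int(rng.poisson(2)),
        "likes": int(rng.poisson(20)),
        "current_time": current_time,
        "description": description,
    }
    gold = {
        "gold_label": label,
        "gold_sentiment": label_sentiment(label),
        "user_type": user_type,
        "date": day.date().isoformat(),
    }
    return raw, gold


def generate_gold_eval_set(
    n: int,
    classes: Sequence[str],
    noise: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gold labels plus predictions corrupted by symmetric label noise.

    Each prediction equals its gold label with probability 1 - ``noise`` and
    is otherwise drawn uniformly from the remaining classes, so expected
    accuracy is exactly 1 - noise and the full metrics report has known
    closed-form values.
    """
    if not 0.0 <= noise <= 1.0:
        raise ConfigError("noise must lie in [0, 1]")
    classes = list(classes)
    if len(classes) < 2:
        raise ConfigError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    gold = [classes[int(i)] for i in rng.integers(len(classes), size=n)]
    pred = []
    for g in gold:
        if rng.random() < noise:
            others = [c for c in classes if c != g]
            pred.append(_choice(rng, others))
        else:
            pred.append(g)
    return pd.DataFrame({"gold": gold, "predicted": pred})


def generate_planted_topics(
    n_topics: int,
    n_docs: int = 120,
    words_per_topic: int = 12,
    doc_len: int = 25,
    seed: int = 0,
) -> tuple[list[list[str]], list[int]]:
    """Token documents with K planted topics over disjoint vocabularies.

    Each document draws all its tokens from a single topic's vocabulary
    (words ``t{k}w{j}``), so the true number of topics is known exactly.
    Returns (documents, per-document topic ids).
    """
    if n_topics < 1:
        raise ConfigError("n_topics must be >= 1")
    rng = np.random.default_rng(seed)
    vocabs = [
        [f"t{k}w{j}" for j in range(words_per_topic)] for k in range(n_topics)
    ]
    docs, topics = [], []
    assignments = allocate_largest_remainder(n_docs, np.ones(n_topics))
    for k, n_k in enumerate(assignments):
        for _ in range(int(n_k)):
            docs.append([_choice(rng, vocabs[k]) for _ in range(doc_len)])
            topics.append(k)
    order = rng.permutation(len(docs))
    return [docs[i] for i in order], [topics[i] for i in order]
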