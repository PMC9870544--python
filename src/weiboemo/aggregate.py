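"""Corpus-level aggregation: distributions, group comparison, time series.

Given labeled posts, this module computes the emotion and sentiment
distribution tables, compares official and personal users with a Pearson
chi-square test on the 2x3 group-by-sentiment contingency table, builds
zero-filled daily post-count series per emotion and user type (official
series are conventionally scaled up by the personal/official volume ratio so
trends are comparable), and quantifies lead-lag between two series as the
shift maximizing Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import round_half_up
from .lexicon import CATEGORIES, NEUTRAL_LABEL, EmotionCategory, Sentiment

__all__ = [
    "DistributionTable",
    "GroupComparison",
    "DailySeries",
    "label_sentiment",
    "distribution",
    "distribution_from_counts",
    "compare_groups",
    "daily_series",
    "lead_lag",
]

EMOTION_ORDER = [c.value for c in CATEGORIES]
SENTIMENT_ORDER = [s.value for s in Sentiment]


def label_sentiment(label: str) -> str:
    """Sentiment rollup of an emotion label (neutral stays neutral)."""
    if label == NEUTRAL_LABEL:
        return Sentiment.NEUTRAL.value
    return EmotionCategory(label).sentiment.value


@dataclass(frozen=True)
class DistributionTable:
    """Counts and percentages per emotion and per sentiment."""

    emotion_counts: dict[str, int]
    sentiment_counts: dict[str, int]
    total: int
    emotion_ndigits: int = 2
    sentiment_ndigits: int = 1

    def emotion_percentages(self, ndigits: int | None = None) -> dict[str, float]:
        nd = self.emotion_ndigits if ndigits is None else ndigits
        return {
            k: round_half_up(100.0 * v / self.total, nd)
            for k, v in self.emotion_counts.items()
        }

    def sentiment_percentages(self, ndigits: int | None = None) -> dict[str, float]:
        nd = self.sentiment_ndigits if ndigits is None else ndigits
        return {
            k: round_half_up(100.0 * v / self.total, nd)
            for k, v in self.sentiment_counts.items()
        }

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": k,
                "kind": "emotion" if k != NEUTRAL_LABEL else "neutral",
                "count": v,
                "percentage": self.emotion_percentages()[k],
            }
            for k, v in self.emotion_counts.items()
        ]
        return pd.DataFrame(rows)


def distribution_from_counts(
    counts: Mapping[str, int],
    emotion_ndigits: int = 2,
    sentiment_ndigits: int = 1,
) -> DistributionTable:
    """Build a distribution table from per-label counts.

    ``counts`` maps emotion labels (plus ``neutral``) to post counts; the
    total and the sentiment rollup are derived from the counts themselves.
    """
    if not counts:
        raise ValueError("empty counts")
    emotion_counts = {k: int(counts.get(k, 0)) for k in EMOTION_ORDER + [NEUTRAL_LABEL]}
    total = sum(emotion_counts.values())
    if total == 0:
        raise ValueError("counts sum to zero")
    sentiment_counts = {s: 0 for s in SENTIMENT_ORDER}
    for k, v in emotion_counts.items():
        sentiment_counts[label_sentiment(k)] += v
    return DistributionTable(
        emotion_counts=emotion_counts,
        sentiment_counts=sentiment_counts,
        total=total,
        emotion_ndigits=emotion_ndigits,
        sentiment_ndigits=sentiment_ndigits,
    )


def distribution(
    labels: Sequence[str],
    emotion_ndigits: int = 2,
    sentiment_ndigits: int = 1,
) -> DistributionTable:
    """Distribution table of a labeled corpus (one label per post)."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty corpus")
    counts = pd.Series(labels).value_counts().to_dict()
    unknown = set(counts) - set(EMOTION_ORDER) - {NEUTRAL_LABEL}
    if unknown:
        raise ValueError(f"unknown labels in corpus: {sorted(unknown)}")
    return distribution_from_counts(counts, emotion_ndigits, sentiment_ndigits)


@dataclass(frozen=True)
class GroupComparison:
    """Official vs personal sentiment comparison with a chi-square test."""

    official: DistributionTable
    personal: DistributionTable
    statistic: float
    p_value: float
    dof: int
    table: pd.DataFrame
    warnings: tuple[str, ...] = field(default=())

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_groups(
    official_labels: Sequence[str], personal_labels: Sequence[str]
) -> GroupComparison:
    """Pearson chi-square (no continuity correction) on the 2x3 group-by-sentiment table."""
    if not len(official_labels) or not len(personal_labels):
        raise ValueError("both groups must be non-empty")
    off = distribution(list(official_labels))
    per = distribution(list(personal_labels))
    table = pd.DataFrame(
        [off.sentiment_counts, per.sentiment_counts], index=["official", "personal"]
    )[SENTIMENT_ORDER]
    # drop sentiment columns empty in both groups (chi-square undefined there)
    table = table.loc[:, table.sum(axis=0) > 0]
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    warns = ()
    if (expected < 1).any():
        warns = ("expected cell count below 1; chi-square approximation unreliable",)
    return GroupComparison(
        official=off,
        personal=per,
        statistic=float(chi2),
        p_value=float(p),
        dof=int(dof),
        table=table,
        warnings=warns,
    )


@dataclass(frozen=True)
class DailySeries:
    """Date-indexed daily post counts for one (emotion, user type) slice."""

    counts: pd.Series  # DatetimeIndex (daily), int counts before scaling
    emotion: str
    user_type: str
    scale: float = 1.0

    @property
    def scaled(self) -> pd.Series:
        return self.counts * self.scale


def daily_series(
    posts: pd.DataFrame,
    emotion: str | None = None,
    user_type: str | None = None,
    span: tuple | None = None,
    scale: float = 1.0,
    date_col: str = "posted_at",
) -> DailySeries:
    """Zero-filled daily counts of posts matching an emotion and user type.

    ``span`` (start, end) defaults to the full corpus date range so that
    series for different slices share an index.
    """
    if date_col not in posts.columns:
        raise ValueError(f"posts lack a {date_col!r} column")
    dates = pd.to_datetime(posts[date_col]).dt.normalize()
    sel = pd.Series(True, index=posts.index)
    if emotion is not None:
        sel &= posts["label"] == emotion
    if user_type is not None:
        sel &= posts["user_type"] == user_type
    if span is None:
        if dates.dropna().empty:
            raise ValueError("no parseable dates in corpus")
        span = (dates.min(), dates.max())
    idx = pd.date_range(pd.Timestamp(span[0]), pd.Timestamp(span[1]), freq="D")
    counts = (
        dates[sel].value_counts().reindex(idx, fill_value=0).astype(int).sort_index()
    )
    return DailySeries(
        counts=counts, emotion=emotion or "all", user_type=user_type or "all", scale=scale
    )


def lead_lag(
    series_a: pd.Series | np.ndarray,
    series_b: pd.Series | np.ndarray,
    max_lag: int = 7,
) -> tuple[int, float]:
    """Best shift of b relative to a, by Pearson correlation.

    A positive lag L means ``series_b`` follows ``series_a`` by L days
    (b[t] tracks a[t-L]): a leads b.  Ties prefer the smallest |lag|, then
    the positive sign.  Raises on constant overlapping segments, where the
    correlation is undefined.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n = len(a)
    if n <= max_lag:
        raise ValueError("series shorter than max_lag + 1")
    best: tuple[int, float] | None = None
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), -np.sign(l))):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if best is None or r > best[1] + 1e-12:
            best = (lag, r)
    if best is None:
        raise ValueError("correlation undefined: constant series at every lag")
    return best
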