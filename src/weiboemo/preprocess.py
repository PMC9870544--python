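"""Preprocessing of crawled microblog post tables.

Turns the raw crawl export (publisher, content, publisher link, relative
posting time, engagement counts, crawl timestamp) into a cleaned, typed table:
absolute posting timestamps, extracted user IDs, official/personal user
typing, and content with topic markers, @-mentions and URLs stripped.

Stopword removal is deliberately deferred to the topic-mining path
(``for_topics=True``): common stopword lists contain negation and degree
words, and removing them before emotion scoring would corrupt the
emotion-unit windows.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RAW_COLUMNS",
    "TimeParseError",
    "UserIdError",
    "parse_relative_time",
    "extract_user_id",
    "clean_content",
    "classify_user",
    "dedupe_posts",
    "preprocess_posts",
]

#: Canonical raw-crawl column names.
RAW_COLUMNS = (
    "publisher",
    "content",
    "publisher_link",
    "posting_time",
    "source",
    "comments",
    "retweets",
    "likes",
    "current_time",
)


class TimeParseError(ValueError):
    """Unrecognized posting-time string."""


class UserIdError(ValueError):
    """Publisher link without an extractable user ID."""


_REL_PATTERNS = [
    (re.compile(r"^(\d+)\s*(?:秒|秒钟)前$"), "seconds"),
    (re.compile(r"^(\d+)\s*(?:分|分钟)前$"), "minutes"),
    (re.compile(r"^(\d+)\s*(?:小时)前$"), "hours"),
    (re.compile(r"^(\d+)\s*seconds?\s+ago$", re.I), "seconds"),
    (re.compile(r"^(\d+)\s*minutes?\s+ago$", re.I), "minutes"),
    (re.compile(r"^(\d+)\s*hours?\s+ago$", re.I), "hours"),
]
_TODAY = re.compile(r"^(?:今天|today)\s*(\d{1,2}):(\d{2})$", re.I)


def parse_relative_time(posting_time: str, current_time) -> pd.Timestamp:
    """Resolve a crawl-style posting time against the crawl timestamp.

    Accepts "N秒前"/"N分钟前"/"N小时前" (and English equivalents),
    "今天 HH:MM"/"Today HH:MM", and absolute datetimes.
    """
    now = pd.Timestamp(current_time)
    s = str(posting_time).strip()
    for pattern, unit in _REL_PATTERNS:
        m = pattern.match(s)
        if m:
            return now - pd.Timedelta(**{unit: int(m.group(1))})
    m = _TODAY.match(s)
    if m:
        hh, mm = int(m.group(1)), int(m.group(2))
        if hh > 23 or mm > 59:
            raise TimeParseError(f"invalid time of day in {posting_time!r}")
        return now.normalize() + pd.Timedelta(hours=hh, minutes=mm)
    try:
        ts = pd.Timestamp(s)
    except (ValueError, TypeError) as exc:
        raise TimeParseError(f"unrecognized posting time {posting_time!r}") from exc
    if pd.isna(ts):
        raise TimeParseError(f"unrecognized posting time {posting_time!r}")
    return ts


_USER_ID = re.compile(r"weibo\.com/(?:u/)?(\d+)(?:[/?#]|$)")


def extract_user_id(publisher_link: str) -> str:
    """Extract the numeric user ID from a profile URL.

    Both ``weibo.com/<digits>`` and ``weibo.com/u/<digits>`` dialects are
    accepted; query strings are ignored.
    """
    m = _USER_ID.search(str(publisher_link))
    if not m:
        raise UserIdError(f"no user ID in publisher link {publisher_link!r}")
    return m.group(1)


_TOPIC = re.compile(r"#([^#]*)#")
_MENTION = re.compile(r"@[\w一-鿿·\-]+")
_URL = re.compile(r"(?:https?://|www\.)\S+")


def clean_content(
    text: str, stopwords: Iterable[str] = (), *, for_topics: bool = False
) -> str:
    """Strip #topic# spans, @-mentions and URLs; optionally stopwords.

    Paired ``#...#`` topic markers are removed with their contents; an
    unpaired ``#`` is left intact.  Stopwords are removed only when
    ``for_topics`` is set (topic-mining path); the emotion-scoring path keeps
    them so negation and degree words survive.  Idempotent.
    """
    if not text:
        return ""
    s = _TOPIC.sub("", str(text))
    s = _URL.sub("", s)
    s = _MENTION.sub("", s)
    s = re.sub(r"\s+", " ", s).strip()
    if for_topics and stopwords:
        for w in sorted(set(stopwords), key=len, reverse=True):
            if w:
                s = s.replace(w, "")
    return s.strip()


def _normalize(text: str) -> str:
    # full-width -> half-width, casefold; makes keyword matching width/case-insensitive
    return unicodedata.normalize("NFKC", str(text or "")).casefold()


def classify_user(username: str, description: str, keywords: Sequence[str]) -> str:
    """Type a user as official/personal/unknown from profile text.

    Official if any keyword occurs in the (normalized) username or brief
    description; unknown when both fields are empty; personal otherwise.
    """
    if not keywords:
        raise ValueError("official-user keyword list must be non-empty")
    uname, desc = _normalize(username), _normalize(description)
    if not uname and not desc:
        return "unknown"
    for kw in keywords:
        k = _normalize(kw)
        if k and (k in uname or k in desc):
            return "official"
    return "personal"


def dedupe_posts(df: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (publisher, content) rows, keeping the first occurrence."""
    return df.drop_duplicates(subset=["publisher", "content"], keep="first").reset_index(
        drop=True
    )


@dataclass
class PreprocessReport:
    n_in: int
    n_deduped: int
    n_time_errors: int
    n_id_errors: int


def preprocess_posts(
    df: pd.DataFrame,
    official_keywords: Sequence[str],
    stopwords: Iterable[str] = (),
    description_col: str = "description",
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full preprocessing pass over a raw-crawl table.

    Returns the cleaned table (adds user_id, user_type, posted_at,
    content_clean, content_topics) and a small report of row counts.  Rows
    with unparseable times or links keep NaT/empty values rather than being
    dropped; content-empty posts are retained (they classify as neutral
    downstream).
    """
    missing = {"publisher", "content", "publisher_link", "posting_time", "current_time"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    n_in = len(df)
    out = dedupe_posts(df).copy()

    n_time_err = 0

    def _time(row):
        nonlocal n_time_err
        try:
            return parse_relative_time(row["posting_time"], row["current_time"])
        except TimeParseError:
            n_time_err += 1
            return pd.NaT

    n_id_err = 0

    def _uid(link):
        nonlocal n_id_err
        try:
            return extract_user_id(link)
        except UserIdError:
            n_id_err += 1
            return ""

    out["posted_at"] = out.apply(_time, axis=1)
    out["user_id"] = out["publisher_link"].map(_uid)
    desc = out[description_col] if description_col in out.columns else [""] * len(out)
    out["user_type"] = [
        classify_user(u, d, official_keywords)
        for u, d in zip(out["publisher"].fillna(""), pd.Series(desc).fillna(""))
    ]
    out["content_clean"] = out["content"].fillna("").map(clean_content)
    out["content_topics"] = out["content"].fillna("").map(
        lambda t: clean_content(t, stopwords, for_topics=True)
    )
    report = PreprocessReport(
        n_in=n_in,
        n_deduped=n_in - len(out),
        n_time_errors=n_time_err,
        n_id_errors=n_id_err,
    )
    return out, report
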