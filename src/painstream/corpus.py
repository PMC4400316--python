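"""Tweet corpus data model and I/O.

A :class:`Corpus` is an ordered collection of :class:`Tweet` records sharing a
query term (the search keyword every tweet contains, e.g. ``"pain"``).  The
module provides parsing from JSON-lines or CSV, exact-duplicate removal
(producing the *reduced* corpus), microblog-aware tokenization, and
localization of UTC timestamps to per-city local hour bins.

Tokenization rules: text is lower-cased; URLs, @-mentions and leading ``#``
are removed; punctuation is stripped except intra-word apostrophes (so
contractions like ``don't`` stay single tokens); stopwords and, optionally,
the query term are dropped; emoticons are preserved verbatim as tokens.
Negators (``no``, ``not``, ``don't`` ...) are deliberately absent from the
packaged stopword list because they feed the sentiment negation rule and are
themselves high-frequency content terms in pain discourse.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "Tweet",
    "Corpus",
    "CorpusParseError",
    "DEFAULT_STOPWORDS",
    "load_stopwords",
    "parse_tweets",
    "write_tweets",
    "deduplicate",
    "tokenize",
    "tokenize_corpus",
    "localize_timestamps",
    "hour_bin",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# Common western emoticons: an optional nose between eyes and mouth, plus a
# handful of fixed forms (hearts, D:, \o/). Checked on raw whitespace tokens
# before any punctuation stripping.
_EMOTICON_RE = re.compile(
    r"^(?:>?[:;=8xX][-'o^]?[)(\[\]dDpP/\\|@*{}3]|D:|<3|</3|\\o/|[xX][dD])$"
)
_PUNCT_RE = re.compile(r"[^\w']+")


class CorpusParseError(ValueError):
    """Raised for malformed tweet records; carries the offending line number."""


@dataclass(frozen=True)
class Tweet:
    """A single microblog post.

    ``local_hour`` is filled by :func:`localize_timestamps`: bins are labeled
    1..24 where bin ``h`` covers local clock hour ``h:00-h:59`` and bin 24
    covers 00:00-00:59 (midnight reported as "2400").
    """

    id: str
    user: str
    text: str
    timestamp_utc: datetime
    city: Optional[str] = None
    lat: Optional[float] = None
    lon: Optional[float] = None
    label: Optional[str] = None
    truth: Optional[dict] = None
    local_hour: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if self.label is not None and self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclass
class Corpus:
    """Ordered tweet collection with provenance ``raw``/``reduced``/``synthetic``."""

    tweets: list[Tweet] = field(default_factory=list)
    query_term: str = ""
    provenance: str = "raw"

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self) -> Iterator[Tweet]:
        return iter(self.tweets)

    def __getitem__(self, i):
        return self.tweets[i]


def load_stopwords() -> frozenset[str]:
    text = resources.files("painstream.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


DEFAULT_STOPWORDS: frozenset[str] = load_stopwords()


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(str(raw).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _tweet_from_record(rec: Mapping, lineno: int) -> Tweet:
    for key in ("id", "user", "text", "timestamp_utc"):
        if key not in rec or rec[key] in (None, ""):
            raise CorpusParseError(f"line {lineno}: record missing required field {key!r}")
    try:
        ts = _parse_timestamp(rec["timestamp_utc"])
    except ValueError as exc:
        raise CorpusParseError(f"line {lineno}: bad timestamp {rec['timestamp_utc']!r}: {exc}")

    def _num(key):
        val = rec.get(key)
        if val in (None, ""):
            return None
        return float(val)

    try:
        return Tweet(
            id=str(rec["id"]),
            user=str(rec["user"]),
            text=str(rec["text"]),
            timestamp_utc=ts,
            city=rec.get("city") or None,
            lat=_num("lat"),
            lon=_num("lon"),
            label=rec.get("label") or None,
        )
    except ValueError as exc:
        raise CorpusParseError(f"line {lineno}: {exc}")


def parse_tweets(path: str | Path, query_term: str = "") -> Corpus:
    """Read a corpus from a JSON-lines (``.jsonl``/``.json``) or CSV file.

    Each record needs ``id``, ``user``, ``text`` and an ISO-8601
    ``timestamp_utc``; optional keys are ``city``, ``lat``, ``lon``, ``label``.
    Raises :class:`CorpusParseError` naming the line of the first malformed
    record, and on duplicate tweet ids.
    """
    path = Path(path)
    tweets: list[Tweet] = []
    seen: set[str] = set()
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):  # header is line 1
                tweets.append(_tweet_from_record(rec, lineno))
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(f"line {lineno}: invalid JSON: {exc}")
                tweets.append(_tweet_from_record(rec, lineno))
    for tw in tweets:
        if tw.id in seen:
            raise CorpusParseError(f"duplicate tweet id {tw.id!r}")
        seen.add(tw.id)
    return Corpus(tweets=tweets, query_term=query_term, provenance="raw")


def write_tweets(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON-lines (UTF-8, one object per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for tw in corpus:
            rec = {
                "id": tw.id,
                "user": tw.user,
                "text": tw.text,
                "timestamp_utc": tw.timestamp_utc.isoformat().replace("+00:00", "Z"),
                "city": tw.city,
                "lat": tw.lat,
                "lon": tw.lon,
                "label": tw.label,
            }
            fh.write(json.dumps({k: v for k, v in rec.items() if v is not None}) + "\n")


def _dedup_key(text: str) -> str:
    return " ".join(text.casefold().split())


def deduplicate(corpus: Corpus) -> Corpus:
    """Drop repeated tweets, keeping first occurrences (the *reduced* corpus).

    Two tweets are duplicates when their case-folded, whitespace-collapsed
    texts are identical.
    """
    seen: set[str] = set()
    kept: list[Tweet] = []
    for tw in corpus:
        key = _dedup_key(tw.text)
        if key not in seen:
            seen.add(key)
            kept.append(tw)
    return Corpus(tweets=kept, query_term=corpus.query_term, provenance="reduced")


def is_emoticon(token: str) -> bool:
    return bool(_EMOTICON_RE.match(token))


def tokenize(
    text: str,
    query_term: str = "",
    *,
    keep_query: bool = False,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> list[str]:
    """Tokenize raw tweet text into a lowercase token stream.

    ``keep_query=True`` retains the query term (wanted for sentiment scoring,
    where the lexicon may weight it); the default drops it, matching its
    exclusion from graph statistics.
    """
    text = text.replace("’", "'")
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    query = query_term.lower()
    tokens: list[str] = []
    for raw in text.split():
        if _EMOTICON_RE.match(raw):
            tokens.append(raw)
            continue
        tok = raw.lower()
        if tok.startswith("#"):
            tok = tok.lstrip("#")
        tok = _PUNCT_RE.sub("", tok).strip("'_")
        if not tok or tok in stopwords:
            continue
        if not keep_query and query and tok == query:
            continue
        tokens.append(tok)
    return tokens


def tokenize_corpus(
    corpus: Corpus,
    *,
    keep_query: bool = False,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> list[list[str]]:
    """Token stream for every tweet, in corpus order."""
    return [
        tokenize(tw.text, corpus.query_term, keep_query=keep_query, stopwords=stopwords)
        for tw in corpus
    ]


def hour_bin(local_hour_0_23: int) -> int:
    """Map a 0-23 clock hour to the 1..24 bin labeling (midnight -> 24)."""
    return 24 if local_hour_0_23 == 0 else local_hour_0_23


def localize_timestamps(corpus: Corpus, offsets: Mapping[str, float]) -> Corpus:
    """Annotate each tweet with its local hour bin from a city->UTC-offset map.

    Offsets are fixed hours (no DST). Raises ``KeyError`` listing every city
    absent from the map.
    """
    cities = {tw.city for tw in corpus}
    missing = sorted(c for c in cities if c not in offsets)
    if missing:
        raise KeyError(f"no UTC offset configured for cities: {', '.join(map(str, missing))}")
    localized = []
    for tw in corpus:
        local = tw.timestamp_utc + timedelta(hours=offsets[tw.city])
        localized.append(replace(tw, local_hour=hour_bin(local.hour)))
    return Corpus(tweets=localized, query_term=corpus.query_term, provenance=corpus.provenance)
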