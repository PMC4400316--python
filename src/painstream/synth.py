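"""Synthetic tweet-corpus and mention-network generator with ground truth.

The original pain-tweet corpora were collected live from the Twitter search
API and never deposited, so every downstream stage here is exercised on
synthetic corpora whose generating process is fully known.  The generator
plants, per tweet: the query term, a sentiment marker drawn from a small
positive or negative lexicon sample, topic words drawn from one of several
disjoint word communities, a city and a local posting hour; and, for mention
corpora, a directed retweet/mention edge list with controllable topology
(broadcaster star, chain, planted-partition blocks).  All randomness flows
from a single integer seed; two runs with equal config are byte-identical.

Defaults mirror the study conditions the analyses assume: 1500 tweets per
search (the API cap used for every city/term search), a positive-sentiment
rate of 0.3 (the observed median across cities was about 29%), and a uniform
hour profile.  No attempt is made at linguistic realism — only the
statistical structure the analyses consume.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from random import Random
from typing import Optional, Sequence

from .corpus import Corpus, Tweet

__all__ = [
    "CityConfig",
    "NetworkConfig",
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_mention_corpus",
    "generate_timeline_corpus",
    "city_offsets",
    "POSITIVE_MARKERS",
    "NEGATIVE_MARKERS",
    "DEFAULT_TOPIC_COMMUNITIES",
]

# Sentiment markers are a sample of strongly weighted lexicon terms (|w| >= 3
# on the positive side so a planted marker always dominates the query term's
# own negative lexicon weight in the rule score).
POSITIVE_MARKERS = (
    "love", "happy", "great", "good", "awesome",
    "amazing", "wonderful", "excited", "lol", "glad",
)
NEGATIVE_MARKERS = (
    "sad", "hurt", "awful", "terrible", "hate",
    "crying", "worst", "angry", "sick", "miserable",
)

# Disjoint topic word communities; none of these words appear in the packaged
# lexicon or stopword list, so planted token counts survive tokenization.
DEFAULT_TOPIC_COMMUNITIES = (
    ("gym", "workout", "exercise", "muscle", "cardio", "sweat", "marathon", "miles"),
    ("doctor", "hospital", "medicine", "knee", "surgery", "recovery", "clinic", "nurse"),
    ("friend", "family", "weekend", "party", "dinner", "movie", "concert", "holiday"),
)

_FILLERS = (
    "morning", "coffee", "work", "school", "game", "music", "video", "weather",
    "road", "phone", "meeting", "tomorrow", "night", "bus", "train", "book",
    "rain", "window", "street", "kitchen", "garden", "chair",
)


@dataclass(frozen=True)
class CityConfig:
    name: str
    utc_offset: float = 0.0
    p_positive_offset: float = 0.0
    weight: float = 1.0
    lat: Optional[float] = None
    lon: Optional[float] = None


DEFAULT_CITIES = (
    CityConfig("new york", -5, lat=40.7, lon=-74.0),
    CityConfig("los angeles", -8, lat=34.1, lon=-118.2),
    CityConfig("london", 0, lat=51.5, lon=-0.1),
    CityConfig("sydney", 10, lat=-33.9, lon=151.2),
    CityConfig("manila", 8, lat=14.6, lon=121.0),
)


@dataclass(frozen=True)
class NetworkConfig:
    """Topology of the planted mention/retweet edge list."""

    topology: str = "none"  # star | chain | planted_partition | none
    n_users: int = 50
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    p_retweet: float = 0.7  # fraction of edge tweets using the "RT @x" form
    n_plain: int = 0  # additional mention-free tweets


@dataclass(frozen=True)
class GeneratorConfig:
    n_tweets: int = 1500
    query_term: str = "pain"
    p_positive: float = 0.3
    topic_communities: Sequence[Sequence[str]] = DEFAULT_TOPIC_COMMUNITIES
    words_per_tweet: tuple[int, int] = (6, 12)
    cities: Sequence[CityConfig] = DEFAULT_CITIES
    hour_profile: Optional[Sequence[float]] = None  # 24 weights, bins 1..24
    negation_rate: float = 0.0
    n_authors: int = 50
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must be in [0, 1]")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise ValueError("negation_rate must be in [0, 1]")
        if not self.topic_communities or not any(self.topic_communities):
            raise ValueError("at least one nonempty topic community is required")
        seen: set[str] = set()
        for comm in self.topic_communities:
            overlap = seen.intersection(comm)
            if overlap:
                raise ValueError(f"topic communities must be disjoint; shared: {sorted(overlap)}")
            seen.update(comm)
        if self.hour_profile is not None:
            if len(self.hour_profile) != 24:
                raise ValueError("hour_profile must have 24 weights")
            if any(w < 0 for w in self.hour_profile):
                raise ValueError("hour_profile weights must be nonnegative")
        if self.words_per_tweet[0] < 3 or self.words_per_tweet[1] < self.words_per_tweet[0]:
            raise ValueError("words_per_tweet must be an increasing range with minimum >= 3")


@dataclass
class GroundTruth:
    """Exhaustive generator bookkeeping for the emitted corpus."""

    tweet_polarity: dict[str, str] = field(default_factory=dict)
    term_community: dict[str, int] = field(default_factory=dict)
    user_block: dict[str, int] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)
    token_counts: Counter = field(default_factory=Counter)
    user_tweet_counts: Counter = field(default_factory=Counter)
    mention_tweet_ids: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        payload = {
            "tweet_polarity": self.tweet_polarity,
            "term_community": self.term_community,
            "user_block": self.user_block,
            "edges": [list(e) for e in self.edges],
            "token_counts": dict(self.token_counts),
            "user_tweet_counts": dict(self.user_tweet_counts),
            "mention_tweet_ids": self.mention_tweet_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), "utf-8")


def _offsets(cities: Sequence[CityConfig]) -> dict[str, float]:
    return {c.name: c.utc_offset for c in cities}


def city_offsets(config: GeneratorConfig) -> dict[str, float]:
    """City -> UTC offset map for :func:`painstream.corpus.localize_timestamps`."""
    return _offsets(config.cities)


def _draw_hour(rng: Random, profile: Optional[Sequence[float]]) -> int:
    """Local clock hour 0..23; profile index i weights bin i+1 (bin 24 = hour 0)."""
    if profile is None:
        return rng.randrange(24)
    bin_label = rng.choices(range(1, 25), weights=list(profile))[0]
    return 0 if bin_label == 24 else bin_label


def _timestamp(rng: Random, local_hour: int, offset: float, year: int, month: int) -> datetime:
    local = datetime(year, month, rng.randint(1, 28), local_hour, rng.randrange(60),
                     rng.randrange(60))
    return (local - timedelta(hours=offset)).replace(tzinfo=timezone.utc)


def _assemble_tokens(
    rng: Random,
    config: GeneratorConfig,
    truth: GroundTruth,
    p_positive: Optional[float] = None,
) -> tuple[list[str], str, int]:
    """Draw one tweet's tokens; returns (tokens, final_polarity, topic_id)."""
    p = config.p_positive if p_positive is None else p_positive
    positive = rng.random() < min(1.0, max(0.0, p))
    negated = positive and rng.random() < config.negation_rate
    if negated:
        markers = [rng.choice(POSITIVE_MARKERS)]
        polarity = "negative"
    else:
        pool = POSITIVE_MARKERS if positive else NEGATIVE_MARKERS
        markers = rng.sample(pool, rng.randint(1, 2))
        polarity = "positive" if positive else "negative"

    topic_id = rng.randrange(len(config.topic_communities))
    comm = list(config.topic_communities[topic_id])
    topic_tokens = rng.sample(comm, min(len(comm), rng.randint(2, 3)))

    target_len = rng.randint(*config.words_per_tweet)
    n_fill = max(0, target_len - 1 - len(markers) - len(topic_tokens) - (1 if negated else 0))
    fillers = [rng.choice(_FILLERS) for _ in range(n_fill)]

    if negated:
        # Keep the negated marker at the end, "not" 1-4 tokens before it with
        # only lexicon-free tokens between, so no other weighted token falls
        # inside the negation window and ground truth stays exact.
        gap = min(rng.randint(0, 3), len(fillers))
        between, fillers = fillers[:gap], fillers[gap:]
        body = [config.query_term] + topic_tokens + fillers
        rng.shuffle(body)
        tokens = body + ["not"] + between + markers
    else:
        tokens = [config.query_term] + markers + topic_tokens + fillers
        rng.shuffle(tokens)

    for tok in tokens:
        if tok != config.query_term:
            truth.token_counts[tok] += 1
    return tokens, polarity, topic_id


def _record_term_communities(config: GeneratorConfig, truth: GroundTruth) -> None:
    for cid, comm in enumerate(config.topic_communities):
        for term in comm:
            truth.term_community[term] = cid


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a plain (mention-free) tweet corpus with ground truth.

    Every tweet contains the query term; its truth polarity, topic community,
    city and local posting hour are recorded in the returned
    :class:`GroundTruth` (token counts are for the post-tokenization view:
    query term excluded, negator ``not`` included).
    """
    config.validate()
    rng = Random(config.seed)
    truth = GroundTruth()
    _record_term_communities(config, truth)
    cities = list(config.cities)
    weights = [c.weight for c in cities]
    tweets: list[Tweet] = []
    for i in range(config.n_tweets):
        city = rng.choices(cities, weights=weights)[0]
        local_hour = _draw_hour(rng, config.hour_profile)
        # Per-city offsets shift the positive rate around the global mixture.
        eff = min(1.0, max(0.0, config.p_positive + city.p_positive_offset))
        tokens, polarity, topic_id = _assemble_tokens(rng, config, truth, p_positive=eff)
        user = f"u{rng.randrange(config.n_authors):04d}"
        tid = f"t{i:06d}"
        tweets.append(
            Tweet(
                id=tid,
                user=user,
                text=" ".join(tokens),
                timestamp_utc=_timestamp(rng, local_hour, city.utc_offset, 2012, 9),
                city=city.name,
                lat=city.lat,
                lon=city.lon,
                label=polarity,
                truth={"polarity": polarity, "topic": topic_id,
                       "hour_bin": 24 if local_hour == 0 else local_hour},
            )
        )
        truth.tweet_polarity[tid] = polarity
        truth.user_tweet_counts[user] += 1
    return Corpus(tweets=tweets, query_term=config.query_term, provenance="synthetic"), truth


def _planted_edges(rng: Random, net: NetworkConfig, users: list[str],
                   truth: GroundTruth) -> list[tuple[str, str]]:
    n = len(users)
    edges: list[tuple[str, str]] = []
    if net.topology == "star":
        hub = users[0]
        edges = [(u, hub) for u in users[1:]]
        truth.user_block.update({u: 0 for u in users})
    elif net.topology == "chain":
        edges = [(users[i], users[i + 1]) for i in range(n - 1)]
        truth.user_block.update({u: 0 for u in users})
    elif net.topology == "planted_partition":
        if net.p_in <= net.p_out:
            warnings.warn("p_in <= p_out: planted communities are unrecoverable")
        block_size = max(1, n // net.n_blocks)
        for idx, u in enumerate(users):
            truth.user_block[u] = min(idx // block_size, net.n_blocks - 1)
        for i in range(n):
            for j in range(i + 1, n):
                same = truth.user_block[users[i]] == truth.user_block[users[j]]
                if rng.random() < (net.p_in if same else net.p_out):
                    if rng.random() < 0.5:
                        edges.append((users[i], users[j]))
                    else:
                        edges.append((users[j], users[i]))
    else:
        raise ValueError(f"unsupported topology {net.topology!r}")
    return edges


def generate_mention_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus whose tweets realize a planted directed mention list.

    Each planted edge (src, dst) appears in exactly one tweet authored by
    ``src`` whose text opens with ``RT @dst`` (retweet form) or ``@dst``
    (plain mention); ``network.n_plain`` extra mention-free tweets pad the
    corpus for involvement statistics and timeline pools.
    """
    config.validate()
    if config.network.topology == "none":
        raise ValueError("generate_mention_corpus requires a network topology")
    rng = Random(config.seed)
    truth = GroundTruth()
    _record_term_communities(config, truth)
    net = config.network
    users = [f"u{i:04d}" for i in range(net.n_users)]
    edges = _planted_edges(rng, net, users, truth)
    truth.edges = list(edges)

    tweets: list[Tweet] = []
    cities = list(config.cities)
    weights = [c.weight for c in cities]

    def _emit(idx: int, user: str, prefix: str, is_mention: bool) -> None:
        city = rng.choices(cities, weights=weights)[0]
        local_hour = _draw_hour(rng, config.hour_profile)
        tokens, polarity, topic_id = _assemble_tokens(rng, config, truth)
        text = (prefix + " " if prefix else "") + " ".join(tokens)
        tid = f"m{idx:06d}"
        tweets.append(
            Tweet(
                id=tid, user=user, text=text,
                timestamp_utc=_timestamp(rng, local_hour, city.utc_offset, 2013, 3),
                city=city.name, lat=city.lat, lon=city.lon, label=polarity,
                truth={"polarity": polarity, "topic": topic_id, "mention": is_mention},
            )
        )
        truth.tweet_polarity[tid] = polarity
        truth.user_tweet_counts[user] += 1
        if is_mention:
            truth.mention_tweet_ids.append(tid)

    for k, (src, dst) in enumerate(edges):
        form = f"RT @{dst}" if rng.random() < net.p_retweet else f"@{dst}"
        _emit(k, src, form, True)
    for k in range(net.n_plain):
        _emit(len(edges) + k, rng.choice(users), "", False)
    return Corpus(tweets=tweets, query_term=config.query_term, provenance="synthetic"), truth


def generate_timeline_corpus(
    term_counts: dict[str, int],
    n_tweets: int,
    n_users: int = 100,
    seed: int = 0,
) -> Corpus:
    """Emulate a sampled-user timeline pool with exact planted term counts.

    Each term in ``term_counts`` appears as a whole token exactly that many
    times across the corpus (occurrences spread over random tweets); all other
    tokens are neutral fillers.  Used to exercise term-frequency reporting
    against known counts.
    """
    rng = Random(seed)
    if n_tweets < 1:
        raise ValueError("n_tweets must be >= 1")
    total = sum(term_counts.values())
    if total > 0 and n_tweets < 1:
        raise ValueError("corpus too small for requested term counts")
    fillers = [w for w in _FILLERS if w not in term_counts]
    slots: list[list[str]] = [[] for _ in range(n_tweets)]
    for term, count in term_counts.items():
        if count < 0:
            raise ValueError("term counts must be nonnegative")
        for _ in range(count):
            slots[rng.randrange(n_tweets)].append(term)
    tweets = []
    for i, planted in enumerate(slots):
        tokens = planted + [rng.choice(fillers) for _ in range(rng.randint(3, 8))]
        rng.shuffle(tokens)
        tweets.append(
            Tweet(
                id=f"tl{i:06d}",
                user=f"u{rng.randrange(n_users):04d}",
                text=" ".join(tokens),
                timestamp_utc=_timestamp(rng, rng.randrange(24), 0.0, 2013, 3),
            )
        )
    return Corpus(tweets=tweets, query_term="", provenance="synthetic")
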