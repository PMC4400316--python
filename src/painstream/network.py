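"""Directed mention/retweet network extraction and topology metrics.

A mention network has one node per user handle and a directed edge from the
tweet's author to every distinct user mentioned in it ("RT @x" retweets and
bare "@x" mentions are merged into a single edge type; a flag restricts to
retweets).  Parallel mentions accumulate as edge weights; self-mentions are
dropped.

The metric battery mirrors standard social-network reporting: node and edge
counts, diameter and average path length (computed undirected on the largest
weakly connected component, the only convention that yields finite values on
fragmented graphs), density of the simple directed graph, weak/strong
component counts, giant-component fraction, and Louvain modularity community
count on the undirected weighted projection — plus the per-node ratios
(components per node, communities per node) used to contrast fragmented
"emotion-term" networks against broadcast-style "objective-term" cascades.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .corpus import Corpus, Tweet
from .termgraph import louvain_communities

__all__ = [
    "MentionNetwork",
    "NetworkMetrics",
    "ComparisonResult",
    "TermFrequencyReport",
    "extract_mention_edges",
    "build_network",
    "network_metrics",
    "degree_stats",
    "compare_networks",
    "sample_user_timelines",
    "term_frequency_report",
    "involvement_report",
]

_MENTION_RE = re.compile(r"@(\w+)")
_RT_RE = re.compile(r"(?:^|\s)RT\s+@(\w+)", re.IGNORECASE)


@dataclass
class MentionNetwork:
    """Directed user graph; edge weight = mention multiplicity."""

    g: nx.DiGraph = field(default_factory=nx.DiGraph)
    query_term: str = ""

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def to_graphml(self, path: str | Path) -> None:
        g = self.g.copy()
        for n in g.nodes:
            g.nodes[n]["in_degree"] = g.in_degree(n)
            g.nodes[n]["out_degree"] = g.out_degree(n)
            g.nodes[n]["total_degree"] = g.in_degree(n) + g.out_degree(n)
        nx.write_graphml(g, str(path))

    def to_gexf(self, path: str | Path) -> None:
        nx.write_gexf(self.g, str(path))


def extract_mention_edges(
    corpus: Corpus, *, retweets_only: bool = False
) -> list[tuple[str, str]]:
    """Directed (author -> mentioned user) edges, one per distinct handle per tweet."""
    edges: list[tuple[str, str]] = []
    for tw in corpus:
        if retweets_only:
            handles = list(dict.fromkeys(_RT_RE.findall(tw.text)))
        else:
            handles = list(dict.fromkeys(_MENTION_RE.findall(tw.text)))
        for h in handles:
            if h != tw.user:
                edges.append((tw.user, h))
    return edges


def build_network(edges: Sequence[tuple[str, str]], query_term: str = "") -> MentionNetwork:
    """Accumulate a directed edge list into a weighted mention network."""
    g = nx.DiGraph()
    for src, dst in edges:
        if src == dst:
            continue
        if g.has_edge(src, dst):
            g[src][dst]["weight"] += 1
        else:
            g.add_edge(src, dst, weight=1)
    return MentionNetwork(g=g, query_term=query_term)


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    diameter: int
    avg_path_length: float
    density: float
    n_wcc: int
    n_scc: int
    giant_fraction: float
    n_modularity_communities: int
    wcc_per_node: float
    communities_per_node: float


def network_metrics(net: MentionNetwork, seed: int = 0) -> NetworkMetrics:
    """Full network-level metric battery (see module docstring for conventions)."""
    g = net.g
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot compute metrics of an empty network")
    und = g.to_undirected(as_view=False)
    wccs = list(nx.connected_components(und))
    giant = max(wccs, key=len)
    giant_und = und.subgraph(giant)
    if len(giant) > 1:
        diameter = nx.diameter(giant_und)
        apl = nx.average_shortest_path_length(giant_und)
    else:
        diameter, apl = 0, 0.0
    density = g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    part = louvain_communities(und, seed=seed)
    return NetworkMetrics(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        diameter=diameter,
        avg_path_length=apl,
        density=density,
        n_wcc=len(wccs),
        n_scc=nx.number_strongly_connected_components(g),
        giant_fraction=len(giant) / n,
        n_modularity_communities=part.n_communities,
        wcc_per_node=len(wccs) / n,
        communities_per_node=part.n_communities / n,
    )


def degree_stats(net: MentionNetwork) -> dict:
    """Per-node in/out/total degrees on the simple digraph plus max/median rows."""
    g = net.g
    per_node = {
        u: {"in": g.in_degree(u), "out": g.out_degree(u),
            "total": g.in_degree(u) + g.out_degree(u)}
        for u in g.nodes
    }
    summary = {}
    for key in ("in", "out", "total"):
        vals = [d[key] for d in per_node.values()] or [0]
        summary[key] = {"max": int(max(vals)), "median": float(np.median(vals))}
    return {"per_node": per_node, "summary": summary}


@dataclass(frozen=True)
class ComparisonResult:
    mean_difference: float
    u_statistic: float
    p: float
    effect_size: float  # |Z| / sqrt(N) for the rank test
    test: str = "mann_whitney_u"


def _mwu_z(a: np.ndarray, b: np.ndarray, u: float) -> float:
    """Tie-corrected normal Z for the Mann-Whitney U statistic."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return 0.0
    return (u - n1 * n2 / 2.0) / np.sqrt(var)


def compare_networks(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    test: str = "mann_whitney_u",
) -> ComparisonResult:
    """Compare two degree-score vectors (e.g. in-degrees of two networks).

    Default is a two-sided Mann-Whitney U rank test (exact for small tie-free
    samples, normal approximation with tie correction otherwise) with
    effect size |Z|/sqrt(n_a + n_b); a Welch t-test is available via
    ``test="welch_t"``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both score vectors must be nonempty")
    mean_diff = float(a.mean() - b.mean())
    if test == "welch_t":
        t, p = stats.ttest_ind(a, b, equal_var=False)
        n = len(a) + len(b)
        return ComparisonResult(mean_difference=mean_diff, u_statistic=float(t),
                                p=float(p), effect_size=abs(float(t)) / np.sqrt(n),
                                test="welch_t")
    if test != "mann_whitney_u":
        raise ValueError(f"unknown test {test!r}")
    if np.ptp(np.concatenate([a, b])) == 0:
        # fully tied: no evidence of any difference
        u = len(a) * len(b) / 2.0
        return ComparisonResult(mean_difference=mean_diff, u_statistic=u, p=1.0,
                                effect_size=0.0)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    z = _mwu_z(a, b, float(res.statistic))
    effect = abs(z) / np.sqrt(len(a) + len(b))
    return ComparisonResult(mean_difference=mean_diff, u_statistic=float(res.statistic),
                            p=float(res.pvalue), effect_size=float(effect))


def sample_user_timelines(
    net: MentionNetwork,
    corpus: Corpus,
    pool: Corpus,
    n_users: int = 100,
    per_user: int = 100,
    seed: int = 0,
) -> Corpus:
    """Sample users from the mention network and collect their recent tweets.

    Eligible users authored at least one edge-bearing tweet in ``corpus``
    containing the query term; ``n_users`` are drawn uniformly without
    replacement (all of them if fewer exist), then for each the up-to-
    ``per_user`` most recent tweets in ``pool`` are kept (recency ties broken
    by id, descending).
    """
    query = net.query_term.lower()
    eligible = set()
    for tw in corpus:
        if tw.user not in net.g.nodes:
            continue
        mentions = [h for h in _MENTION_RE.findall(tw.text) if h != tw.user]
        if not mentions:
            continue
        if not query or query in (t.lower() for t in re.findall(r"[\w']+", tw.text)):
            eligible.add(tw.user)
    if not eligible:
        raise ValueError("no eligible users: none authored an edge-bearing query tweet")
    rng = Random(seed)
    ordered = sorted(eligible)
    chosen = set(rng.sample(ordered, min(n_users, len(ordered))))
    by_user: dict[str, list[Tweet]] = {}
    for tw in pool:
        if tw.user in chosen:
            by_user.setdefault(tw.user, []).append(tw)
    sampled: list[Tweet] = []
    for user in sorted(by_user):
        tws = sorted(by_user[user], key=lambda t: (t.timestamp_utc, t.id), reverse=True)
        sampled.extend(tws[:per_user])
    return Corpus(tweets=sampled, query_term=net.query_term, provenance=pool.provenance)


@dataclass
class TermFrequencyReport:
    """Whole-token term counts with rates relative to a reference term."""

    rows: list[dict]  # term, frequency, proportion_to_reference (2 dp)
    reference_term: str
    n_tweets: int


def _token_count(texts: Sequence[str], term: str) -> int:
    pattern = re.compile(r"(?<![\w'])" + re.escape(term.lower()) + r"(?![\w'])")
    return sum(len(pattern.findall(t.lower())) for t in texts)


def term_frequency_report(
    corpus: Corpus,
    terms: Sequence[str],
    reference_term: str,
) -> TermFrequencyReport:
    """Count whole-token occurrences of each term across all tweet texts.

    Substring hits do not count (``pains`` is not ``pain``). Proportions are
    frequency / reference frequency, rounded to 2 decimals.
    """
    texts = [tw.text for tw in corpus]
    ref = _token_count(texts, reference_term)
    if ref == 0:
        raise ValueError(f"reference term {reference_term!r} absent from corpus")
    rows = []
    for term in terms:
        freq = _token_count(texts, term)
        rows.append({"term": term, "frequency": freq,
                     "proportion_to_reference": round(freq / ref, 2)})
    return TermFrequencyReport(rows=rows, reference_term=reference_term,
                               n_tweets=len(corpus))


def involvement_report(corpora: Sequence[Corpus]) -> tuple[float, int, int]:
    """Percent of tweets (across all corpora) contributing a mention edge.

    Returns (percent rounded to 2 decimals, n_involved, n_total).
    """
    n_total = 0
    n_involved = 0
    for corpus in corpora:
        for tw in corpus:
            n_total += 1
            if any(h != tw.user for h in _MENTION_RE.findall(tw.text)):
                n_involved += 1
    if n_total == 0:
        raise ValueError("no tweets supplied")
    return round(100.0 * n_involved / n_total, 2), n_involved, n_total
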