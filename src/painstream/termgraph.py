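"""Term co-occurrence graph and modularity community detection.

Two terms share an undirected edge whenever they occur in the same tweet;
each tweet contributes at most 1 to an edge's weight regardless of token
repetition (set semantics — in 140-character posts multiplicity is noise).
Degree centrality is reported as the count of distinct neighbors, matching
how term "links" are counted for ranking; weighted degree is available
separately.

Community detection is a from-scratch implementation of the Louvain method:
greedy local moves maximizing the modularity gain, followed by community
aggregation, repeated until no move improves Q by more than a tolerance.
Modularity is the standard weighted Newman-Girvan quality

    Q = sum_c [ w_in(c)/W - gamma * (s(c) / 2W)^2 ]

with W the total edge weight, w_in(c) the intra-community edge weight,
s(c) the summed weighted degrees, and gamma a resolution parameter
(default 1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "TermGraph",
    "CommunityPartition",
    "build_cooccurrence_graph",
    "top_terms",
    "top_edges",
    "modularity",
    "louvain_communities",
    "community_size_report",
    "community_sizes",
]


@dataclass
class TermGraph:
    """Weighted undirected term graph backed by a :class:`networkx.Graph`."""

    g: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self):
        return self.g.nodes

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def weight(self, u, v) -> int:
        return self.g[u][v]["weight"]

    def degree(self, term) -> int:
        """Distinct-neighbor count (unweighted degree centrality)."""
        return self.g.degree(term)

    def weighted_degree(self, term) -> float:
        return self.g.degree(term, weight="weight")

    def to_graphml(self, path: str | Path,
                   partition: "CommunityPartition | None" = None) -> None:
        g = self.g.copy()
        for n in g.nodes:
            g.nodes[n]["degree_centrality"] = self.degree(n)
            if partition is not None:
                g.nodes[n]["community"] = int(partition.assignment[n])
        nx.write_graphml(g, str(path))


@dataclass
class CommunityPartition:
    assignment: dict
    q: float
    n_communities: int
    q_history: list[float] = field(default_factory=list)  # Q after each level

    def communities(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return out


def build_cooccurrence_graph(token_streams: Iterable[Sequence[str]]) -> TermGraph:
    """Accumulate per-tweet co-occurrence into an edge-weighted term graph.

    ``token_streams`` is one token list per tweet (query term already
    excluded by the tokenizer). Every unordered pair of distinct tokens in a
    tweet adds 1 to that pair's edge weight, once per tweet.
    """
    g = nx.Graph()
    for tokens in token_streams:
        uniq = sorted(set(tokens))
        g.add_nodes_from(uniq)
        for i, a in enumerate(uniq):
            for b in uniq[i + 1:]:
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
    return TermGraph(g)


def top_terms(graph: TermGraph, k: int, *, weighted: bool = False) -> list[tuple[str, float]]:
    """Top-k terms by degree centrality, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    key = graph.weighted_degree if weighted else graph.degree
    ranked = sorted(graph.nodes, key=lambda t: (-key(t), t))
    return [(t, key(t)) for t in ranked[:k]]


def top_edges(graph: TermGraph, k: int) -> list[tuple[str, str, int]]:
    """Top-k edges by weight, ties broken lexicographically on (term1, term2)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = [tuple(sorted((u, v))) + (d["weight"],) for u, v, d in graph.g.edges(data=True)]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    return edges[:k]


def _adjacency(graph) -> dict:
    """Adjacency dict {node: {nbr: weight}} from TermGraph or networkx graph."""
    g = graph.g if isinstance(graph, TermGraph) else graph
    if g.is_directed():
        g = g.to_undirected(as_view=False)
    adj: dict = {n: {} for n in g.nodes}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        if u == v:
            adj[u][u] = adj[u].get(u, 0.0) + w
        else:
            adj[u][v] = adj[u].get(v, 0.0) + w
            adj[v][u] = adj[v].get(u, 0.0) + w
    return adj


def _degrees(adj: Mapping) -> dict:
    # A self-loop of weight w contributes 2w to its node's weighted degree.
    return {
        n: sum(w for m, w in nbrs.items() if m != n) + 2.0 * nbrs.get(n, 0.0)
        for n, nbrs in adj.items()
    }


def modularity(graph, assignment: Mapping[Hashable, int], resolution: float = 1.0) -> float:
    """Evaluate weighted modularity Q of a node->community assignment."""
    adj = _adjacency(graph)
    missing = [n for n in adj if n not in assignment]
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(map(str, missing))[:5]}")
    deg = _degrees(adj)
    two_w = sum(deg.values())
    if two_w == 0:
        return 0.0
    w_in: dict = {}
    s_tot: dict = {}
    for n, nbrs in adj.items():
        c = assignment[n]
        s_tot[c] = s_tot.get(c, 0.0) + deg[n]
        for m, w in nbrs.items():
            if m == n:
                w_in[c] = w_in.get(c, 0.0) + w
            elif assignment[m] == c:
                w_in[c] = w_in.get(c, 0.0) + w / 2.0  # each intra edge seen twice
    total_w = two_w / 2.0
    q = 0.0
    for c in s_tot:
        q += w_in.get(c, 0.0) / total_w - resolution * (s_tot[c] / two_w) ** 2
    return q


def _one_level(adj: dict, rng: Random, resolution: float, tol: float) -> tuple[dict, bool]:
    """One Louvain local-move phase; returns (node->community, improved?)."""
    deg = _degrees(adj)
    two_w = sum(deg.values())
    node2com = {n: i for i, n in enumerate(adj)}
    if two_w == 0:  # edgeless graph: everyone stays a singleton
        return node2com, False
    com_tot = {node2com[n]: deg[n] for n in adj}
    improved = False
    nodes = list(adj)
    moved = True
    while moved:
        moved = False
        rng.shuffle(nodes)
        for n in nodes:
            c_old = node2com[n]
            # weight from n to each neighboring community (self-loops excluded)
            links: dict = {}
            for m, w in adj[n].items():
                if m != n:
                    links[node2com[m]] = links.get(node2com[m], 0.0) + w
            com_tot[c_old] -= deg[n]
            k_in_old = links.get(c_old, 0.0)
            best_c, best_gain = c_old, 0.0
            for c, k_in in links.items():
                if c == c_old:
                    continue
                # gain of moving n from (removed) to c, in units of Q:
                gain = (k_in - k_in_old) / (two_w / 2.0) \
                    - resolution * deg[n] * (com_tot[c] - com_tot[c_old]) / (2.0 * (two_w / 2.0) ** 2)
                if gain > best_gain + tol:
                    best_c, best_gain = c, gain
            node2com[n] = best_c
            com_tot[best_c] = com_tot.get(best_c, 0.0) + deg[n]
            if best_c != c_old:
                improved = True
                moved = True
    return node2com, improved


def _aggregate(adj: dict, node2com: Mapping) -> dict:
    new_adj: dict = {}
    for n, nbrs in adj.items():
        cn = node2com[n]
        new_adj.setdefault(cn, {})
        for m, w in nbrs.items():
            cm = node2com[m]
            if n == m:
                new_adj[cn][cn] = new_adj[cn].get(cn, 0.0) + w
            elif cn == cm:
                # each intra edge appears twice in the symmetric adjacency
                new_adj[cn][cn] = new_adj[cn].get(cn, 0.0) + w / 2.0
            else:
                new_adj[cn][cm] = new_adj[cn].get(cm, 0.0) + w / 2.0
                new_adj.setdefault(cm, {})
                new_adj[cm][cn] = new_adj[cm].get(cn, 0.0) + w / 2.0
    return new_adj


def louvain_communities(graph, seed: int = 0, resolution: float = 1.0,
                        tol: float = 1e-7) -> CommunityPartition:
    """Detect communities with the (from-scratch) Louvain method.

    Node visit order is shuffled by ``seed``; Q is guaranteed non-decreasing
    across levels (recorded in ``q_history``) and the returned ``q`` is
    recomputed from the final assignment on the input graph.
    """
    adj = _adjacency(graph)
    if not adj:
        raise ValueError("cannot detect communities in an empty graph")
    rng = Random(seed)
    # original node -> current community label
    mapping = {n: n for n in adj}
    current = adj
    q_history: list[float] = []
    q_prev = modularity(graph, {n: i for i, n in enumerate(adj)}, resolution)
    while True:
        node2com, improved = _one_level(current, rng, resolution, tol)
        mapping = {n: node2com[c] for n, c in mapping.items()}
        q_now = modularity(graph, mapping, resolution)
        if q_now < q_prev - 1e-12:
            raise AssertionError("modularity decreased across a Louvain level")
        q_history.append(q_now)
        if not improved or q_now - q_prev <= tol:
            break
        q_prev = q_now
        current = _aggregate(current, node2com)
    labels = sorted(set(mapping.values()), key=str)
    relabel = {c: i for i, c in enumerate(labels)}
    assignment = {n: relabel[c] for n, c in mapping.items()}
    q = modularity(graph, assignment, resolution)
    return CommunityPartition(assignment=assignment, q=q,
                              n_communities=len(labels), q_history=q_history)


def community_sizes(partition: CommunityPartition) -> list[int]:
    return sorted((len(v) for v in partition.communities().values()), reverse=True)


def community_size_report(partition: CommunityPartition, m: int) -> float:
    """Fraction of all terms contained in the m largest communities."""
    if m < 1:
        raise ValueError("m must be >= 1")
    sizes = community_sizes(partition)
    total = sum(sizes)
    return sum(sizes[:m]) / total if total else 0.0


def write_top_terms_csv(graph: TermGraph, k: int, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["term", "degree_centrality"])
        w.writerows(top_terms(graph, k))


def write_top_edges_csv(graph: TermGraph, k: int, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "term1", "term2", "edge_weight"])
        for i, (a, b, wt) in enumerate(top_edges(graph, k), 1):
            w.writerow([i, a, b, wt])
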