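"""Keyword co-occurrence graph and its partition into item testlets.

The co-word graph connects two terms when at least one document contains
both; the edge weight is the number of such documents. Clustering is done
either with a deterministic single-pass leader-following algorithm (FLCA) or
with Louvain modularity optimization for the robustness comparison. In both
cases each cluster's *leader* is its highest-frequency member, and clusters
of keywords are interpreted as thematic units ("item testlets").
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .errors import ParameterError
from .keyword_sources import TermDocMatrix

#: The co-word graph is a plain networkx Graph; node attributes are
#: ``freq`` (document frequency) and ``docs`` (frozenset of document ids),
#: edge attribute ``weight`` is the co-occurrence document count.
CowordGraph = nx.Graph


@dataclass
class ClusterSolution:
    """A term partition with one leader per cluster."""

    membership: dict[str, int]           # term -> cluster id (1-based)
    leaders: dict[int, str]              # cluster id -> leader term
    method: str                          # "flca" or "louvain"
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.leaders)

    def members(self, cid: int) -> list[str]:
        return sorted(t for t, c in self.membership.items() if c == cid)


def build_coword_graph(tdm: TermDocMatrix) -> CowordGraph:
    """Co-occurrence graph over the matrix's terms.

    Edge weight(a, b) = number of documents containing both a and b.
    """
    g = nx.Graph()
    for term in tdm.terms:
        docs = tdm.doc_set(term)
        g.add_node(term, freq=len(docs), docs=docs)
    # invert: document -> terms present, then count pairwise intersections
    doc_terms: dict[str, list[str]] = {}
    for term in tdm.terms:
        for doc in tdm.counts[term]:
            doc_terms.setdefault(doc, []).append(term)
    for terms in doc_terms.values():
        terms = sorted(terms)
        for i, a in enumerate(terms):
            for b in terms[i + 1:]:
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
    return g


def jaccard(graph: CowordGraph, a: str, b: str) -> float:
    """Jaccard similarity of the two terms' co-occurring-document sets."""
    da, db = graph.nodes[a]["docs"], graph.nodes[b]["docs"]
    union = len(da | db)
    return len(da & db) / union if union else 0.0


def _term_order(graph: CowordGraph) -> list[str]:
    return sorted(graph.nodes, key=lambda t: (-graph.nodes[t]["freq"], t))


def _recompute_leaders(graph: CowordGraph, membership: dict[str, int]) -> dict[int, str]:
    leaders: dict[int, str] = {}
    for cid in sorted(set(membership.values())):
        members = [t for t, c in membership.items() if c == cid]
        leaders[cid] = min(members, key=lambda t: (-graph.nodes[t]["freq"], t))
    return leaders


def _renumber(membership: dict[str, int], leaders: dict[int, str]):
    """Compact cluster ids to 1..K preserving founding order."""
    old_ids = sorted(leaders)
    remap = {old: new for new, old in enumerate(old_ids, start=1)}
    return ({t: remap[c] for t, c in membership.items()},
            {remap[c]: l for c, l in leaders.items()})


def flca_cluster(graph: CowordGraph, tau: float = 0.1,
                 target_clusters: Optional[int] = None) -> ClusterSolution:
    """Single-pass leader-following clustering of the co-word graph.

    Terms are visited by descending document frequency (alphabetical
    tie-break). Each term joins the existing cluster whose *leader* is most
    Jaccard-similar to it, provided that similarity reaches ``tau``;
    otherwise it founds a new cluster and becomes its leader. Afterwards
    leaders are recomputed as each cluster's highest-frequency member
    (alphabetical tie-break). Fully deterministic.

    When ``target_clusters`` is given, the smallest clusters are merged into
    the cluster with the most similar leader until exactly that many remain
    (no-op if fewer clusters were found than requested).
    """
    if len(graph) == 0:
        raise ParameterError("empty graph")
    if target_clusters is not None:
        if target_clusters < 1:
            raise ParameterError(f"target_clusters must be >= 1, got {target_clusters}")
        if target_clusters > len(graph):
            raise ParameterError("target_clusters exceeds the number of terms")

    membership: dict[str, int] = {}
    leaders: dict[int, str] = {}
    for term in _term_order(graph):
        best_cid, best_sim = None, -1.0
        for cid in sorted(leaders):
            sim = jaccard(graph, term, leaders[cid])
            if sim > best_sim:
                best_cid, best_sim = cid, sim
        if best_cid is not None and best_sim >= tau:
            membership[term] = best_cid
        else:
            cid = len(leaders) + 1
            leaders[cid] = term
            membership[term] = cid

    leaders = _recompute_leaders(graph, membership)

    if target_clusters is not None:
        while len(leaders) > target_clusters:
            sizes = {c: sum(1 for v in membership.values() if v == c) for c in leaders}
            # smallest cluster; among ties, the latest-founded (largest id)
            small = min(leaders, key=lambda c: (sizes[c], -c))
            others = [c for c in leaders if c != small]
            target = max(others,
                         key=lambda c: (jaccard(graph, leaders[small], leaders[c]), -c))
            for t, c in membership.items():
                if c == small:
                    membership[t] = target
            del leaders[small]
            leaders = _recompute_leaders(graph, membership)
        membership, leaders = _renumber(membership, leaders)

    return ClusterSolution(membership, leaders, "flca",
                           {"tau": tau, "target_clusters": target_clusters})


def louvain_cluster(graph: CowordGraph, seed: int = 0) -> ClusterSolution:
    """Louvain modularity communities on the weighted co-word graph.

    Deterministic for a fixed seed. Communities are numbered 1..K by
    descending size (leader term as tie-break); leaders are computed exactly
    as for FLCA.
    """
    if len(graph) == 0:
        raise ParameterError("empty graph")
    communities = nx.community.louvain_communities(graph, weight="weight", seed=seed)

    def leader_of(comm) -> str:
        return min(comm, key=lambda t: (-graph.nodes[t]["freq"], t))

    ordered = sorted(communities, key=lambda c: (-len(c), leader_of(c)))
    membership: dict[str, int] = {}
    leaders: dict[int, str] = {}
    for cid, comm in enumerate(ordered, start=1):
        leaders[cid] = leader_of(comm)
        for t in comm:
            membership[t] = cid
    return ClusterSolution(membership, leaders, "louvain", {"seed": seed})


def modularity(graph: CowordGraph, solution: ClusterSolution) -> float:
    """Weighted modularity of a cluster solution on the graph."""
    parts = [set(solution.members(c)) for c in sorted(solution.leaders)]
    return nx.community.modularity(graph, parts, weight="weight")


def write_terms_nodes(solution: ClusterSolution, path: str | Path) -> Path:
    """Export term-to-theme membership as ``terms_nodes.csv``
    (columns: term, cluster, leader_flag)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["term", "cluster", "leader_flag"])
        for term in sorted(solution.membership):
            cid = solution.membership[term]
            w.writerow([term, cid, int(solution.leaders[cid] == term)])
    return path


def write_edge_list(graph: CowordGraph, path: str | Path) -> Path:
    """Export the co-word graph as an edge-list CSV (source, target, weight)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "weight"])
        for a, b, d in sorted(graph.edges(data=True)):
            w.writerow([a, b, d["weight"]])
    return path


def write_graphml(graph: CowordGraph, path: str | Path) -> Path:
    """Export the graph as GraphML (document sets dropped, counts kept)."""
    g = nx.Graph()
    for n, d in graph.nodes(data=True):
        g.add_node(n, freq=d["freq"])
    g.add_edges_from(graph.edges(data=True))
    nx.write_graphml(g, str(path))
    return Path(path)
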