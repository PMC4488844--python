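"""Protein-protein interaction network construction and enrichment.

Candidate pathogenic genes are placed on an undirected PPI graph supplied
as an edge list, together with a designated seed set (the known LQTS
genes) and a hub protein (calmodulin).  Three questions are asked:

* does a candidate interact directly (adjacent) or indirectly (within two
  steps) with a seed gene;
* what seeded sub-networks of bounded size best capture the query set,
  scored by a hypergeometric (Fisher) tail; and
* are candidates over-represented among the hub's direct interactors,
  by a 2x2 Fisher exact test against the rest of the graph.

The greedy network-growth heuristic used here is an open stand-in for
commercial pathway tools whose algorithms are unpublished; rankings are
not expected to be identical to theirs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "InteractionGraph",
    "read_edge_list",
    "write_edge_list",
    "classify_interaction",
    "build_networks",
    "score_network",
    "fisher_exact_2x2",
    "hub_enrichment",
]


@dataclass
class InteractionGraph:
    """Undirected gene graph with seed, hub and candidate designations."""

    graph: nx.Graph
    seeds: set[str] = field(default_factory=set)
    hub: str | None = None
    candidates: set[str] = field(default_factory=set)

    def __post_init__(self):
        nodes = set(self.graph.nodes)
        for group, name in ((self.seeds, "seed"), (self.candidates, "candidate")):
            missing = set(group) - nodes
            if missing:
                raise ValueError(f"{name} genes not in graph: {sorted(missing)}")
        if self.hub is not None and self.hub not in nodes:
            raise ValueError(f"hub {self.hub!r} not in graph")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def read_edge_list(path) -> nx.Graph:
    """Read a two-column TSV of undirected edges (gene_a, gene_b)."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            if a == b:
                continue
            g.add_edge(a, b)
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def classify_interaction(ig: InteractionGraph, gene: str) -> str:
    """Classify a gene as 'direct', 'indirect' or 'none' w.r.t. the seed set.

    direct: adjacent to at least one seed; indirect: within path length 2
    of a seed but not adjacent; none otherwise.
    """
    g = ig.graph
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in graph")
    neighbors = set(g.neighbors(gene))
    if neighbors & ig.seeds:
        return "direct"
    second = set()
    for n in neighbors:
        second.update(g.neighbors(n))
    second.discard(gene)
    if second & ig.seeds:
        return "indirect"
    return "none"


def score_network(
    network_nodes: set[str], query_set: set[str], universe_size: int
) -> float:
    """-log10 right-tail hypergeometric probability of the network's query count.

    P(X >= k) for k query nodes in a network of size n drawn from a
    universe of ``universe_size`` genes containing |query_set| eligible
    genes.
    """
    n = len(network_nodes)
    k = len(set(network_nodes) & set(query_set))
    K = len(query_set)
    if k > n:
        raise ValueError("query count exceeds network size")
    p = float(stats.hypergeom.sf(k - 1, universe_size, K, n))
    # guard against log(0) for extreme configurations
    p = max(p, np.finfo(float).tiny)
    return float(-np.log10(p))


def build_networks(
    ig: InteractionGraph,
    query_set: set[str],
    max_size: int = 35,
    max_networks: int = 10,
    universe_size: int | None = None,
) -> list[dict]:
    """Greedy seeded growth of up to ``max_networks`` sub-networks.

    Each network starts from the highest-degree unassigned query node and
    expands by the neighbor adding the most unassigned query nodes
    (ties broken by degree then name) until ``max_size`` nodes.  Networks
    are returned ranked by :func:`score_network`.
    """
    g = ig.graph
    universe = universe_size if universe_size is not None else g.number_of_nodes()
    unassigned = {q for q in query_set if q in g}
    networks: list[dict] = []
    while unassigned and len(networks) < max_networks:
        start = max(unassigned, key=lambda q: (g.degree(q), q))
        members = {start}
        unassigned.discard(start)
        while len(members) < max_size:
            frontier = set()
            for m in members:
                frontier.update(g.neighbors(m))
            frontier -= members
            if not frontier:
                break

            def gain(node: str) -> tuple:
                new_query = len((set(g.neighbors(node)) | {node}) & unassigned)
                return (new_query, g.degree(node), node)

            best = max(frontier, key=gain)
            members.add(best)
            if best in unassigned:
                unassigned.discard(best)
            # absorb adjacent query nodes eagerly while room remains
            for q in sorted(set(g.neighbors(best)) & unassigned):
                if len(members) >= max_size:
                    break
                members.add(q)
                unassigned.discard(q)
            if best not in query_set and not (set(g.neighbors(best)) & (query_set | members)):
                break
        networks.append(
            {
                "nodes": members,
                "n_query": len(members & query_set),
                "score": score_network(members, query_set, universe),
            }
        )
    networks.sort(key=lambda d: (-d["score"], -d["n_query"], min(d["nodes"])))
    return networks


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sidedness: str = "two-sided") -> float:
    """Fisher exact p for the table [[a, b], [c, d]].

    Two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell counts")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=sidedness)[1])


def hub_enrichment(
    ig: InteractionGraph, candidates: set[str] | None = None, sidedness: str = "two-sided"
) -> tuple[tuple[int, int], float]:
    """Enrichment of hub-adjacent genes among the candidate set.

    Returns ((k, n), p) where k of the n candidates are adjacent to the
    hub, and p is the Fisher exact p of the 2x2 table splitting
    candidates vs all other (non-hub) graph genes by hub adjacency.
    """
    if ig.hub is None:
        raise ValueError("no hub designated on the graph")
    cand = set(candidates) if candidates is not None else set(ig.candidates)
    cand.discard(ig.hub)
    hub_neighbors = set(ig.graph.neighbors(ig.hub))
    k = len(cand & hub_neighbors)
    n = len(cand)
    background = ig.nodes - cand - {ig.hub}
    bk = len(background & hub_neighbors)
    bn = len(background)
    p = fisher_exact_2x2(k, n - k, bk, bn - bk, sidedness=sidedness)
    return (k, n), p
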