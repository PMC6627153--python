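"""Molecular-complex detection (MCODE) on a simple undirected graph.

The algorithm runs in three stages:

1. **Vertex weighting.** Each node ``v`` with degree >= ``degree_cutoff``
   receives weight ``k_max * density(C)``, where ``C`` is the highest
   k-core of the *closed* neighborhood of ``v`` (v plus its direct
   neighbors) and ``k_max`` the largest ``k`` for which that core is
   nonempty — the core-clustering coefficient scaled by its core level.
   Nodes below the degree cutoff get weight 0.
2. **Complex prediction.** Seeds are visited in decreasing weight order
   (ties broken by lexicographic node id). From a seed ``s`` the complex
   grows breadth-first up to ``max_depth`` levels, admitting an unassigned
   neighbor ``v`` iff ``weight(v) > weight(s) * (1 - node_score_cutoff)``
   (strict inequality; boundary equality excludes). Memberships are
   disjoint; a seed whose expansion yields only itself produces no complex
   but may still join one grown later.
3. **Post-processing.** Complexes whose induced subgraph contains no
   ``k_core``-core (default 2 — i.e. no cycle, hence at most two
   interactions) are discarded. With *haircut* on, members of degree < 2
   within the complex are removed iteratively. With *fluff* on, outside
   neighbors whose closed-neighborhood density exceeds
   ``fluff_density_cutoff`` are added (fluffed nodes may overlap between
   complexes).

The cluster score is ``density * |V|`` with
``density = |E| / (|V| (|V| - 1) / 2)``, so a clique of n nodes scores n.
Ranking sorts by descending score, then descending node count, then the
lexicographically smallest member, making every run deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "McodeParams",
    "Cluster",
    "VertexWeightTable",
    "core_decomposition",
    "vertex_weights",
    "predict_complexes",
    "postprocess",
    "score_and_rank",
    "find_clusters",
    "cluster_score",
    "induced_cluster",
]


@dataclasses.dataclass(frozen=True)
class McodeParams:
    """Tuning knobs; the defaults are the canonical Cytoscape-plugin ones."""

    node_score_cutoff: float = 0.2
    degree_cutoff: int = 2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.degree_cutoff < 2 or self.k_core < 2 or self.max_depth < 1:
            raise ValueError("degree_cutoff, k_core >= 2 and max_depth >= 1 required")


@dataclasses.dataclass(frozen=True)
class Cluster:
    """A detected subnetwork with its density-based score."""

    members: frozenset
    n_edges: int
    density: float
    score: float
    seed: str
    rank: int | None = None


@dataclasses.dataclass(frozen=True)
class VertexWeightTable:
    """Per-node MCODE weight plus the graph-wide core number."""

    weight: Mapping[str, float]
    core: Mapping[str, int]


def cluster_score(n_nodes: int, n_edges: int) -> float:
    """Density times node count; density = |E| / (|V|(|V|-1)/2)."""
    if n_nodes < 2:
        return 0.0
    density = n_edges / (n_nodes * (n_nodes - 1) / 2)
    return density * n_nodes


def induced_cluster(network: nx.Graph, members: Iterable[str],
                    seed: str | None = None, rank: int | None = None
                    ) -> Cluster:
    """Build a :class:`Cluster` from an explicit member set."""
    members = frozenset(members)
    sub = network.subgraph(members)
    n, m = len(members), sub.number_of_edges()
    density = 0.0 if n < 2 else m / (n * (n - 1) / 2)
    return Cluster(members=members, n_edges=m, density=density,
                   score=density * n,
                   seed=seed if seed is not None else min(members),
                   rank=rank)


def core_decomposition(network: nx.Graph) -> dict:
    """Core number of every node (largest k with v inside a k-core)."""
    if network.number_of_nodes() == 0:
        return {}
    return dict(nx.core_number(network))


def _highest_core_density(subgraph: nx.Graph) -> tuple:
    """(k_max, density of the highest k-core) of a nonempty subgraph."""
    cores = nx.core_number(subgraph)
    k_max = max(cores.values())
    core_nodes = [v for v, k in cores.items() if k >= k_max]
    core_sub = subgraph.subgraph(core_nodes)
    n = core_sub.number_of_nodes()
    if n < 2:
        return k_max, 0.0
    density = core_sub.number_of_edges() / (n * (n - 1) / 2)
    return k_max, density


def vertex_weights(network: nx.Graph,
                   params: McodeParams = McodeParams()) -> VertexWeightTable:
    """MCODE vertex weighting over the whole network."""
    weight = {}
    for v in network.nodes:
        if network.degree(v) < params.degree_cutoff:
            weight[v] = 0.0
            continue
        closed = set(network[v]) | {v}
        k_max, density = _highest_core_density(network.subgraph(closed))
        weight[v] = k_max * density
    return VertexWeightTable(weight=weight, core=core_decomposition(network))


def predict_complexes(network: nx.Graph, weights: VertexWeightTable,
                      params: McodeParams = McodeParams()) -> list:
    """Greedy seeded expansion; returns unranked disjoint complexes."""
    w = weights.weight
    assigned: set = set()
    complexes: list = []
    for s in sorted(network.nodes, key=lambda v: (-w[v], v)):
        if s in assigned or w[s] <= 0.0:
            continue
        threshold = w[s] * (1.0 - params.node_score_cutoff)
        members = {s}
        frontier = [s]
        depth = 0
        while frontier and depth < params.max_depth:
            next_frontier = []
            for u in frontier:
                for v in sorted(network[u]):
                    if v in members or v in assigned:
                        continue
                    if w[v] > threshold:
                        members.add(v)
                        next_frontier.append(v)
            frontier = next_frontier
            depth += 1
        if len(members) < 2:
            continue  # seed stays free to join a later complex
        assigned |= members
        complexes.append(induced_cluster(network, members, seed=s))
    return complexes


def _neighborhood_density(network: nx.Graph, v: str) -> float:
    closed = set(network[v]) | {v}
    sub = network.subgraph(closed)
    n = len(closed)
    if n < 2:
        return 0.0
    return sub.number_of_edges() / (n * (n - 1) / 2)


def postprocess(clusters: Iterable[Cluster], network: nx.Graph,
                params: McodeParams = McodeParams()) -> list:
    """Core filter, then optional haircut and fluff."""
    out = []
    for cluster in clusters:
        sub = network.subgraph(cluster.members)
        cores = nx.core_number(sub)
        if not cores or max(cores.values()) < params.k_core:
            continue
        members = set(cluster.members)
        if params.haircut:
            # iterated removal of degree-<2 members == the 2-core
            members = {v for v, k in cores.items() if k >= 2}
        if params.fluff:
            extra = set()
            for v in sorted(members):
                for u in network[v]:
                    if u in members or u in extra:
                        continue
                    if _neighborhood_density(network, u) > params.fluff_density_cutoff:
                        extra.add(u)
            members |= extra
        out.append(induced_cluster(network, members, seed=cluster.seed))
    return out


def score_and_rank(clusters: Iterable[Cluster]) -> list:
    """Recompute scores from final membership and assign 1-based ranks.

    Order: descending score, then descending node count, then the
    lexicographically smallest member.
    """
    ranked = sorted(
        clusters,
        key=lambda c: (-c.score, -len(c.members), min(c.members)),
    )
    return [dataclasses.replace(c, rank=i) for i, c in enumerate(ranked, 1)]


def find_clusters(network: nx.Graph,
                  params: McodeParams = McodeParams()) -> list:
    """Full pipeline: weight, predict, post-process, score and rank."""
    weights = vertex_weights(network, params)
    raw = predict_complexes(network, weights, params)
    return score_and_rank(postprocess(raw, network, params))
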