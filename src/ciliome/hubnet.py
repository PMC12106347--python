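"""Topological centralities and consensus hub-gene selection.

A clean-room implementation of the twelve node-ranking methods popularised
by the CytoHubba Cytoscape plug-in, applied to protein-protein interaction
networks, plus the consensus rule: a node is a hub when it ranks in the
top *k* under at least *m* of the twelve methods (defaults k=50, m=6).

Score conventions (all oriented so larger = more central):

- Degree: |N(v)|.
- MNC: node count of the largest connected component of the subgraph
  induced on N(v).
- DMNC: |E| / |V|^epsilon (epsilon = 1.7) of that same component.
- MCC: sum over maximal cliques C containing v of (|C|-1)!; equals the
  degree for nodes contained in no clique larger than an edge.
- EPC (edge percolation): mean size of v's component when each edge
  survives independently with p = 0.5, over Monte-Carlo replicates.
- BottleNeck: number of source nodes s whose shortest-path tree routes
  more than n/4 of its component's nodes through v.
- EcCentricity: component diameter minus eccentricity(v).
- Closeness: harmonic closeness, sum over reachable w of 1/d(v, w).
- Radiality: sum over w in v's component of (diam + 1 - d(v, w)) / (n_c - 1).
- Betweenness: sum of pair-fractions of shortest paths through v.
- Stress: count of shortest paths through v.
- ClusteringCoefficient: 2 tri(v) / (deg (deg - 1)).

Distance-based scores are computed per connected component.  Rank ties use
minimum rank ("1224") so the top-k boundary is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

METHODS = [
    "Degree", "MNC", "DMNC", "MCC", "EPC", "BottleNeck", "EcCentricity",
    "Closeness", "Radiality", "Betweenness", "Stress",
    "ClusteringCoefficient",
]


@dataclass(frozen=True)
class CentralityConfig:
    dmnc_epsilon: float = 1.7
    epc_reps: int = 200
    seed: int = 0
    bottleneck_fraction: float = 0.25


def _validate(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise ValueError("centralities are undefined on an empty graph")
    if any(u == v for u, v in graph.edges):
        raise ValueError("graph must not contain self-loops")
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("graph must be simple and undirected")


def _mnc_dmnc(graph: nx.Graph, epsilon: float):
    mnc, dmnc = {}, {}
    for v in graph:
        nbrs = list(graph.neighbors(v))
        if not nbrs:
            mnc[v], dmnc[v] = 0, 0.0
            continue
        sub = graph.subgraph(nbrs)
        comp = max(nx.connected_components(sub), key=len)
        comp_sub = sub.subgraph(comp)
        mnc[v] = comp_sub.number_of_nodes()
        dmnc[v] = (comp_sub.number_of_edges()
                   / comp_sub.number_of_nodes() ** epsilon)
    return mnc, dmnc


def _mcc(graph: nx.Graph):
    scores = {v: 0.0 for v in graph}
    has_big_clique = {v: False for v in graph}
    for clique in nx.find_cliques(graph):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
            if len(clique) >= 3:
                has_big_clique[v] = True
    for v in graph:
        if not has_big_clique[v]:
            scores[v] = float(graph.degree(v))
    return scores


def _epc(graph: nx.Graph, reps: int, seed: int):
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = list(graph.edges)
    totals = np.zeros(len(nodes))
    for _ in range(reps):
        mask = rng.random(len(edges)) < 0.5
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(e for e, keep in zip(edges, mask) if keep)
        for comp in nx.connected_components(sub):
            size = len(comp)
            for v in comp:
                totals[index[v]] += size
    return {v: totals[index[v]] / reps for v in nodes}


def _bfs_tree_descendants(graph: nx.Graph, source) -> dict:
    """Subtree sizes (including the root of each subtree) of the
    deterministic BFS shortest-path tree rooted at ``source``; neighbors are
    explored in sorted order so parents are reproducible."""
    parent = {source: None}
    order = [source]
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in sorted(graph.neighbors(u), key=str):
                if w not in parent:
                    parent[w] = u
                    order.append(w)
                    nxt.append(w)
        frontier = nxt
    size = {v: 1 for v in order}
    for v in reversed(order):
        if parent[v] is not None:
            size[parent[v]] += size[v]
    return size


def _bottleneck(graph: nx.Graph, fraction: float):
    scores = {v: 0.0 for v in graph}
    for comp in nx.connected_components(graph):
        threshold = fraction * len(comp)
        comp_sub = graph.subgraph(comp)
        for s in comp:
            sizes = _bfs_tree_descendants(comp_sub, s)
            for v, sz in sizes.items():
                if v != s and sz > threshold:
                    scores[v] += 1
    return scores


def _distance_scores(graph: nx.Graph):
    """EcCentricity, Radiality, Stress from per-component BFS; also returns
    path-count matrices for the stress computation."""
    ecc_score = {v: 0.0 for v in graph}
    radiality = {v: 0.0 for v in graph}
    stress = {v: 0.0 for v in graph}
    for comp in nx.connected_components(graph):
        comp = sorted(comp, key=str)
        n = len(comp)
        sub = graph.subgraph(comp)
        if n == 1:
            continue
        index = {v: i for i, v in enumerate(comp)}
        dist = np.full((n, n), np.inf)
        sigma = np.zeros((n, n))
        for v in comp:
            i = index[v]
            dist[i, i] = 0.0
            sigma[i, i] = 1.0
            # BFS with shortest-path counting
            frontier = [v]
            d = 0
            while frontier:
                nxt = []
                for u in frontier:
                    for w in sub.neighbors(u):
                        j, k = index[u], index[w]
                        if np.isinf(dist[i, k]):
                            dist[i, k] = d + 1
                            nxt.append(w)
                        if dist[i, k] == d + 1:
                            sigma[i, k] += sigma[i, j]
                d += 1
                frontier = nxt
        diam = float(dist.max())
        ecc = dist.max(axis=1)
        for v in comp:
            i = index[v]
            ecc_score[v] = diam - ecc[i]
            radiality[v] = float((diam + 1 - dist[i]).sum() - (diam + 1)) / (
                n - 1)
            on_path = (dist[:, i][:, None] + dist[i][None, :]) == dist
            pair_counts = sigma[:, i][:, None] * sigma[i][None, :] * on_path
            pair_counts[i, :] = 0.0
            pair_counts[:, i] = 0.0
            np.fill_diagonal(pair_counts, 0.0)
            stress[v] = float(pair_counts.sum()) / 2.0
    return ecc_score, radiality, stress


@dataclass
class CentralityTable:
    """Node x method scores with per-method minimum ranks (rank 1 = most
    central)."""

    scores: pd.DataFrame
    config: CentralityConfig = field(default_factory=CentralityConfig)

    @property
    def ranks(self) -> pd.DataFrame:
        return self.scores.rank(ascending=False, method="min")

    def top(self, method: str, k: int) -> set:
        ranks = self.ranks[method]
        return set(ranks.index[ranks <= k])


def centralities(graph: nx.Graph,
                 config: CentralityConfig | None = None) -> CentralityTable:
    """Compute all twelve scores for every node of a simple undirected
    graph.  EPC is Monte-Carlo and reproducible given (seed, reps)."""
    config = config or CentralityConfig()
    _validate(graph)
    nodes = sorted(graph.nodes, key=str)

    degree = {v: float(graph.degree(v)) for v in graph}
    mnc, dmnc = _mnc_dmnc(graph, config.dmnc_epsilon)
    mcc = _mcc(graph)
    epc = _epc(graph, config.epc_reps, config.seed)
    bottleneck = _bottleneck(graph, config.bottleneck_fraction)
    closeness = nx.harmonic_centrality(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    clustering = nx.clustering(graph)
    ecc, radiality, stress = _distance_scores(graph)

    data = {
        "Degree": degree, "MNC": mnc, "DMNC": dmnc, "MCC": mcc, "EPC": epc,
        "BottleNeck": bottleneck, "EcCentricity": ecc,
        "Closeness": closeness, "Radiality": radiality,
        "Betweenness": betweenness, "Stress": stress,
        "ClusteringCoefficient": clustering,
    }
    scores = pd.DataFrame({m: [float(data[m][v]) for v in nodes]
                           for m in METHODS}, index=nodes)
    return CentralityTable(scores=scores, config=config)


@dataclass(frozen=True)
class HubSet:
    """Consensus hubs: nodes in the top k of at least m methods."""

    hubs: frozenset
    support: Mapping
    k: int
    m: int


def consensus_hubs(table: CentralityTable, k: int = 50, m: int = 6) -> HubSet:
    """Apply the consensus rule to a centrality table.

    ``k`` is clipped to the node count.  Support counts, per node, the
    number of methods ranking it within the (tie-inclusive) top k.
    """
    n = len(table.scores)
    k = min(k, n)
    support = {v: 0 for v in table.scores.index}
    for method in METHODS:
        for v in table.top(method, k):
            support[v] += 1
    hubs = frozenset(v for v, s in support.items() if s >= m)
    return HubSet(hubs=hubs, support=support, k=k, m=m)
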