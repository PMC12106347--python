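"""Brute-force centrality oracles, independent of the package's
implementations: explicit BFS, exhaustive clique/subset enumeration, and
shortest-path enumeration.  Intended for small graphs only."""

import math
from itertools import combinations

import networkx as nx


def _bfs_distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def _adjacency(graph):
    return {v: set(graph.neighbors(v)) for v in graph}


def oracle_degree(graph, v):
    return float(len(set(graph.neighbors(v))))


def _neighbor_components(graph, v):
    adj = _adjacency(graph)
    nbrs = adj[v]
    sub = {u: adj[u] & nbrs for u in nbrs}
    seen, comps = set(), []
    for u in nbrs:
        if u in seen:
            continue
        comp = set(_bfs_distances(sub, u))
        seen |= comp
        comps.append(comp)
    return comps, sub


def oracle_mnc(graph, v):
    comps, _ = _neighbor_components(graph, v)
    return float(max((len(c) for c in comps), default=0))


def oracle_dmnc(graph, v, epsilon=1.7):
    comps, sub = _neighbor_components(graph, v)
    if not comps:
        return 0.0
    comp = max(comps, key=len)
    edges = sum(1 for a, b in combinations(sorted(comp, key=str), 2)
                if b in sub[a])
    return edges / len(comp) ** epsilon


def oracle_mcc(graph, v):
    """Sum of (|C|-1)! over maximal cliques containing v, by exhaustive
    subset enumeration; degree when v sits in no clique of size >= 3."""
    adj = _adjacency(graph)
    nodes = sorted(graph.nodes, key=str)

    def is_clique(sub):
        return all(b in adj[a] for a, b in combinations(sub, 2))

    cliques = [frozenset(sub) for r in range(1, len(nodes) + 1)
               for sub in combinations(nodes, r) if is_clique(sub)]
    maximal = [c for c in cliques
               if not any(c < d for d in cliques)]
    mine = [c for c in maximal if v in c]
    if not any(len(c) >= 3 for c in mine):
        return float(len(adj[v]))
    return float(sum(math.factorial(len(c) - 1) for c in mine))


def oracle_closeness(graph, v):
    dist = _bfs_distances(_adjacency(graph), v)
    return sum(1.0 / d for w, d in dist.items() if w != v)


def oracle_eccentricity_score(graph, v):
    adj = _adjacency(graph)
    comp = set(_bfs_distances(adj, v))
    if len(comp) == 1:
        return 0.0
    ecc = {u: max(_bfs_distances(adj, u).values()) for u in comp}
    return float(max(ecc.values()) - ecc[v])


def oracle_radiality(graph, v):
    adj = _adjacency(graph)
    dist_v = _bfs_distances(adj, v)
    comp = set(dist_v)
    if len(comp) == 1:
        return 0.0
    diam = max(max(_bfs_distances(adj, u).values()) for u in comp)
    return sum(diam + 1 - d for w, d in dist_v.items() if w != v) / (
        len(comp) - 1)


def _paths_through(graph, v):
    """(pair-fraction sum, path-count sum) of shortest paths through v."""
    frac = count = 0.0
    others = [n for n in graph if n != v]
    for s, t in combinations(others, 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_shortest_paths(graph, s, t))
        through = sum(1 for p in paths if v in p[1:-1])
        frac += through / len(paths)
        count += through
    return frac, count


def oracle_betweenness(graph, v):
    return _paths_through(graph, v)[0]


def oracle_stress(graph, v):
    return _paths_through(graph, v)[1]


def oracle_clustering(graph, v):
    adj = _adjacency(graph)
    d = len(adj[v])
    if d < 2:
        return 0.0
    tri = sum(1 for a, b in combinations(sorted(adj[v], key=str), 2)
              if b in adj[a])
    return 2.0 * tri / (d * (d - 1))


def oracle_bottleneck(graph, v, fraction=0.25):
    """Independent re-derivation of the shortest-path-tree rule: BFS trees
    with sorted first-discovery parents, counting subtree sizes."""
    score = 0.0
    adj = _adjacency(graph)
    for s in graph:
        comp = set(_bfs_distances(adj, s))
        if v not in comp or v == s:
            continue
        parent = {s: None}
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(adj[u], key=str):
                    if w not in parent:
                        parent[w] = u
                        order.append(w)
                        nxt.append(w)
            frontier = nxt
        subtree = {u: 1 for u in order}
        for u in reversed(order):
            if parent[u] is not None:
                subtree[parent[u]] += subtree[u]
        if subtree[v] > fraction * len(comp):
            score += 1
    return score


def oracle_epc_exact(graph, p=0.5):
    """Exact expected component size under independent edge percolation,
    by enumerating all edge subsets.  Only viable for few edges."""
    edges = list(graph.edges)
    nodes = list(graph.nodes)
    expect = {v: 0.0 for v in nodes}
    for mask in range(2 ** len(edges)):
        keep = [e for i, e in enumerate(edges) if mask >> i & 1]
        prob = p ** len(keep) * (1 - p) ** (len(edges) - len(keep))
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(keep)
        for comp in nx.connected_components(sub):
            for v in comp:
                expect[v] += prob * len(comp)
    return expect


ORACLES = {
    "Degree": oracle_degree,
    "MNC": oracle_mnc,
    "DMNC": oracle_dmnc,
    "MCC": oracle_mcc,
    "BottleNeck": oracle_bottleneck,
    "EcCentricity": oracle_eccentricity_score,
    "Closeness": oracle_closeness,
    "Radiality": oracle_radiality,
    "Betweenness": oracle_betweenness,
    "Stress": oracle_stress,
    "ClusteringCoefficient": oracle_clustering,
}
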