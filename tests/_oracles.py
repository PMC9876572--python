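"""Independent brute-force reference implementations of the graph metrics.

Deliberately naive (BFS over all pairs, triple enumeration, direct Pearson
and modularity sums) and independent of the igraph-backed code under test.
Only suitable for small graphs.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from typing import Dict

import networkx as nx


def bfs_distances(g: nx.Graph, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def largest_component_nodes(g: nx.Graph):
    # deterministic: size, then smallest member id as string
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(str(n) for n in c)))
    return comps[0]


def diameter_and_mean_distance(g: nx.Graph):
    """Hop-count diameter and mean pairwise distance on the largest
    component (all ordered pairs averaged, matching the undirected mean)."""
    nodes = list(largest_component_nodes(g))
    if len(nodes) < 2:
        return 0.0, 0.0
    sub = g.subgraph(nodes)
    diam = 0
    total = 0
    n_pairs = 0
    for s in nodes:
        d = bfs_distances(sub, s)
        for t, dv in d.items():
            if t == s:
                continue
            diam = max(diam, dv)
            total += dv
            n_pairs += 1
    return float(diam), total / n_pairs


def triangle_count(g: nx.Graph) -> int:
    n = 0
    for a, b, c in itertools.combinations(sorted(g.nodes(), key=str), 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            n += 1
    return n


def transitivity(g: nx.Graph) -> float:
    """3 * triangles / number of connected triples (paths of length 2)."""
    triples = sum(
        d * (d - 1) // 2 for _, d in g.degree()
    )
    if triples == 0:
        return 0.0
    return 3.0 * triangle_count(g) / triples


def assortativity(g: nx.Graph) -> float:
    """Pearson correlation of degrees across edge endpoints, each edge
    counted in both orientations."""
    xs, ys = [], []
    deg = dict(g.degree())
    for u, v in g.edges():
        xs.extend([deg[u], deg[v]])
        ys.extend([deg[v], deg[u]])
    n = len(xs)
    if n == 0:
        return float("nan")
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    if vx == 0 or vy == 0:
        return float("nan")
    return cov / math.sqrt(vx * vy)


def newman_modularity(g: nx.Graph, membership: Dict) -> float:
    """Weighted Newman-Girvan modularity, direct double sum."""
    m2 = 2.0 * sum(d.get("weight", 1) for _, _, d in g.edges(data=True))
    if m2 == 0:
        return 0.0
    strength = {n: 0.0 for n in g.nodes()}
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1)
        strength[u] += w
        strength[v] += w
    q = 0.0
    for u, v, d in g.edges(data=True):
        if membership[u] == membership[v]:
            q += 2.0 * d.get("weight", 1)
    comm_strength: Dict = {}
    for n, s in strength.items():
        comm_strength[membership[n]] = comm_strength.get(membership[n], 0.0) + s
    for s in comm_strength.values():
        q -= s * s / m2
    return q / m2


def rb_configuration_quality(g: nx.Graph, membership: Dict, gamma: float) -> float:
    """Unnormalised RB-configuration quality:
    sum_in_w - gamma * sum_c (S_c^2) / (2m)."""
    m2 = 2.0 * sum(d.get("weight", 1) for _, _, d in g.edges(data=True))
    if m2 == 0:
        return 0.0
    strength: Dict = {n: 0.0 for n in g.nodes()}
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1)
        strength[u] += w
        strength[v] += w
    q = 0.0
    for u, v, d in g.edges(data=True):
        if membership[u] == membership[v]:
            q += d.get("weight", 1)
    comm: Dict = {}
    for n, s in strength.items():
        comm[membership[n]] = comm.get(membership[n], 0.0) + s
    for s in comm.values():
        q -= gamma * s * s / (2.0 * m2)
    return q


def all_partitions(items):
    """Enumerate all set partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_exhaustive(g: nx.Graph, gamma: float):
    """Globally optimal RB-configuration partition by enumeration."""
    best_q, best = -math.inf, None
    for part in all_partitions(sorted(g.nodes(), key=str)):
        membership = {n: i for i, block in enumerate(part) for n in block}
        q = rb_configuration_quality(g, membership, gamma)
        if q > best_q:
            best_q, best = q, membership
    return best, best_q
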