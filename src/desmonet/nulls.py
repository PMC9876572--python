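"""Random-graph null ensembles matched to an empirical graph.

Three synthetic families with exactly the empirical node and edge counts:

* ``erdos_renyi`` — uniform G(n, m);
* ``scale_free`` — static power-law fitness model (Goh-style): endpoint
  probabilities proportional to i^(-1/(exponent-1)), edges sampled until
  m distinct non-loop pairs are reached;
* ``preferential_attachment`` — Barabási–Albert growth with per-step
  attachment round(m/n), then random edge additions/removals to hit m
  exactly (plain BA cannot reach an arbitrary edge count).

Empirical edge weights are transplanted onto each generated graph by a
uniform random permutation, conserving the weight multiset exactly.  The
empirical graph itself is compared through node-deletion subsamples.

Seeding is counter-based: graph i of a family derives its seed from
(master seed, family index, i), so ensembles are reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .netstats import graph_stats

__all__ = [
    "FAMILIES",
    "EnsembleSpec",
    "generate_null",
    "transplant_weights",
    "subsample_graph",
    "compare_ensembles",
    "derive_seed",
]

FAMILIES = ("erdos_renyi", "scale_free", "preferential_attachment")
DEFAULT_SF_EXPONENT = 2.5


@dataclass
class EnsembleSpec:
    """Specification of one comparison ensemble."""

    family: str
    n_graphs: int = 1000
    n_nodes: int = 0
    n_edges: int = 0
    subsample_delete: int = 100
    sf_exponent: float = DEFAULT_SF_EXPONENT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES + ("subsample",):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_graphs < 1:
            raise ValueError("n_graphs must be >= 1")


def derive_seed(master_seed: int, family: str, i: int) -> int:
    """Counter-based per-graph seed (< 2**31)."""
    label = FAMILIES.index(family) if family in FAMILIES else 99
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(label, int(i)))
    return int(ss.generate_state(1)[0] % (2**31))


def _scale_free_edges(
    n: int, m: int, exponent: float, rng: np.random.Generator
) -> set:
    # static fitness model: P(endpoint = i) ~ (i+1)^(-alpha),
    # alpha = 1/(exponent-1) yields a degree exponent ~ `exponent`
    alpha = 1.0 / (exponent - 1.0)
    fitness = (np.arange(1, n + 1)) ** (-alpha)
    p = fitness / fitness.sum()
    edges: set = set()
    while len(edges) < m:
        need = m - len(edges)
        us = rng.choice(n, size=2 * need + 8, p=p)
        vs = rng.choice(n, size=2 * need + 8, p=p)
        for u, v in zip(us, vs):
            if u == v:
                continue
            e = (int(u), int(v)) if u < v else (int(v), int(u))
            edges.add(e)
            if len(edges) == m:
                break
    return edges


def generate_null(
    family: str,
    n_nodes: int,
    n_edges: int,
    seed: int,
    sf_exponent: float = DEFAULT_SF_EXPONENT,
) -> nx.Graph:
    """Generate one unweighted null graph with exactly (n_nodes, n_edges).

    No self-loops or multi-edges; nodes are 0..n_nodes-1.  Deterministic
    given seed.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges={n_edges} infeasible for n_nodes={n_nodes} (max {max_edges})"
        )
    seed = int(seed) % (2**31)
    if family == "erdos_renyi":
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    elif family == "scale_free":
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(_scale_free_edges(n_nodes, n_edges, sf_exponent, rng))
    elif family == "preferential_attachment":
        m_star = max(1, int(round(n_edges / n_nodes)))
        m_star = min(m_star, n_nodes - 1)
        g = nx.barabasi_albert_graph(n_nodes, m_star, seed=seed)
        rng = np.random.default_rng(seed + 1)
        _adjust_edge_count(g, n_edges, rng)
    else:
        raise ValueError(f"unknown null family {family!r}")
    assert g.number_of_nodes() == n_nodes and g.number_of_edges() == n_edges
    return g


def _adjust_edge_count(g: nx.Graph, target: int, rng: np.random.Generator) -> None:
    n = g.number_of_nodes()
    while g.number_of_edges() > target:
        edges = list(g.edges())
        u, v = edges[int(rng.integers(0, len(edges)))]
        g.remove_edge(u, v)
    while g.number_of_edges() < target:
        u = int(rng.integers(0, n))
        v = int(rng.integers(0, n))
        if u != v and not g.has_edge(u, v):
            g.add_edge(u, v)


def transplant_weights(
    g: nx.Graph, weights: Sequence[float], seed: int
) -> nx.Graph:
    """Assign an empirical weight multiset onto a graph's edges by a
    uniform random permutation.  The output's edge-weight multiset equals
    the input multiset exactly."""
    weights = list(weights)
    if len(weights) != g.number_of_edges():
        raise ValueError(
            f"{len(weights)} weights for {g.number_of_edges()} edges"
        )
    rng = np.random.default_rng(int(seed) % (2**31))
    perm = rng.permutation(len(weights))
    out = g.copy()
    for (u, v), k in zip(sorted(out.edges()), perm):
        out[u][v]["weight"] = weights[int(k)]
    return out


def subsample_graph(g: nx.Graph, n_delete: int = 100, seed: int = 0) -> nx.Graph:
    """Delete ``n_delete`` uniformly chosen nodes (with incident edges)."""
    if n_delete >= g.number_of_nodes():
        raise ValueError("n_delete must be smaller than the node count")
    rng = np.random.default_rng(int(seed) % (2**31))
    nodes = sorted(g.nodes(), key=str)
    drop = rng.choice(len(nodes), size=n_delete, replace=False)
    out = g.copy()
    out.remove_nodes_from([nodes[int(i)] for i in drop])
    return out


def empirical_weights(g: nx.Graph) -> List[float]:
    """Edge-weight multiset of a graph, self-loops excluded (nulls are
    loop-free)."""
    return [
        float(d.get("weight", 1)) for u, v, d in g.edges(data=True) if u != v
    ]


def compare_ensembles(
    empirical: nx.Graph,
    n_graphs: int = 1000,
    families: Iterable[str] = FAMILIES,
    subsample_delete: int = 100,
    sf_exponent: float = DEFAULT_SF_EXPONENT,
    seed: int = 0,
    include_subsample: bool = True,
) -> pd.DataFrame:
    """Metric battery across matched null families plus empirical
    subsamples.

    Returns a long DataFrame: one row per graph with a ``family`` column
    ("empirical_subsample" for the node-deletion subsamples) and all
    :class:`~desmonet.netstats.StatsRecord` fields.
    """
    loops = [(u, v) for u, v in nx.selfloop_edges(empirical)]
    base = empirical.copy()
    base.remove_edges_from(loops)
    n, m = base.number_of_nodes(), base.number_of_edges()
    weights = empirical_weights(base)
    rows = []
    for family in families:
        for i in range(n_graphs):
            s = derive_seed(seed, family, i)
            g = generate_null(family, n, m, seed=s, sf_exponent=sf_exponent)
            g = transplant_weights(g, weights, seed=s + 1)
            rec = graph_stats(g, graph_id=f"{family}_{i}", seed=s)
            d = rec.as_dict()
            d["family"] = family
            rows.append(d)
    if include_subsample:
        for i in range(n_graphs):
            s = derive_seed(seed, "subsample", i)
            g = subsample_graph(base, n_delete=subsample_delete, seed=s)
            rec = graph_stats(g, graph_id=f"subsample_{i}", seed=s)
            d = rec.as_dict()
            d["family"] = "empirical_subsample"
            rows.append(d)
    return pd.DataFrame(rows)


def ensemble_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Median and 2.5/97.5% quantiles per metric per family."""
    metrics = [
        "modularity", "diameter", "mean_distance", "transitivity",
        "n_triangles", "assortativity",
    ]
    out = stats.groupby("family")[metrics].quantile([0.025, 0.5, 0.975])
    out.index.names = ["family", "quantile"]
    return out
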