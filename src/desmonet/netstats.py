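"""Community detection and whole-graph statistics.

Module detection uses the Leiden algorithm optimising the
Reichardt-Bornholdt configuration-model quality (``RBConfiguration``
partition) at a tunable resolution γ; at γ = 1 the quality equals
standard Newman-Girvan weighted modularity.

The metric battery per graph: weighted modularity Q, diameter and mean
distance (hop metric, on the unweighted topology), global transitivity,
triangle count, degree assortativity, and degree / weighted-degree
summaries.  Self-loops are removed before all metrics except weighted
degree, whose standard definition counts loops twice.  Disconnected
graphs have distances computed within the largest component and are
flagged.

Graphs are held as :mod:`networkx` objects; heavy metrics are evaluated
through igraph's C core for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .types import AnnotationSet

__all__ = [
    "Partition",
    "StatsRecord",
    "detect_modules",
    "graph_stats",
    "degree_table",
    "module_anatomy_alignment",
    "weighted_degrees",
    "to_igraph",
]

DEFAULT_RESOLUTION = 0.3
DEFAULT_SEED = 42


@dataclass
class Partition:
    """A node -> module assignment with its quality score."""

    membership: Dict[object, int]
    resolution: float
    quality: float
    seed: int

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0

    def labels(self, nodes) -> np.ndarray:
        return np.array([self.membership[n] for n in nodes])


@dataclass
class StatsRecord:
    """One graph's metric battery."""

    graph_id: str
    n_nodes: int
    n_edges: int
    modularity: float
    n_modules: int
    diameter: float
    mean_distance: float
    transitivity: float
    n_triangles: int
    assortativity: float
    mean_degree: float
    max_degree: int
    mean_weighted_degree: float
    max_weighted_degree: float
    distances_on_largest_component: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def to_igraph(g: nx.Graph, keep_loops: bool = False) -> ig.Graph:
    """Convert to igraph, preserving edge weights; node order is the
    networkx node order, stored in vertex attribute "name"."""
    nodes = list(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges, weights = [], []
    for u, v, d in g.edges(data=True):
        if u == v and not keep_loops:
            continue
        edges.append((index[u], index[v]))
        weights.append(float(d.get("weight", 1)))
    h = ig.Graph(n=len(nodes), edges=edges)
    h.vs["name"] = [str(n) for n in nodes]
    h.es["weight"] = weights
    return h


def _strip_loops(g: nx.Graph) -> nx.Graph:
    if any(True for _ in nx.selfloop_edges(g)):
        g = g.copy()
        g.remove_edges_from(list(nx.selfloop_edges(g)))
    return g


def detect_modules(
    g: nx.Graph,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = DEFAULT_SEED,
    warn_disconnected: bool = True,
) -> Partition:
    """Leiden community detection on the weighted graph.

    Optimises the RB configuration-model quality at the given resolution,
    iterating until no further improvement.  Deterministic given seed.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    if warn_disconnected and not nx.is_connected(_strip_loops(g)):
        warnings.warn("graph is disconnected: modules computed per component",
                      stacklevel=2)
    nodes = list(g.nodes())
    h = to_igraph(g, keep_loops=False)
    part = leidenalg.find_partition(
        h,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    membership = dict(zip(nodes, part.membership))
    # dense module ids ordered by first appearance
    remap: Dict[int, int] = {}
    for n in nodes:
        m = membership[n]
        if m not in remap:
            remap[m] = len(remap)
        membership[n] = remap[m]
    return Partition(
        membership=membership,
        resolution=resolution,
        quality=float(part.quality()),
        seed=int(seed),
    )


def rb_quality(g: nx.Graph, membership: Dict[object, int], resolution: float = 1.0) -> float:
    """RB configuration quality of a given partition; equals weighted
    Newman modularity at resolution 1 (up to the conventional 1/2m
    normalisation applied here)."""
    h = to_igraph(g, keep_loops=False)
    member = [membership[n] for n in g.nodes()]
    m2 = sum(h.es["weight"]) * 2.0
    if m2 == 0:
        return 0.0
    strength = h.strength(weights="weight")
    q = 0.0
    by_comm: Dict[int, list] = {}
    for i, c in enumerate(member):
        by_comm.setdefault(c, []).append(i)
    for u, v, w in zip(*[[e.source for e in h.es], [e.target for e in h.es], h.es["weight"]]):
        if member[u] == member[v]:
            q += 2.0 * w
    for comm, members in by_comm.items():
        s = sum(strength[i] for i in members)
        q -= resolution * s * s / m2
    return q / m2


def weighted_degrees(g: nx.Graph) -> Dict[object, float]:
    """Sum of incident edge weights per node; self-loops count twice."""
    out = {n: 0.0 for n in g.nodes()}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1))
        if u == v:
            out[u] += 2.0 * w
        else:
            out[u] += w
            out[v] += w
    return out


def graph_stats(
    g: nx.Graph,
    partition: Optional[Partition] = None,
    graph_id: str = "graph",
    seed: int = DEFAULT_SEED,
) -> StatsRecord:
    """Compute the full metric battery for one graph.

    If no partition is supplied, a Leiden partition at resolution 1 is
    detected and its weighted Newman modularity reported.  Distances and
    the diameter use hop counts on the unweighted topology; on
    disconnected graphs they are computed within the largest component
    and the record is flagged.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("graph_stats needs at least 2 nodes")
    wdeg = weighted_degrees(g)
    simple = _strip_loops(g)
    if partition is None:
        # disconnectedness is expected for sparse nulls; flagged below
        partition = detect_modules(
            simple, resolution=1.0, seed=seed, warn_disconnected=False
        )
    h = to_igraph(simple)
    member = [partition.membership[n] for n in simple.nodes()]
    # modularity of an edgeless graph is taken as 0 (igraph yields NaN)
    modularity = (
        float(h.modularity(member, weights="weight")) if h.ecount() else 0.0
    )

    connected = h.is_connected()
    if connected:
        comp = h
    else:
        comp = h.connected_components().giant()
    diameter = float(comp.diameter(unconn=False)) if comp.vcount() > 1 else 0.0
    mean_distance = (
        float(comp.average_path_length(unconn=False)) if comp.vcount() > 1 else 0.0
    )
    transitivity = float(h.transitivity_undirected(mode="zero"))
    n_triangles = len(h.list_triangles())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        assort = h.assortativity_degree(directed=False)
    assortativity = float("nan") if assort is None else float(assort)

    degrees = [d for _, d in simple.degree()]
    wvals = list(wdeg.values())
    return StatsRecord(
        graph_id=graph_id,
        n_nodes=g.number_of_nodes(),
        n_edges=simple.number_of_edges(),
        modularity=modularity,
        n_modules=partition.n_modules,
        diameter=diameter,
        mean_distance=mean_distance,
        transitivity=transitivity,
        n_triangles=int(n_triangles),
        assortativity=assortativity,
        mean_degree=float(np.mean(degrees)),
        max_degree=int(np.max(degrees)),
        mean_weighted_degree=float(np.mean(wvals)),
        max_weighted_degree=float(np.max(wvals)),
        distances_on_largest_component=not connected,
    )


def degree_table(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree and weighted degree, sorted by weighted degree
    (descending).  Self-loops count twice toward weighted degree."""
    wdeg = weighted_degrees(g)
    simple_deg = dict(_strip_loops(g).degree())
    rows = [
        {
            "node": n,
            "degree": simple_deg.get(n, 0),
            "weighted_degree": wdeg[n],
            "cell_type": g.nodes[n].get("cell_type", ""),
            "cell_class": g.nodes[n].get("cell_class", ""),
        }
        for n in g.nodes()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["weighted_degree", "node"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def module_anatomy_alignment(partition: Partition, aset: AnnotationSet) -> dict:
    """Compare detected modules with (segment, side) anatomical labels.

    Returns the contingency table (module x anatomical label), the
    adjusted Rand index, and each module's majority label.
    """
    index = aset.skeleton_index
    nodes = [n for n in partition.membership if n in index]
    mods = [partition.membership[n] for n in nodes]
    anat = [f"{index[n].segment.value}_{index[n].side.value}" for n in nodes]
    ari = float(adjusted_rand_score(anat, mods))
    ct = pd.crosstab(
        pd.Series(mods, name="module"), pd.Series(anat, name="anatomy")
    )
    majority = {int(m): ct.loc[m].idxmax() for m in ct.index}
    return {"ari": ari, "contingency": ct, "majority_label": majority}
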