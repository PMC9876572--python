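"""Desmosomal connectome graph construction.

Nodes are skeletons that participate in at least one adhesive junction;
edge weights count the (hemi)desmosomes joining a pair.  Desmosomes and
hemidesmosomes are pooled with weight 1 each.  Self-loops (a cell
adhering to itself, e.g. ring-shaped muscles) are retained.
"""

from __future__ import annotations

import logging
import warnings
from typing import Tuple

import networkx as nx
import pandas as pd

from .types import AnnotationSet, CellClass

__all__ = [
    "build_desmo_graph",
    "largest_component",
    "group_by_type",
    "composition_summary",
    "total_weight",
]

log = logging.getLogger(__name__)

_NODE_FIELDS = ("cell_class", "cell_type", "segment", "side")


def build_desmo_graph(aset: AnnotationSet) -> nx.Graph:
    """Build the undirected weighted adhesive-junction graph.

    One node per skeleton with >= 1 desmosome or hemidesmosome; edge
    weight = number of adhesive connectors joining the pair.  Synapse
    connectors are ignored.  Total edge weight (self-loops counted once)
    equals the number of adhesive connectors.
    """
    g = nx.Graph()
    index = aset.skeleton_index
    for c in aset.adhesive_connectors():
        a, b = c.partners
        for node in {a, b}:
            if node not in g:
                s = index[node]
                g.add_node(
                    node,
                    cell_class=s.cell_class.value,
                    cell_type=s.cell_type or "unclassified",
                    segment=s.segment.value,
                    side=s.side.value,
                    has_soma=s.soma is not None,
                )
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    return g


def total_weight(g: nx.Graph) -> int:
    """Sum of edge weights, self-loops counted once."""
    return int(sum(d.get("weight", 1) for _, _, d in g.edges(data=True)))


def largest_component(g: nx.Graph) -> Tuple[nx.Graph, int]:
    """Extract the maximum-order connected component.

    Returns (component, removed_count).  Ties between equal-order
    components break toward the one containing the lexicographically
    smallest node id, for determinism.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot take the largest component of an empty graph")
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    keep = comps[0]
    sub = g.subgraph(keep).copy()
    return sub, g.number_of_nodes() - sub.number_of_nodes()


def group_by_type(g: nx.Graph) -> nx.Graph:
    """Merge nodes of the same cell type into one node.

    Within-type edges become self-loops; total edge weight is conserved.
    Nodes lacking a cell type map to "unclassified" (warning logged).
    """
    grouped = nx.Graph()
    type_of = {}
    for n, data in g.nodes(data=True):
        t = data.get("cell_type") or "unclassified"
        if t == "unclassified":
            log.warning("node %s lacks a cell_type; grouped as 'unclassified'", n)
        type_of[n] = t
        if t not in grouped:
            grouped.add_node(t, cell_type=t,
                             cell_class=data.get("cell_class", ""), n_cells=0)
        grouped.nodes[t]["n_cells"] += 1
    for u, v, d in g.edges(data=True):
        tu, tv = type_of[u], type_of[v]
        w = d.get("weight", 1)
        if grouped.has_edge(tu, tv):
            grouped[tu][tv]["weight"] += w
        else:
            grouped.add_edge(tu, tv, weight=w)
    return grouped


def composition_summary(g: nx.Graph) -> dict:
    """Class-level composition of the adhesive network.

    Returns junction-count-weighted fractions (primary, as percentages in
    [0, 100]) and edge-count-weighted variants:

    * ``muscle_basal_lamina_pct``: share of total junction weight on
      muscle <-> basal-lamina edges;
    * ``muscle_muscle_pct``: share on muscle <-> muscle edges;
    * ``muscle_muscle_different_type_pct``: among muscle-muscle weight,
      share joining *different* muscle cell types;
    * per-class node counts and the number of nodes with a tagged soma.
    """
    tot = 0
    mus_bl = 0
    mus_mus = 0
    mus_mus_diff = 0
    e_tot = e_mus_bl = e_mus_mus = e_mus_mus_diff = 0
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1)
        cu = g.nodes[u].get("cell_class", "")
        cv = g.nodes[v].get("cell_class", "")
        tot += w
        e_tot += 1
        classes = {cu, cv}
        if classes == {"muscle", "basal_lamina"}:
            mus_bl += w
            e_mus_bl += 1
        elif classes == {"muscle"}:
            mus_mus += w
            e_mus_mus += 1
            if g.nodes[u].get("cell_type") != g.nodes[v].get("cell_type"):
                mus_mus_diff += w
                e_mus_mus_diff += 1
    class_counts: dict = {}
    n_soma = 0
    for _, data in g.nodes(data=True):
        c = data.get("cell_class", "other")
        class_counts[c] = class_counts.get(c, 0) + 1
        if data.get("has_soma", c != "basal_lamina"):
            n_soma += 1

    def pct(a, b):
        return 100.0 * a / b if b else float("nan")

    return {
        "total_junction_weight": tot,
        "n_edges": e_tot,
        "muscle_basal_lamina_pct": pct(mus_bl, tot),
        "muscle_muscle_pct": pct(mus_mus, tot),
        "muscle_muscle_different_type_pct": pct(mus_mus_diff, mus_mus),
        "muscle_basal_lamina_edge_pct": pct(e_mus_bl, e_tot),
        "muscle_muscle_edge_pct": pct(e_mus_mus, e_tot),
        "muscle_muscle_different_type_edge_pct": pct(e_mus_mus_diff, e_mus_mus),
        "nodes_per_class": class_counts,
        "n_nodes_with_soma": n_soma,
    }
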