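"""Combined synaptic-desmosomal analysis: motoneuron influence sets.

A motoneuron's activation contracts its postsynaptic muscles; the
contraction pulls on everything those muscles adhere to.  The *influence
set* of a motoneuron class is therefore its postsynaptic muscles (passing
a synapse-count threshold) plus the desmosomal partners of those muscles
— the tissue mechanically reachable by one contraction.  The traversal is
exactly one adhesive step: second-order desmosomal hops are not included.

Threshold semantics are strict: a "more than k synapses" cut keeps a
connection iff its count is >= k+1 (``min_synapses = k + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import pandas as pd

from .netstats import Partition
from .types import AnnotationSet, CellClass

__all__ = [
    "build_syn_graph",
    "innervation_matrix",
    "influence_set",
    "module_projection",
    "InfluenceSet",
]


def build_syn_graph(aset: AnnotationSet) -> nx.DiGraph:
    """Directed synapse graph: edge weight = synapse count pre -> post.

    Adhesive connectors are ignored.  Node attributes carry cell class,
    type, segment and side.
    """
    g = nx.DiGraph()
    index = aset.skeleton_index
    for c in aset.synapse_connectors():
        pre, post = c.partners
        for node in (pre, post):
            if node not in g:
                s = index[node]
                g.add_node(
                    node,
                    cell_class=s.cell_class.value,
                    cell_type=s.cell_type or "unclassified",
                    segment=s.segment.value,
                    side=s.side.value,
                )
        if g.has_edge(pre, post):
            g[pre][post]["weight"] += 1
        else:
            g.add_edge(pre, post, weight=1)
    return g


def innervation_matrix(
    syn: nx.DiGraph, min_synapses: int = 1
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Grouped synapse-count matrix (motoneuron class x muscle type).

    Each cell sums synapses from all neurons of a class onto all muscles
    of a type.  Returns (raw, masked): the masked matrix zeroes entries
    below ``min_synapses``.
    """
    if min_synapses < 1:
        raise ValueError("min_synapses must be >= 1")
    rows = []
    for pre, post, d in syn.edges(data=True):
        if syn.nodes[pre].get("cell_class") != CellClass.NEURON.value:
            continue
        if syn.nodes[post].get("cell_class") != CellClass.MUSCLE.value:
            continue
        rows.append(
            {
                "mn_class": syn.nodes[pre].get("cell_type", "unclassified"),
                "muscle_type": syn.nodes[post].get("cell_type", "unclassified"),
                "synapses": d.get("weight", 1),
            }
        )
    if not rows:
        empty = pd.DataFrame()
        return empty, empty
    df = pd.DataFrame(rows)
    raw = df.pivot_table(
        index="mn_class", columns="muscle_type", values="synapses",
        aggfunc="sum", fill_value=0,
    ).sort_index(axis=0).sort_index(axis=1)
    masked = raw.where(raw >= min_synapses, 0)
    return raw, masked


@dataclass
class InfluenceSet:
    """Tissue influenced by one motoneuron class."""

    motoneuron_class: str
    motoneuron_ids: Tuple[str, ...]
    min_synapses: int
    muscles: Dict[str, int]  # muscle skeleton id -> synapse count from class
    partners: Dict[str, float]  # partner id -> summed junction weight to muscles

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def n_partners(self) -> int:
        return len(self.partners)


def influence_set(
    mn_class: str,
    syn: nx.DiGraph,
    desmo: nx.Graph,
    min_synapses: int = 1,
    per_neuron: bool = False,
) -> InfluenceSet:
    """Postsynaptic muscles of a motoneuron class plus the desmosomal
    partners of those muscles.

    By default the synapse threshold applies to class-summed counts per
    muscle; with ``per_neuron=True`` a muscle qualifies if any single
    neuron of the class reaches the threshold.  Partners exclude the
    qualifying muscles themselves; each partner's junction weight sums
    over all its desmosomal edges to the muscle set.
    """
    neurons = [
        n for n, d in syn.nodes(data=True)
        if d.get("cell_type") == mn_class
        and d.get("cell_class") == CellClass.NEURON.value
    ]
    if not neurons:
        known = sorted(
            {
                d.get("cell_type")
                for _, d in syn.nodes(data=True)
                if d.get("cell_class") == CellClass.NEURON.value
            }
        )
        raise KeyError(
            f"unknown motoneuron class {mn_class!r}; known classes: {known}"
        )
    per_muscle: Dict[str, int] = {}
    per_muscle_max: Dict[str, int] = {}
    for n in neurons:
        for _, post, d in syn.out_edges(n, data=True):
            if syn.nodes[post].get("cell_class") != CellClass.MUSCLE.value:
                continue
            w = int(d.get("weight", 1))
            per_muscle[post] = per_muscle.get(post, 0) + w
            per_muscle_max[post] = max(per_muscle_max.get(post, 0), w)
    qualify = per_muscle_max if per_neuron else per_muscle
    muscles = {m: per_muscle[m] for m, w in qualify.items() if w >= min_synapses}
    partners: Dict[str, float] = {}
    for m in muscles:
        if m not in desmo:
            continue
        for _, nb, d in desmo.edges(m, data=True):
            if nb in muscles or nb == m:
                continue
            partners[nb] = partners.get(nb, 0.0) + float(d.get("weight", 1))
    return InfluenceSet(
        motoneuron_class=mn_class,
        motoneuron_ids=tuple(sorted(neurons)),
        min_synapses=min_synapses,
        muscles=dict(sorted(muscles.items())),
        partners=dict(sorted(partners.items())),
    )


def module_projection(influence: InfluenceSet, partition: Partition) -> pd.DataFrame:
    """Distribution of an influence set across partition modules.

    One row per module present, with counts of influenced muscles and of
    desmosomal partners assigned to it.  Row sums over the table equal
    the set sizes (nodes missing from the partition are dropped).
    """
    rows: Dict[int, Dict[str, int]] = {}
    for m in influence.muscles:
        if m in partition.membership:
            mod = partition.membership[m]
            rows.setdefault(mod, {"n_muscles": 0, "n_partners": 0})["n_muscles"] += 1
    for p in influence.partners:
        if p in partition.membership:
            mod = partition.membership[p]
            rows.setdefault(mod, {"n_muscles": 0, "n_partners": 0})["n_partners"] += 1
    if not rows:
        return pd.DataFrame(columns=["module", "n_muscles", "n_partners"])
    df = pd.DataFrame(
        [{"module": mod, **counts} for mod, counts in sorted(rows.items())]
    )
    return df
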