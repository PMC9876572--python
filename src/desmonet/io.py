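"""File I/O: annotation JSON, graph export, keypoint CSV.

Annotation dialect
------------------
One top-level JSON object with two arrays::

    {
      "skeletons": [
        {"skeleton_id": "mus_1", "cable_length": 42000.0,
         "soma": {"position": [x, y, z], "radius": 1200.0},
         "cell_class": "muscle", "cell_type": "MUSlongD",
         "segment": "sg2", "side": "left", "extra_annotations": []},
        ...
      ],
      "connectors": [
        {"connector_id": "d_001", "kind": "desmosome",
         "partners": ["mus_1", "mus_2"], "position": [x, y, z]},
        ...
      ]
    }

Coordinates and cable lengths are in nm.  ``soma`` and ``position`` may be
null.  For synapses ``partners`` is ordered (presynaptic, postsynaptic).
Serialization uses sorted keys and sorted record order, so equal annotation
sets serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import networkx as nx

from .types import (
    AnnotationSet,
    Connector,
    IntegrityError,
    Skeleton,
    Soma,
)

__all__ = [
    "read_annotations",
    "write_annotations",
    "annotations_to_json",
    "export_graph",
    "read_keypoints",
    "write_keypoints",
]


def _skeleton_to_dict(s: Skeleton) -> dict:
    return {
        "skeleton_id": s.skeleton_id,
        "cable_length": s.cable_length,
        "soma": None
        if s.soma is None
        else {"position": list(s.soma.position), "radius": s.soma.radius},
        "cell_class": s.cell_class.value,
        "cell_type": s.cell_type,
        "segment": s.segment.value,
        "side": s.side.value,
        "extra_annotations": sorted(s.extra_annotations),
    }


def _skeleton_from_dict(d: dict) -> Skeleton:
    soma = d.get("soma")
    return Skeleton(
        skeleton_id=str(d["skeleton_id"]),
        cable_length=float(d.get("cable_length", 0.0)),
        soma=None
        if soma is None
        else Soma(tuple(float(x) for x in soma["position"]), float(soma.get("radius", 1000.0))),
        cell_class=d.get("cell_class", "other"),
        cell_type=d.get("cell_type", ""),
        segment=d.get("segment", "none"),
        side=d.get("side", "none"),
        extra_annotations=frozenset(d.get("extra_annotations", ())),
    )


def _connector_to_dict(c: Connector) -> dict:
    return {
        "connector_id": c.connector_id,
        "kind": c.kind.value,
        "partners": list(c.partners),
        "position": None if c.position is None else list(c.position),
    }


def _connector_from_dict(d: dict) -> Connector:
    pos = d.get("position")
    return Connector(
        connector_id=str(d["connector_id"]),
        kind=d["kind"],
        partners=tuple(str(p) for p in d["partners"]),
        position=None if pos is None else tuple(float(x) for x in pos),
    )


def annotations_to_json(aset: AnnotationSet) -> str:
    """Serialize deterministically (sorted keys, sorted record order)."""
    payload = {
        "skeletons": sorted(
            (_skeleton_to_dict(s) for s in aset.skeletons),
            key=lambda d: d["skeleton_id"],
        ),
        "connectors": sorted(
            (_connector_to_dict(c) for c in aset.connectors),
            key=lambda d: d["connector_id"],
        ),
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def write_annotations(aset: AnnotationSet, path: Union[str, Path]) -> None:
    """Write an annotation set as JSON readable by :func:`read_annotations`."""
    Path(path).write_text(annotations_to_json(aset))


def read_annotations(path: Union[str, Path], format: str = "json") -> AnnotationSet:
    """Read and validate an annotation set.

    Raises a parse error naming the byte offset for malformed JSON and an
    :class:`IntegrityError` naming the offending connector for dangling
    skeleton references.
    """
    if format != "json":
        raise ValueError(f"unsupported annotation format: {format!r}")
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(
            f"{path}: malformed JSON at byte offset {e.pos}: {e.msg}"
        ) from e
    if not isinstance(payload, dict) or "skeletons" not in payload or "connectors" not in payload:
        raise ValueError(
            f"{path}: expected top-level object with 'skeletons' and 'connectors'"
        )
    skeletons = [_skeleton_from_dict(d) for d in payload["skeletons"]]
    connectors = [_connector_from_dict(d) for d in payload["connectors"]]
    return AnnotationSet(skeletons=skeletons, connectors=connectors)


# ---------------------------------------------------------------------------
# graph export

_NODE_ATTRS = ("cell_class", "cell_type", "segment", "side", "weighted_degree")


def export_graph(graph: nx.Graph, path: Union[str, Path], format: str = "graphml") -> None:
    """Export a desmosomal graph to GraphML or GEXF.

    Node attributes cell_class, cell_type, segment, side and weighted_degree
    and the edge attribute ``weight`` are written; other attributes are
    dropped so the file validates against the plain XML schemas.
    """
    if format not in ("graphml", "gexf"):
        raise ValueError(f"unknown export format: {format!r} (use graphml or gexf)")
    g = nx.Graph()
    for n, data in graph.nodes(data=True):
        wdeg = data.get("weighted_degree")
        if wdeg is None:
            # self-loops contribute twice to weighted degree
            wdeg = sum(
                d.get("weight", 1) * (2 if u == v else 1)
                for u, v, d in graph.edges(n, data=True)
            )
        attrs = {k: data.get(k, "") for k in _NODE_ATTRS[:-1]}
        attrs = {k: (v.value if hasattr(v, "value") else str(v)) for k, v in attrs.items()}
        attrs["weighted_degree"] = float(wdeg)
        g.add_node(str(n), **attrs)
    for u, v, data in graph.edges(data=True):
        g.add_edge(str(u), str(v), weight=float(data.get("weight", 1)))
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        nx.write_gexf(g, path)


# ---------------------------------------------------------------------------
# keypoint CSV (DeepLabCut dialects)


def read_keypoints(path: Union[str, Path]):
    """Read a keypoint-track CSV into a :class:`~desmonet.kinematics.KeypointTrack`.

    Two dialects are accepted: the pose-tracking 3-row header
    (scorer / bodyparts / coords) and a flat 1-row header
    (``frame, <part>_x, <part>_y, <part>_likelihood, ...``).
    """
    from .kinematics import KeypointTrack  # local import avoids a cycle

    import pandas as pd

    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.split(",")[0].strip().lower() == "scorer":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
        df.columns = [f"{bp}_{coord}" for (_, bp, coord) in df.columns]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        if "frame" in df.columns:
            df = df.set_index("frame")
    return KeypointTrack.from_frame(df)


def write_keypoints(track, path: Union[str, Path]) -> None:
    """Write a keypoint track in the flat 1-row header dialect."""
    df = track.data.copy()
    df.index.name = "frame"
    # default float repr round-trips float64 exactly
    df.to_csv(path)
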