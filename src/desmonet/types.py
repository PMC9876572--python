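"""Core domain types for the desmosomal-connectome pipeline.

The data model mirrors what a volume-EM annotation environment exports:
*skeletons* (traced cells or basal-lamina fragments) and *connectors*
(typed junction records linking skeletons).  Adhesive connectors
(desmosomes between two cells, hemidesmosomes between a cell and the
basal lamina) are undirected; synapses are directed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Tuple

__all__ = [
    "CellClass",
    "Segment",
    "Side",
    "ConnectorKind",
    "Soma",
    "Skeleton",
    "Connector",
    "AnnotationSet",
    "IntegrityError",
]


class IntegrityError(ValueError):
    """Raised when an annotation set violates referential integrity."""


class CellClass(str, Enum):
    MUSCLE = "muscle"
    EPIDERMAL = "epidermal"
    CILIATED = "ciliated"
    GLIA = "glia"
    FOLLICLE = "follicle"
    NEURON = "neuron"
    BASAL_LAMINA = "basal_lamina"
    OTHER = "other"


class Segment(str, Enum):
    HEAD = "head"
    SG0 = "sg0"
    SG1 = "sg1"
    SG2 = "sg2"
    SG3 = "sg3"
    PYGIDIUM = "pygidium"
    NONE = "none"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"
    NONE = "none"


class ConnectorKind(str, Enum):
    DESMOSOME = "desmosome"
    HEMIDESMOSOME = "hemidesmosome"
    SYNAPSE = "synapse"


ADHESIVE_KINDS = (ConnectorKind.DESMOSOME, ConnectorKind.HEMIDESMOSOME)


@dataclass(frozen=True)
class Soma:
    """Cell-body marker: position (nm, 3-vector) and radius (nm)."""

    position: Tuple[float, float, float]
    radius: float = 1000.0


@dataclass
class Skeleton:
    """A traced cell or basal-lamina fragment.

    ``cable_length`` is the total traced path length in nm.  Basal-lamina
    fragments never carry a soma: the matrix sheet is traced as many short
    local fragments rather than one body-spanning skeleton.
    """

    skeleton_id: str
    cable_length: float = 0.0
    soma: Optional[Soma] = None
    cell_class: CellClass = CellClass.OTHER
    cell_type: str = ""
    segment: Segment = Segment.NONE
    side: Side = Side.NONE
    extra_annotations: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.cell_class = CellClass(self.cell_class)
        self.segment = Segment(self.segment)
        self.side = Side(self.side)
        self.extra_annotations = frozenset(self.extra_annotations)
        if self.cable_length < 0:
            raise ValueError(
                f"skeleton {self.skeleton_id}: cable_length must be >= 0"
            )
        if self.cell_class is CellClass.BASAL_LAMINA and self.soma is not None:
            raise ValueError(
                f"skeleton {self.skeleton_id}: basal-lamina fragments have no soma"
            )


@dataclass
class Connector:
    """A typed junction record.

    For desmosomes/hemidesmosomes ``partners`` is an unordered pair of
    skeleton ids (self-pairs are legal: ring-shaped muscles can adhere to
    themselves).  For synapses ``partners`` is the ordered
    (presynaptic, postsynaptic) pair.
    """

    connector_id: str
    kind: ConnectorKind
    partners: Tuple[str, str]
    position: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.kind = ConnectorKind(self.kind)
        if len(self.partners) != 2:
            raise ValueError(
                f"connector {self.connector_id}: exactly two partners required"
            )
        self.partners = (str(self.partners[0]), str(self.partners[1]))
        if self.kind in ADHESIVE_KINDS:
            # canonical unordered representation
            a, b = sorted(self.partners)
            self.partners = (a, b)

    @property
    def is_adhesive(self) -> bool:
        return self.kind in ADHESIVE_KINDS


@dataclass
class AnnotationSet:
    """A validated collection of skeletons and connectors."""

    skeletons: list
    connectors: list

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.skeleton_id for s in self.skeletons]
        id_set = set(ids)
        if len(ids) != len(id_set):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate skeleton ids: {dupes}")
        cids = [c.connector_id for c in self.connectors]
        if len(cids) != len(set(cids)):
            dupes = sorted({i for i in cids if cids.count(i) > 1})
            raise IntegrityError(f"duplicate connector ids: {dupes}")
        by_id = {s.skeleton_id: s for s in self.skeletons}
        for c in self.connectors:
            missing = [p for p in c.partners if p not in id_set]
            if missing:
                raise IntegrityError(
                    f"connector {c.connector_id} references unknown "
                    f"skeleton(s): {sorted(set(missing))}"
                )
            if c.kind is ConnectorKind.HEMIDESMOSOME:
                n_bl = sum(
                    by_id[p].cell_class is CellClass.BASAL_LAMINA
                    for p in c.partners
                )
                if n_bl != 1:
                    raise IntegrityError(
                        f"hemidesmosome {c.connector_id} must join exactly one "
                        f"basal-lamina fragment (found {n_bl})"
                    )

    def skeleton(self, skeleton_id: str) -> Skeleton:
        for s in self.skeletons:
            if s.skeleton_id == skeleton_id:
                return s
        raise KeyError(skeleton_id)

    @property
    def skeleton_index(self) -> dict:
        return {s.skeleton_id: s for s in self.skeletons}

    def adhesive_connectors(self) -> Iterable[Connector]:
        return [c for c in self.connectors if c.is_adhesive]

    def synapse_connectors(self) -> Iterable[Connector]:
        return [c for c in self.connectors if c.kind is ConnectorKind.SYNAPSE]

    def __len__(self) -> int:
        return len(self.skeletons)
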