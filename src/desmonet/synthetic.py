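"""Synthetic larva generator.

Emulates the statistical structure of a whole-body volume-EM annotation
set for a three-segmented nectochaete larva, so every downstream stage of
the pipeline can be exercised without the deposited reconstruction:

* segmentally repeated, left-right stereotyped cell-type counts (the
  packaged muscle census plus generated support cells);
* strictly local adhesive wiring — desmosomes only between skeletons whose
  somas lie within a locality radius, no long-range links;
* the basal lamina as many short fragment skeletons, each with a cable
  length below a cap and at least two attached hemidesmosomes;
* hub cells (aciculae and acicular follicle cells) with elevated
  attachment propensity;
* motoneuron classes innervating muscle types via Poisson-distributed
  synapse counts.

The geometry is a stylised cylinder: one z-slab per segment, left/right
x-offsets, Gaussian jitter.  Only locality matters downstream, not
anatomical realism.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .kinematics import KeypointTrack
from .types import (
    AnnotationSet,
    CellClass,
    Connector,
    ConnectorKind,
    Segment,
    Side,
    Skeleton,
    Soma,
)

__all__ = [
    "BasalLaminaConfig",
    "BodyPlanConfig",
    "GaitConfig",
    "default_body_plan",
    "load_muscle_census",
    "generate_larva",
    "generate_gait_tracks",
    "gait_angle_series",
]

SEGMENT_ORDER = ("head", "sg0", "sg1", "sg2", "sg3", "pygidium")

# hub cell types: the chitin rods of the parapodia and their follicle cells
DEFAULT_HUB_TYPES = ("acicula_not", "acicula_neu", "acFC_not", "acFC_neu")

DEFAULT_INNERVATION = (
    ("MNcrab", "MUSac-notA", 1.0),
    ("MNcrab", "MUSac-neuAV", 0.8),
    ("MNcrab", "MUSac-neuPV", 0.6),
    ("MNcrab", "MUSlongD", 0.3),
    ("MNbow", "MUSac-notP", 1.2),
    ("MNbow", "MUSac-neuDach", 0.5),
    ("MNwave", "MUSac-notM", 1.0),
    ("MNwave", "MUSac-notP", 0.8),
    ("MNspider-ant", "MUSobA-re", 0.9),
    ("MNspider-ant", "MUSobA-arc", 0.7),
    ("MNspider-ant", "MUSchae-notAac", 0.5),
    ("MNspider-post", "MUSobP-neuV", 0.9),
    ("MNspider-post", "MUSobP-neuDprox", 0.7),
    ("MNhose", "MUSobA-mpp", 1.0),
    ("MNhose", "MUSobP-notV", 0.8),
    ("MNhose", "MUStrans", 0.4),
    ("MNchae", "MUSchae-neuVob", 1.0),
    ("MNchae", "MUSchae-neuDac", 0.8),
    ("MNring", "MUStrans", 0.8),
    ("MNring", "MUSlongV", 0.4),
    ("MNring", "MUSac-notA", 0.5),
    ("MNacic", "MUSac-notP", 1.0),
    ("MNacic", "MUSac-notM", 0.6),
    ("MNbiramous", "MUSchae-notAac", 0.9),
    ("MNbiramous", "MUSchae-neuDac", 0.7),
    ("MNladder", "MUStrans", 0.6),
    ("MNladder", "MUSobP-notV", 0.5),
)


@dataclass
class BasalLaminaConfig:
    """Basal-lamina fragmentation rule.

    The matrix sheet is emitted as many short fragment skeletons; each
    fragment's cable length stays below ``fragment_max_cable`` (nm) and
    each fragment carries at least ``min_desmosomes_per_fragment``
    hemidesmosomes.
    """

    total_cable: float = 12_000_000.0
    fragment_max_cable: float = 63_700.0
    min_desmosomes_per_fragment: int = 2

    def __post_init__(self) -> None:
        if self.fragment_max_cable <= 0:
            raise ValueError("fragment_max_cable must be positive")


@dataclass
class BodyPlanConfig:
    """Study conditions for the synthetic larva.

    ``type_table`` is long-format: columns cell_type, cell_class, segment,
    side, count.  Wiring is strictly local *contact* wiring: each cell
    adheres to about ``contact_mean`` of its within-``locality_radius``
    neighbours (chosen with probability proportional to the partner's
    attachment propensity, so hub types attract contacts at
    ``hub_factor`` times the base propensity), and every contacting pair
    carries on average ``desmosome_rate`` junctions (at least one).
    Defaults reproduce an adhesive network with mean degree about 5 and
    mean edge weight about 1.8.
    """

    segments: Tuple[str, ...] = SEGMENT_ORDER
    type_table: Optional[pd.DataFrame] = None
    locality_radius: float = 12_000.0
    desmosome_rate: float = 1.8
    contact_mean: float = 2.5
    basal_lamina: BasalLaminaConfig = field(default_factory=BasalLaminaConfig)
    hub_types: Tuple[str, ...] = DEFAULT_HUB_TYPES
    hub_factor: float = 5.0
    muscle_muscle_affinity: float = 0.08
    self_adhesive_types: Tuple[str, ...] = ("MUSring-pyg",)
    innervation_map: Tuple[Tuple[str, str, float], ...] = DEFAULT_INNERVATION
    neurons_per_class_per_side: int = 2
    segment_length: float = 25_000.0
    side_offset: float = 10_000.0
    jitter_sd: Tuple[float, float, float] = (3_000.0, 4_000.0, 6_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_table is None:
            self.type_table = default_body_plan()
        tt = self.type_table
        required = {"cell_type", "cell_class", "segment", "side", "count"}
        if not required.issubset(tt.columns):
            raise ValueError(f"type_table must have columns {sorted(required)}")
        if len(tt) == 0:
            raise ValueError("type_table is empty")
        if (tt["count"] < 0).any():
            raise ValueError("type_table counts must be >= 0")
        if self.desmosome_rate < 0:
            raise ValueError("desmosome_rate must be >= 0")


def load_muscle_census() -> pd.DataFrame:
    """Packaged per-segment, per-side muscle-type census (long format)."""
    ref = importlib.resources.files("desmonet") / "data" / "muscle_types.csv"
    with importlib.resources.as_file(ref) as p:
        wide = pd.read_csv(p)
    rows = []
    for _, r in wide.iterrows():
        for col in wide.columns:
            if col in ("cell_type", "group"):
                continue
            seg, side = col.rsplit("_", 1)
            side = {"l": "left", "r": "right", "m": "midline"}[side]
            seg = {"pyg": "pygidium"}.get(seg, seg)
            n = int(r[col])
            if n > 0:
                rows.append(
                    {
                        "cell_type": r["cell_type"],
                        "cell_class": "muscle",
                        "segment": seg,
                        "side": side,
                        "count": n,
                    }
                )
    return pd.DataFrame(rows)


def _support_cells() -> pd.DataFrame:
    """Generated non-muscle rows: epidermis, ciliary bands, glia, follicle
    cells, aciculae and midline cells, in segment- and side-stereotyped
    counts."""
    rows = []

    def add(cell_type, cell_class, segment, side, count):
        rows.append(
            dict(cell_type=cell_type, cell_class=cell_class, segment=segment,
                 side=side, count=count)
        )

    for side in ("left", "right"):
        add("EC_head", "epidermal", "head", side, 20)
        add("prototroch", "ciliated", "head", side, 6)
        add("glia_head", "glia", "head", side, 3)
        add("EC_sg0", "epidermal", "sg0", side, 10)
        add("glia_sg0", "glia", "sg0", side, 2)
        for seg in ("sg1", "sg2", "sg3"):
            add(f"EC_{seg}", "epidermal", seg, side, 18)
            add(f"paratroch_{seg}", "ciliated", seg, side, 4)
            add(f"glia_{seg}", "glia", seg, side, 2)
            add("acicula_not", "other", seg, side, 1)
            add("acicula_neu", "other", seg, side, 1)
            add("acFC_not", "follicle", seg, side, 3)
            add("acFC_neu", "follicle", seg, side, 3)
            add("chaeFC_not", "follicle", seg, side, 4)
            add("chaeFC_neu", "follicle", seg, side, 4)
        add("EC_pyg", "epidermal", "pygidium", side, 6)
        add("cirrus_pyg", "ciliated", "pygidium", side, 2)
    for seg in ("sg1", "sg2", "sg3"):
        add("midline_glia", "glia", seg, "midline", 2)
    return pd.DataFrame(rows)


def default_body_plan() -> pd.DataFrame:
    """Default type table: packaged muscle census plus support cells."""
    return pd.concat([load_muscle_census(), _support_cells()], ignore_index=True)


# ---------------------------------------------------------------------------


def _segment_z(cfg: BodyPlanConfig) -> Dict[str, float]:
    return {seg: (i + 0.5) * cfg.segment_length for i, seg in enumerate(cfg.segments)}


def _side_x(cfg: BodyPlanConfig) -> Dict[str, float]:
    return {"left": -cfg.side_offset, "right": cfg.side_offset,
            "midline": 0.0, "none": 0.0}


def generate_larva(cfg: BodyPlanConfig) -> AnnotationSet:
    """Generate a synthetic annotation set.

    Deterministic given ``cfg.seed``: skeleton counts per
    (cell_type, segment, side) equal the type table exactly; adhesive
    junctions are placed only between skeletons within
    ``cfg.locality_radius``; basal-lamina fragments obey the
    fragmentation rule; hub types receive elevated attachment propensity;
    synapses follow the innervation map.
    """
    rng = np.random.default_rng(cfg.seed)
    seg_z = _segment_z(cfg)
    side_x = _side_x(cfg)
    sx, sy, sz = cfg.jitter_sd
    hub_set = set(cfg.hub_types)

    skeletons = []
    positions = []
    propensity = []
    table = cfg.type_table.sort_values(
        ["cell_type", "segment", "side"], kind="stable"
    ).reset_index(drop=True)
    for _, row in table.iterrows():
        seg, side = str(row["segment"]), str(row["side"])
        z0 = seg_z.get(seg, 0.0)
        x0 = side_x.get(side, 0.0)
        for k in range(int(row["count"])):
            sid = f"{row['cell_type']}_{seg}_{side}_{k}"
            pos = (
                x0 + rng.normal(0.0, sx),
                rng.normal(0.0, sy),
                z0 + rng.normal(0.0, sz),
            )
            skeletons.append(
                Skeleton(
                    skeleton_id=sid,
                    cable_length=float(rng.uniform(20_000, 100_000)),
                    soma=Soma(pos, radius=float(rng.uniform(800, 2000))),
                    cell_class=str(row["cell_class"]),
                    cell_type=str(row["cell_type"]),
                    segment=seg,
                    side=side,
                )
            )
            positions.append(pos)
            propensity.append(cfg.hub_factor if row["cell_type"] in hub_set else 1.0)

    positions = np.asarray(positions, float)
    propensity = np.asarray(propensity, float)
    n_cells = len(skeletons)

    connectors = []
    cid = 0
    extra_rate = max(cfg.desmosome_rate - 1.0, 0.0)

    # --- desmosomes: strictly local contact wiring.  Each cell adheres to
    # ~contact_mean of its within-radius neighbours; hubs attract contacts.
    is_muscle = np.array(
        [s.cell_class is CellClass.MUSCLE for s in skeletons], bool
    )
    # follicle cells ensheath their rod: few contacts of their own, mostly
    # onto the hub they wrap -> low-degree satellites of high-degree hubs
    contact_scale = np.array(
        [0.5 if s.cell_class is CellClass.FOLLICLE else 1.0 for s in skeletons]
    )
    contact_pairs: set = set()
    if n_cells > 1 and cfg.contact_mean > 0:
        dist = cdist(positions, positions)
        np.fill_diagonal(dist, np.inf)
        for i in range(n_cells):
            nb = np.where(dist[i] <= cfg.locality_radius)[0]
            if nb.size == 0:
                continue
            k = int(rng.poisson(cfg.contact_mean * propensity[i] * contact_scale[i]))
            k = min(k, nb.size)
            if k == 0:
                continue
            # partner choice favours hubs; muscle-muscle contacts are rare
            # (muscles anchor on support tissue, not on each other)
            p = propensity[nb].copy()
            if is_muscle[i]:
                p[is_muscle[nb]] *= cfg.muscle_muscle_affinity
            p /= p.sum()
            chosen = rng.choice(nb, size=k, replace=False, p=p)
            for j in chosen:
                contact_pairs.add((min(i, int(j)), max(i, int(j))))
    for a, b in sorted(contact_pairs):
        count = 1 + int(rng.poisson(extra_rate))
        for _ in range(count):
            connectors.append(
                Connector(
                    connector_id=f"d_{cid}",
                    kind=ConnectorKind.DESMOSOME,
                    partners=(skeletons[a].skeleton_id, skeletons[b].skeleton_id),
                    position=tuple(((positions[a] + positions[b]) / 2.0).tolist()),
                )
            )
            cid += 1

    # --- self-adhering types (ring-shaped muscles): a self-pair junction
    for i, s in enumerate(skeletons):
        if s.cell_type in cfg.self_adhesive_types:
            connectors.append(
                Connector(
                    connector_id=f"d_{cid}",
                    kind=ConnectorKind.DESMOSOME,
                    partners=(s.skeleton_id, s.skeleton_id),
                    position=tuple(positions[i].tolist()),
                )
            )
            cid += 1

    # --- basal lamina: short fragments seeded at host-cell positions
    bl = cfg.basal_lamina
    mean_frag = 0.65 * bl.fragment_max_cable
    n_frags = max(0, int(round(bl.total_cable / mean_frag)))
    bl_skeletons = []
    bl_positions = []
    # the basal lamina runs under the muscle layer: fragments are seeded
    # preferentially at muscle positions and anchor mostly muscle cells
    if n_cells:
        host_p = np.where(is_muscle, 3.0, 1.0)
        host_p /= host_p.sum()
        host_idx = rng.choice(n_cells, size=n_frags, p=host_p)
    else:
        host_idx = np.array([], int)
    for f, h in enumerate(host_idx):
        host = skeletons[h]
        pos = positions[h] + rng.normal(0.0, 1_500.0, size=3)
        frag = Skeleton(
            skeleton_id=f"BL_{f}",
            cable_length=float(rng.uniform(0.3, 0.999) * bl.fragment_max_cable),
            soma=None,
            cell_class=CellClass.BASAL_LAMINA,
            cell_type="basal_lamina",
            segment=host.segment,
            side=host.side,
        )
        bl_skeletons.append(frag)
        bl_positions.append(pos)
    if n_frags:
        bl_positions = np.asarray(bl_positions)
        bl_dist = cdist(bl_positions, positions)
        for f, frag in enumerate(bl_skeletons):
            within = np.where(bl_dist[f] <= cfg.locality_radius)[0]
            if len(within) == 0:
                continue
            # fragmentation rule: at least min_desmosomes_per_fragment
            # hemidesmosomes per fragment, on its nearest in-range cells
            n_attach = bl.min_desmosomes_per_fragment + int(rng.poisson(2.5))
            n_attach = min(n_attach, len(within))
            p = np.where(is_muscle[within], 3.0, 1.0) * np.exp(
                -bl_dist[f][within] / cfg.locality_radius
            )
            p /= p.sum()
            targets = rng.choice(within, size=n_attach, replace=False, p=p)
            counts = 1 + rng.poisson(extra_rate, size=len(targets))
            while counts.sum() < bl.min_desmosomes_per_fragment:
                counts[0] += 1
            for w, count in zip(targets, counts):
                for _ in range(int(count)):
                    connectors.append(
                        Connector(
                            connector_id=f"h_{cid}",
                            kind=ConnectorKind.HEMIDESMOSOME,
                            partners=(frag.skeleton_id, skeletons[w].skeleton_id),
                        )
                    )
                    cid += 1

    # --- motoneurons and synapses
    neuron_skeletons = []
    by_type: Dict[str, list] = {}
    for s in skeletons:
        by_type.setdefault(s.cell_type, []).append(s)
    mn_classes = sorted({mn for mn, _, _ in cfg.innervation_map})
    for mn_class in mn_classes:
        for side in ("left", "right"):
            for k in range(cfg.neurons_per_class_per_side):
                neuron_skeletons.append(
                    Skeleton(
                        skeleton_id=f"{mn_class}_{side}_{k}",
                        cable_length=float(rng.uniform(50_000, 150_000)),
                        soma=Soma(
                            (side_x[side] * 0.3, -5_000.0,
                             seg_z["sg1"] + rng.normal(0, sz))
                        ),
                        cell_class=CellClass.NEURON,
                        cell_type=mn_class,
                        segment="sg1",
                        side=side,
                    )
                )
    neurons_by_class: Dict[str, list] = {}
    for s in neuron_skeletons:
        neurons_by_class.setdefault(s.cell_type, []).append(s)
    for mn_class, muscle_type, mean_syn in cfg.innervation_map:
        targets = by_type.get(muscle_type, [])
        for neuron in neurons_by_class[mn_class]:
            for muscle in targets:
                c = int(rng.poisson(mean_syn))
                for _ in range(c):
                    connectors.append(
                        Connector(
                            connector_id=f"s_{cid}",
                            kind=ConnectorKind.SYNAPSE,
                            partners=(neuron.skeleton_id, muscle.skeleton_id),
                        )
                    )
                    cid += 1

    all_skeletons = skeletons + bl_skeletons + neuron_skeletons
    aset = AnnotationSet(skeletons=all_skeletons, connectors=connectors)

    touched = {p for c in connectors if c.is_adhesive for p in c.partners}
    lonely_types = sorted(
        {s.cell_type for s in skeletons if s.skeleton_id not in touched}
    )
    if lonely_types:
        warnings.warn(
            "cell types with adhesively isolated members (locality radius "
            f"may be too small): {lonely_types}",
            stacklevel=2,
        )
    return aset


# ---------------------------------------------------------------------------
# gait track generation


@dataclass
class GaitConfig:
    """Synthetic undulatory crawl: sinusoidal acicular angles with a
    posterior-to-anterior phase lag, rendered to image-space keypoints.

    ``amplitude_deg`` may be a scalar or one value per parapodium (ordered
    sg1l, sg1r, ..., sg<n>r).  ``phase_lag_deg`` is the phase by which each
    segment lags the one behind it.
    """

    n_frames: int = 500
    frame_rate: float = 50.0
    n_segments: int = 3
    amplitude_deg: Union[float, Sequence[float]] = 30.0
    phase_lag_deg: float = 40.0
    noise_sd_px: float = 1.0
    mean_angle_deg: float = 60.0
    # 1.25 Hz at 50 fps = 40 samples per gait cycle (9 deg phase steps)
    gait_freq_hz: float = 1.25
    # inter-acicular offset oscillates in [-25, 50] deg by default
    inter_offset_deg: float = 12.5
    inter_amp_deg: float = 37.5
    acicula_len_px: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        amps = np.atleast_1d(np.asarray(self.amplitude_deg, float))
        if (amps <= 0).any():
            raise ValueError("amplitude_deg must be positive")

    @property
    def parapodia(self) -> Tuple[str, ...]:
        return tuple(
            f"sg{i}{s}" for i in range(1, self.n_segments + 1) for s in ("l", "r")
        )

    def amplitudes(self) -> Dict[str, float]:
        amps = np.atleast_1d(np.asarray(self.amplitude_deg, float))
        pps = self.parapodia
        if amps.size == 1:
            amps = np.repeat(amps, len(pps))
        if amps.size != len(pps):
            raise ValueError("amplitude_deg must be scalar or one per parapodium")
        return dict(zip(pps, amps))


def _phase(cfg: GaitConfig, pp: str) -> float:
    seg = int(pp[2])
    phi = -np.radians(cfg.phase_lag_deg) * (cfg.n_segments - seg)
    if pp.endswith("r"):
        phi += np.pi  # alternating gait: right side in antiphase
    return phi


def gait_angle_series(cfg: GaitConfig) -> Dict[str, Dict[str, pd.Series]]:
    """Noiseless ground-truth angle series per parapodium.

    Returns {parapodium: {"not": bodyline-angle series,
    "neu": series, "inter": signed inter-acicular offset}}.
    """
    t = np.arange(cfg.n_frames) / cfg.frame_rate
    w = 2 * np.pi * cfg.gait_freq_hz
    amps = cfg.amplitudes()
    out: Dict[str, Dict[str, pd.Series]] = {}
    idx = pd.RangeIndex(cfg.n_frames)
    for pp in cfg.parapodia:
        phi = _phase(cfg, pp)
        theta_not = cfg.mean_angle_deg + amps[pp] * np.sin(w * t + phi)
        delta = cfg.inter_offset_deg + cfg.inter_amp_deg * np.sin(
            w * t + phi + np.pi / 3
        )
        theta_neu = theta_not + delta
        out[pp] = {
            "not": pd.Series(theta_not, index=idx, name=f"{pp}_not"),
            "neu": pd.Series(theta_neu, index=idx, name=f"{pp}_neu"),
            "inter": pd.Series(delta, index=idx, name=f"{pp}_inter"),
        }
    return out


def generate_gait_tracks(cfg: GaitConfig) -> KeypointTrack:
    """Render the ground-truth gait to noisy image-space keypoints.

    Image coordinates are y-down with the body axis vertical (pharynx
    above proctodeum).  Gaussian pixel noise of ``noise_sd_px`` is added
    to every coordinate.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = gait_angle_series(cfg)
    n = cfg.n_frames
    cx, y_ph, y_pr = 200.0, 40.0, 440.0
    body_px = y_pr - y_ph

    cols: Dict[str, np.ndarray] = {}

    def put(part: str, x: np.ndarray, y: np.ndarray) -> None:
        cols[part + "_x"] = x + rng.normal(0.0, cfg.noise_sd_px, size=n)
        cols[part + "_y"] = y + rng.normal(0.0, cfg.noise_sd_px, size=n)
        cols[part + "_likelihood"] = np.full(n, 0.999)

    put("pharynx", np.full(n, cx), np.full(n, y_ph))
    put("proctodeum", np.full(n, cx), np.full(n, y_pr))

    # bodyline direction in the y-up frame is (0, -1); aciculae are this
    # direction rotated by +theta (left side) or -theta (right side)
    for pp in cfg.parapodia:
        seg = int(pp[2])
        side_sign = 1.0 if pp.endswith("l") else -1.0
        y_anchor = y_ph + body_px * (0.3 + 0.2 * seg)
        x_anchor = cx + (-25.0 if pp.endswith("l") else 25.0)
        for lobe in ("not", "neu"):
            theta = np.radians(truth[pp][lobe].to_numpy())
            ang = side_sign * theta
            # rotate (0,-1) by ang (counterclockwise, y-up)
            dx = np.sin(ang)
            dy_up = -np.cos(ang)
            prox_x = np.full(n, x_anchor)
            prox_y = np.full(n, y_anchor)
            dist_x = prox_x + cfg.acicula_len_px * dx
            dist_y = prox_y - cfg.acicula_len_px * dy_up  # back to y-down
            off = 0.0 if lobe == "not" else 6.0
            put(f"{pp}_{lobe}_prox", prox_x + off, prox_y)
            put(f"{pp}_{lobe}_dist", dist_x + off, dist_y)

    df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="frame"))
    return KeypointTrack.from_frame(df)
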