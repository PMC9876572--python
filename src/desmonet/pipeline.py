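"""Config-driven end-to-end run.

Stages: simulate (or ingest) -> build graph -> modules & stats -> null
ensembles -> motoneuron influence -> kinematics -> report bundle.  A
single master seed is fanned out to named per-stage sub-seeds; all seeds
and parameters land in a provenance JSON, so identical (config, seed)
pairs produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .graph import build_desmo_graph, composition_summary, largest_component
from .io import export_graph, read_annotations, write_annotations, write_keypoints
from .kinematics import acicular_angles, gait_heatmap, inter_acicular
from .netstats import detect_modules, graph_stats, degree_table, module_anatomy_alignment
from .neuro import build_syn_graph, influence_set, innervation_matrix
from .nulls import compare_ensembles, ensemble_summary
from .synthetic import BodyPlanConfig, GaitConfig, generate_larva, generate_gait_tracks

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Exactly one input source: an annotation JSON path, or simulation via
    a :class:`~desmonet.synthetic.BodyPlanConfig`.
    """

    out_dir: str = "desmonet_out"
    annotations: Optional[str] = None
    simulate: Optional[BodyPlanConfig] = None
    gait: Optional[GaitConfig] = None
    resolution: float = 0.3
    min_synapses: int = 4
    ensemble_n: int = 0  # 0 disables the (slow) null-ensemble stage
    subsample_delete: int = 100
    run_stats: bool = True
    run_influence: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if (self.annotations is None) == (self.simulate is None):
            raise ValueError(
                "exactly one input source required: annotations path or simulate config"
            )


def _stage_seed(master: int, stage: str) -> int:
    # zlib.crc32 is stable across processes (str hash() is salted)
    import zlib

    key = zlib.crc32(stage.encode()) % (2**31)
    h = np.random.SeedSequence(entropy=int(master), spawn_key=(key,))
    return int(h.generate_state(1)[0] % (2**31))


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns a dict of produced artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    seeds = {
        s: _stage_seed(config.seed, s)
        for s in ("simulate", "modules", "nulls", "gait")
    }

    stage = "input"
    try:
        if config.simulate is not None:
            cfg = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            aset = generate_larva(cfg)
            p = out / "annotations.json"
            write_annotations(aset, p)
            artifacts["annotations"] = str(p)
        else:
            aset = read_annotations(config.annotations)

        stage = "graph"
        raw = build_desmo_graph(aset)
        g, removed = largest_component(raw)
        export_graph(g, out / "desmo_graph.graphml", "graphml")
        artifacts["graph"] = str(out / "desmo_graph.graphml")
        comp = composition_summary(g)
        comp["removed_from_largest_component"] = removed
        pd.json_normalize(comp).to_csv(out / "composition.csv", index=False)
        artifacts["composition"] = str(out / "composition.csv")

        partition = None
        if config.run_stats:
            stage = "stats"
            partition = detect_modules(
                g, resolution=config.resolution, seed=seeds["modules"]
            )
            pd.DataFrame(
                {"node": list(partition.membership),
                 "module": list(partition.membership.values())}
            ).to_csv(out / "partition.csv", index=False)
            artifacts["partition"] = str(out / "partition.csv")
            rec = graph_stats(g, graph_id="empirical", seed=seeds["modules"])
            pd.DataFrame([rec.as_dict()]).to_csv(out / "stats.csv", index=False)
            artifacts["stats"] = str(out / "stats.csv")
            degree_table(g).to_csv(out / "degrees.csv", index=False)
            align = module_anatomy_alignment(partition, aset)
            (out / "alignment.json").write_text(
                json.dumps({"ari": align["ari"],
                            "majority_label": align["majority_label"]}, indent=1)
            )
            artifacts["alignment"] = str(out / "alignment.json")

        if config.ensemble_n > 0:
            stage = "nulls"
            stats = compare_ensembles(
                g,
                n_graphs=config.ensemble_n,
                subsample_delete=min(config.subsample_delete,
                                     max(1, g.number_of_nodes() - 2)),
                seed=seeds["nulls"],
            )
            stats.to_csv(out / "ensemble.csv", index=False)
            ensemble_summary(stats).to_csv(out / "ensemble_summary.csv")
            artifacts["ensemble"] = str(out / "ensemble.csv")

        if config.run_influence:
            stage = "influence"
            syn = build_syn_graph(aset)
            raw_m, masked = innervation_matrix(syn, min_synapses=config.min_synapses)
            raw_m.to_csv(out / "innervation_raw.csv")
            masked.to_csv(out / "innervation_masked.csv")
            artifacts["innervation"] = str(out / "innervation_masked.csv")
            classes = sorted(
                {
                    d.get("cell_type")
                    for _, d in syn.nodes(data=True)
                    if d.get("cell_class") == "neuron"
                }
            )
            influence = {}
            for mn in classes:
                inf = influence_set(mn, syn, g, min_synapses=config.min_synapses)
                influence[mn] = {
                    "muscles": inf.muscles,
                    "partners": inf.partners,
                    "min_synapses": inf.min_synapses,
                }
            (out / "influence.json").write_text(json.dumps(influence, indent=1))
            artifacts["influence"] = str(out / "influence.json")

        if config.gait is not None:
            stage = "kinematics"
            gcfg = dataclasses.replace(config.gait, seed=seeds["gait"])
            track = generate_gait_tracks(gcfg)
            write_keypoints(track, out / "gait_tracks.csv")
            rows = []
            series = {}
            for pp in track.parapodia:
                ang = acicular_angles(track, pp, lobe="not")
                series[pp] = ang
                inter = inter_acicular(track, pp)
                for frame in track.data.index:
                    rows.append(
                        {"frame": frame, "parapodium": pp,
                         "bodyline_angle": ang.loc[frame],
                         "inter_acicular": inter.loc[frame]}
                    )
            pd.DataFrame(rows).to_csv(out / "angles.csv", index=False)
            matrix, lags = gait_heatmap(series)
            matrix.to_csv(out / "gait_heatmap.csv")
            (out / "phase_lags.json").write_text(json.dumps(lags, indent=1))
            artifacts["kinematics"] = str(out / "angles.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "resolution": config.resolution,
        "min_synapses": config.min_synapses,
        "ensemble_n": config.ensemble_n,
        "input": config.annotations or "simulated",
        "artifacts": artifacts,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    artifacts["provenance"] = str(out / "provenance.json")
    return artifacts
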