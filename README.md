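# desmonet

Whole-body **adhesive-junction (desmosomal) connectomics** for segmented
annelid larvae — and, more generally, for any volume-EM reconstruction in
which cells and basal-lamina fragments are traced as skeletons and their
desmosomes and hemidesmosomes are annotated as typed connectors.

Muscles exert force only on what they are attached to.  In annelid larvae
those attachments are desmosomes (cell–cell) and hemidesmosomes
(cell–basal lamina), so the body-wide tension network can be written as an
undirected weighted graph *G = (V, E, w)*: nodes are cells and basal-lamina
fragments, an edge {u, v} exists when the two skeletons share at least one
adhesive junction, and *w(u, v)* counts the junctions.  `desmonet` builds
that graph from annotation exports, characterises it, and combines it with
the directed synaptic connectome:

* **Graph construction** — adhesive graph assembly, largest-component
  extraction, cell-type grouping, class-level composition summaries.
* **Modules and metrics** — Leiden community detection optimising the
  Reichardt–Bornholdt configuration quality at resolution γ (default 0.3;
  at γ = 1 it is weighted Newman–Girvan modularity
  *Q = (1/2m) Σ_ij [w_ij − s_i s_j / 2m] δ(c_i, c_j)*), plus a metric
  battery: diameter and mean hop distance, global transitivity
  (3·triangles / connected triples), triangle count, degree assortativity,
  degree and weighted-degree tables.
* **Null ensembles** — Erdős–Rényi, scale-free (static fitness) and
  preferential-attachment graphs matched exactly in |V| and |E|, with the
  empirical edge-weight multiset transplanted by random permutation, and
  node-deletion subsamples of the empirical graph.
* **Motoneuron influence sets** — postsynaptic muscles of a motoneuron
  class above a synapse threshold (a "> k synapses" cut keeps count ≥ k+1)
  plus one adhesive step to the muscles' desmosomal partners: the tissue a
  single motoneuron class can move.
* **Gait kinematics** — acicular angles against the pharynx→proctodeum
  bodyline from pose-tracking keypoint CSVs, 0–100 normalisation within
  each acicula's range of motion, signed inter-acicular angles, gait
  heatmaps and inter-segment phase lags.
* **Synthetic larva generator** — a first-class, tested module that emits
  annotation sets with the statistical structure the analysis assumes
  (stereotyped cell-type counts per segment and side, strictly local
  wiring, fragmented basal lamina, acicular hubs, Poisson innervation) and
  synthetic gait tracks with known ground truth.

## Worked example

```python
import warnings
from desmonet import (BodyPlanConfig, generate_larva, build_desmo_graph,
                      largest_component, detect_modules, graph_stats,
                      module_anatomy_alignment)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    aset = generate_larva(BodyPlanConfig(seed=1))      # ~1500 skeletons
graph, _ = largest_component(build_desmo_graph(aset))
part = detect_modules(graph, resolution=0.3, seed=42)
print(graph.number_of_nodes(), graph.number_of_edges())
print(round(module_anatomy_alignment(part, aset)["ari"], 2))
print(round(graph_stats(graph).modularity, 2))
```

prints

```
1484 4400
0.84
0.83
```

1484 cells and basal-lamina fragments joined by 4400 weighted edges; the
Leiden modules recover the planted (segment, side) anatomical territories
with adjusted Rand index 0.84; the weighted modularity of 0.83 is far
above matched random graphs (≈ 0.5, see `examples/03_null_ensembles.py`).

The `examples/` directory has one short script per capability (graph
construction, modules/metrics, null ensembles, motoneuron influence, gait
kinematics).  A thin CLI wraps the same functions:

```bash
desmonet simulate --seed 1 --out sim/
desmonet build-graph sim/annotations.json --out graph.graphml --summary comp.csv
desmonet kinematics sim/gait_tracks.csv --out angles.csv --heatmap gait.csv
desmonet run --config run.yaml
```

## File formats

* **Annotation JSON** — one object with `skeletons` and `connectors`
  arrays (documented in `desmonet/io.py`); coordinates and cable lengths
  in nm; adhesive connector partners unordered, synapse partners ordered
  (pre, post).
* **Keypoint CSV** — DeepLabCut-style 3-row header or a flat
  `frame, <part>_x, <part>_y, <part>_likelihood` layout; required parts
  are `pharynx`, `proctodeum` and per-parapodium acicular points
  (`sg2l_not_prox`, `sg2l_not_dist`, `sg2l_neu_prox`, `sg2l_neu_dist`, …).
* **Graph exports** — GraphML / GEXF with node attributes (cell class,
  type, segment, side, weighted degree) and edge weights, ready for
  force-field layout tools.
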