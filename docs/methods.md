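# Methods

## The graph model

The desmosomal connectome is an undirected weighted graph.  Nodes are
skeletons: traced cells, plus basal-lamina *fragments* — the extracellular
matrix sheet is deliberately traced as many short skeletons (cable length
< 63,700 nm, each carrying at least two hemidesmosomes), because a single
body-spanning basal-lamina node would dominate every centrality measure
and erase the locality the analysis is about.  Edge weight is the integer
count of desmosomes plus hemidesmosomes between the pair; both junction
types are pooled at weight 1.  Self-loops (ring-shaped muscles adhering to
themselves) are retained in the graph, count twice toward weighted degree
(the standard convention), and are removed before transitivity, distance
and assortativity computations, whose textbook definitions are undefined
or degenerate on loops.  Only skeletons with at least one adhesive
junction enter the graph; the analysis then proceeds on the largest
connected component (ties broken toward the component containing the
lexicographically smallest node id, for determinism).

Synapses form a separate directed graph (edge weight = synapse count,
presynaptic → postsynaptic) and never contribute to the adhesive graph.

## Module detection and the metric battery

Modules are detected with the Leiden algorithm optimising the
Reichardt–Bornholdt configuration quality at resolution γ (default 0.3,
seed default 42, iterated until no improvement).  At γ = 1 the normalised
quality equals weighted Newman–Girvan modularity, which is what the
`StatsRecord.modularity` field reports; when no partition is supplied,
one is detected at γ = 1 so that modularity is comparable across graphs.

Distances and the diameter are computed on the **unweighted** topology:
the junction count measures adhesive strength, not proximity, and no
principled hop-length transform of it exists.  Transitivity is the global
unweighted clustering coefficient 3·triangles / connected triples — the
weighted variant has no canonical definition, so the unweighted one is
the default (this choice is deliberately conservative and is flagged as
an open modelling question).  Assortativity is the Pearson correlation of
degrees across edge endpoints.  On disconnected graphs (common for sparse
random nulls) distances are computed within the largest component and the
record is flagged (`distances_on_largest_component`).  Heavy metrics run
through igraph's C core; the test suite pins every metric to independent
brute-force implementations (all-pairs BFS, triple enumeration, direct
Pearson and modularity sums, exhaustive partition search) on hundreds of
small random graphs.

## Null ensembles

Three random families are matched **exactly** in node and edge count:
G(n, m) Erdős–Rényi; a static-fitness scale-free model (endpoint
probability ∝ i^(−1/(α−1)), degree exponent α default 2.5 — the exponent
is a configuration knob because no canonical value exists for this
comparison); and Barabási–Albert preferential attachment with per-step
attachment round(m/n) followed by random edge additions/removals, since
plain BA cannot reach an arbitrary edge count.  Each generated graph
receives the empirical edge-weight multiset by a uniform random
permutation (multiset conservation is asserted exactly).  The empirical
graph enters the comparison through node-deletion subsamples (default 100
nodes removed).  Seeding is counter-based — graph i of a family derives
its seed from (master seed, family index, i) via `SeedSequence` — so
ensembles are reproducible and order-independent.

## The synthetic larva

The generator produces annotation sets with the statistical structure the
analysis assumes, not anatomical realism:

* **Body plan.** A stylised cylinder: one 25 µm z-slab per segment (head,
  sg0–sg3, pygidium), left/right x-offsets of ±10 µm, Gaussian soma
  jitter (3, 4, 6 µm).  Cell-type counts per (segment, side) follow the
  packaged 56-row muscle census (853+ cells) plus generated support
  tissue (epidermis, ciliary bands, glia, follicle cells, aciculae,
  midline cells) — left/right symmetric wherever the census is.
* **Wiring.** Strictly local contact wiring: each cell adheres to
  ~`contact_mean` (default 2.5) partners inside `locality_radius`
  (default 12 µm), chosen with probability proportional to the partner's
  attachment propensity.  Hub types (aciculae and acicular follicle
  cells) have propensity `hub_factor` (default 5); follicle cells make
  few contacts of their own, so they become low-degree satellites of
  their rods.  Muscle–muscle contacts are down-weighted
  (`muscle_muscle_affinity`, default 0.08): muscles anchor on support
  tissue and matrix, rarely on each other.  Each contacting pair carries
  1 + Poisson(`desmosome_rate` − 1) junctions (default rate 1.8).  These
  defaults were calibrated once against the published network totals
  (≈2800 nodes, ≈7000 edges, ≈12,700 junctions → mean degree ≈5, mean
  weight ≈1.8) and then frozen.
* **Basal lamina.** Fragments are seeded at (muscle-biased) host-cell
  positions; each anchors 2 + Poisson(2.5) nearby cells with
  hemidesmosomes, so every fragment satisfies the fragmentation rule by
  construction.
* **Innervation.** Motoneuron classes (4 cells each, 2 per side) synapse
  onto muscle types per an innervation map; counts per (neuron, muscle)
  pair are Poisson with the mapped mean, so grouped innervation matrices
  have known expectations for goodness-of-fit tests.

What the generator does *not* emulate: true cell morphology and contact
geometry, the empirical junction-count distribution (Poisson is a
modelling choice), chaetal ultrastructure, and any developmental noise
structure.  Passing tests therefore show that the *pipeline* recovers
planted structure under realistic density and locality — not that the
biological network has been re-derived.

With the default configuration the generated connectome has ≈1480 nodes
and ≈4400 edges, and reproduces the qualitative signature of the real
adhesive network against matched weighted nulls: highest modularity
(≈0.83 vs ≈0.5), largest diameter and mean distance, transitivity above
all three synthetic families, lowest (most negative) assortativity, and
Leiden modules at γ = 0.3 that align with the planted (segment, side)
territories (ARI ≈ 0.8).  These are exactly the quantities
`scripts/acceptance.py` recomputes.

## Kinematics

Input keypoints are image coordinates (y down); all geometry is computed
after flipping to a y-up frame — the convention is stated because
pose-tracking exports never state theirs.  The bodyline axis is the
pharynx→proctodeum unit vector per frame.  Acicular angles
(proximal→distal vector vs bodyline) are reported unsigned in [0°, 180°]
(a signed variant exists behind a flag); inter-acicular angles are signed
by the counterclockwise-positive cross product, so the sign flips under
left-right mirroring, as it must for a bilateral gait.  Keypoints below
the likelihood threshold (default 0.9 — a configuration parameter, since
no standard value exists) are masked; gaps of ≤ 3 frames are linearly
interpolated, longer gaps stay missing.  Range-of-motion normalisation
maps each series' [min, max] to [0, 100]; a constant series has no
defined range and becomes missing with a warning.

Amplitude/phase estimation fits mean + A·sin(2πft + φ) by least squares,
with the frequency located at the FFT peak and refined on the continuous
axis — a plain DFT-bin readout under-estimates the amplitude by ~30% when
the record holds a fractional number of gait cycles, which is the usual
case.  Phase lags between parapodia are differences of fitted phases at
the shared dominant frequency (equivalent to the circular
cross-correlation peak, with sub-frame resolution).

The synthetic gait uses 1.25 Hz at 50 fps (40 samples per cycle, so
noiseless extremes are sampled exactly), amplitude 30° about a 60° mean,
a 40° posterior-to-anterior phase lag with left/right antiphase, and an
inter-acicular offset oscillating over [−25°, 50°].

## Problem sizes and numerical choices

Default analysis sizes — ~1500-cell larva, 100 graphs per null family,
500-frame tracks — were chosen as the smallest sizes at which the
ensemble orderings and recovery tolerances are stable across seeds.
Tolerances: graph metrics are asserted to 1e−9 against oracles; planted
composition percentages recover exactly (integer weights); gait amplitude
within 2° and phase within 5° at 1 px noise.  Degenerate inputs: empty
graphs and empty partitions raise domain errors; edgeless graphs report
modularity 0; regular graphs report assortativity NaN (undefined Pearson
denominator).

## Known limitations

* The annotation JSON dialect is this package's own; it emulates, but is
  not, a CATMAID API export.
* Whether the published composition percentages weight by junction count
  or by edge count is ambiguous; both are computed, junction-count
  weighting is primary.
* The scale-free exponent and the preferential-attachment edge-count
  correction are modelling choices where the comparison protocol is
  under-specified.
* Influence sets traverse exactly one adhesive step; force propagation
  deeper into the tissue is out of scope, as is the neuronal circuitry
  upstream of motoneurons.  The synapse threshold applies per class by
  default (per-neuron available), and no gap junctions are modelled.
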