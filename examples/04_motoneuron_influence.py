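"""Motoneuron tissue-influence sets.

A motoneuron class's influence set is its postsynaptic muscles (passing
a synapse threshold) plus everything those muscles adhere to — the
tissue mechanically reachable by one contraction.
"""
import warnings

from desmonet import (
    BodyPlanConfig,
    build_desmo_graph,
    build_syn_graph,
    generate_larva,
    influence_set,
    innervation_matrix,
    largest_component,
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    aset = generate_larva(BodyPlanConfig(seed=1))
desmo, _ = largest_component(build_desmo_graph(aset))
syn = build_syn_graph(aset)

raw, masked = innervation_matrix(syn, min_synapses=10)
print("innervation matrix (connections with more than 9 synapses):")
print(masked.loc[:, (masked != 0).any()].to_string())

inf = influence_set("MNcrab", syn, desmo, min_synapses=4)
print(f"\nMNcrab (threshold: more than 3 synapses): "
      f"{inf.n_muscles} muscles, {inf.n_partners} desmosomal partners")
from collections import Counter
partner_classes = Counter(
    desmo.nodes[p]["cell_class"] for p in inf.partners if p in desmo
)
print("partner tissue classes:", dict(partner_classes))
# Partners typically include basal-lamina fragments, epidermal and
# follicle cells: the contraction pulls on all of them.
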