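import networkx as nx
import numpy as np
import pytest
from scipy.stats import chisquare

from desmonet import (
    AnnotationSet,
    Connector,
    Partition,
    Skeleton,
    build_desmo_graph,
    build_syn_graph,
    influence_set,
    innervation_matrix,
    module_projection,
)
from desmonet.synthetic import BodyPlanConfig


def skel(sid, cls, ctype):
    return Skeleton(skeleton_id=sid, cell_class=cls, cell_type=ctype)


def toy_annotations():
    """One motoneuron class (2 cells), two muscles, desmosomal partners."""
    skeletons = [
        skel("mn1", "neuron", "MNX"), skel("mn2", "neuron", "MNX"),
        skel("mnB", "neuron", "MNB"),
        skel("M1", "muscle", "T1"), skel("M2", "muscle", "T2"),
        skel("E1", "epidermal", "EC"),
        skel("BL3", "basal_lamina", "basal_lamina"),
    ]
    connectors = []
    cid = [0]

    def syn(pre, post, n):
        for _ in range(n):
            connectors.append(Connector(f"s{cid[0]}", "synapse", (pre, post)))
            cid[0] += 1

    def des(a, b, n):
        for _ in range(n):
            connectors.append(Connector(f"d{cid[0]}", "desmosome", (a, b)))
            cid[0] += 1

    syn("mn1", "M1", 6)
    syn("mn2", "M1", 7)
    syn("mn1", "M2", 3)
    syn("mnB", "M2", 12)
    des("M1", "E1", 2)
    des("M1", "BL3", 1)  # desmosome stand-in for a BL link in this toy
    des("M2", "E1", 4)
    des("M1", "M2", 5)
    return AnnotationSet(skeletons=skeletons, connectors=connectors)


class TestSynGraph:
    def test_edge_weight_is_synapse_count(self):
        g = build_syn_graph(toy_annotations())
        assert g["mn1"]["M1"]["weight"] == 6
        assert g.has_edge("mn2", "M1")

    def test_no_synapses_gives_empty_graph(self):
        aset = AnnotationSet(
            skeletons=[skel("a", "muscle", "T"), skel("b", "muscle", "T")],
            connectors=[Connector("d", "desmosome", ("a", "b"))],
        )
        assert build_syn_graph(aset).number_of_edges() == 0

    def test_total_weight_equals_synapse_count(self, default_larva):
        g = build_syn_graph(default_larva)
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert total == len(list(default_larva.synapse_connectors()))


class TestInnervationMatrix:
    def test_class_sums_pool_neurons(self):
        raw, _ = innervation_matrix(build_syn_graph(toy_annotations()))
        assert raw.loc["MNX", "T1"] == 13

    def test_strict_more_than_nine_threshold(self):
        """A '>9 synapses' cut (min_synapses=10) masks a 9-synapse cell
        and keeps a 10-synapse cell."""
        skeletons = [skel("mn", "neuron", "MN"),
                     skel("a", "muscle", "TA"), skel("b", "muscle", "TB")]
        connectors = [Connector(f"sa{i}", "synapse", ("mn", "a")) for i in range(9)]
        connectors += [Connector(f"sb{i}", "synapse", ("mn", "b")) for i in range(10)]
        syn = build_syn_graph(AnnotationSet(skeletons, connectors))
        raw, masked = innervation_matrix(syn, min_synapses=10)
        assert raw.loc["MN", "TA"] == 9 and masked.loc["MN", "TA"] == 0
        assert masked.loc["MN", "TB"] == 10

    def test_min_one_mask_is_identity(self):
        raw, masked = innervation_matrix(build_syn_graph(toy_annotations()),
                                         min_synapses=1)
        assert raw.equals(masked)

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            innervation_matrix(build_syn_graph(toy_annotations()),
                               min_synapses=0)

    def test_planted_innervation_recovered_within_poisson_error(
            self, default_larva):
        """Class-by-type synapse totals on the synthetic larva match the
        planted Poisson expectations (chi-square goodness of fit)."""
        cfg = BodyPlanConfig()
        counts = {}
        for s in default_larva.skeletons:
            counts[s.cell_type] = counts.get(s.cell_type, 0) + 1
        n_neurons = 2 * cfg.neurons_per_class_per_side
        raw, _ = innervation_matrix(build_syn_graph(default_larva))
        obs, exp = [], []
        for mn_class, muscle_type, mean in cfg.innervation_map:
            expected = n_neurons * counts[muscle_type] * mean
            observed = raw.loc[mn_class, muscle_type]
            obs.append(observed)
            exp.append(expected)
        obs, exp = np.array(obs, float), np.array(exp, float)
        stat, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.01


class TestInfluenceSet:
    def test_muscles_and_partners_of_a_class(self):
        aset = toy_annotations()
        inf = influence_set("MNX", build_syn_graph(aset),
                            build_desmo_graph(aset), min_synapses=1)
        assert set(inf.muscles) == {"M1", "M2"}
        # partners exclude the qualifying muscles themselves
        assert set(inf.partners) == {"E1", "BL3"}
        assert inf.partners["E1"] == 6  # 2 via M1 + 4 via M2

    def test_strict_more_than_three_threshold_empties_weak_set(self):
        aset = toy_annotations()
        inf = influence_set("MNB", build_syn_graph(aset),
                            build_desmo_graph(aset), min_synapses=4)
        assert set(inf.muscles) == {"M2"}
        weak = AnnotationSet(
            skeletons=[skel("mn", "neuron", "MN"), skel("M", "muscle", "T")],
            connectors=[Connector(f"s{i}", "synapse", ("mn", "M"))
                        for i in range(3)],
        )
        inf2 = influence_set("MN", build_syn_graph(weak), nx.Graph(),
                             min_synapses=4)
        assert inf2.n_muscles == 0 and inf2.n_partners == 0

    def test_unknown_class_lists_known_classes(self):
        aset = toy_annotations()
        with pytest.raises(KeyError, match="MNB"):
            influence_set("nonexistent", build_syn_graph(aset),
                          build_desmo_graph(aset))

    def test_monotone_in_threshold(self, default_larva, default_graph):
        """Raising the synapse threshold never enlarges the influenced
        tissue.  The muscle set is monotone on its own; the partner set is
        only monotone jointly with the muscles (a muscle dropped by the
        threshold may re-enter as a desmosomal partner of a kept one)."""
        syn = build_syn_graph(default_larva)
        classes = sorted({d["cell_type"] for _, d in syn.nodes(data=True)
                          if d["cell_class"] == "neuron"})
        for mn in classes[:4]:
            prev_m, prev_u = None, None
            for thr in (1, 4, 10):
                inf = influence_set(mn, syn, default_graph, min_synapses=thr)
                union = set(inf.muscles) | set(inf.partners)
                if prev_m is not None:
                    assert set(inf.muscles) <= prev_m
                    assert union <= prev_u
                prev_m, prev_u = set(inf.muscles), union

    def test_class_influence_is_union_of_neuron_influences(self, default_larva,
                                                           default_graph):
        syn = build_syn_graph(default_larva)
        mn = "MNcrab"
        whole = influence_set(mn, syn, default_graph, min_synapses=1)
        union_muscles = set()
        for nid in whole.motoneuron_ids:
            for _, post, d in syn.out_edges(nid, data=True):
                if syn.nodes[post]["cell_class"] == "muscle":
                    union_muscles.add(post)
        assert set(whole.muscles) == union_muscles


class TestModuleProjection:
    def partition_for(self, influence, n_modules=1):
        nodes = list(influence.muscles) + list(influence.partners)
        membership = {n: i % n_modules for i, n in enumerate(sorted(nodes))}
        return Partition(membership=membership, resolution=0.3,
                         quality=0.0, seed=0)

    def test_single_module_yields_single_row(self):
        aset = toy_annotations()
        inf = influence_set("MNX", build_syn_graph(aset),
                            build_desmo_graph(aset))
        out = module_projection(inf, self.partition_for(inf, 1))
        assert len(out) == 1

    def test_empty_influence_yields_empty_table(self):
        aset = toy_annotations()
        inf = influence_set("MNB", build_syn_graph(aset),
                            build_desmo_graph(aset), min_synapses=100)
        out = module_projection(inf, Partition({}, 0.3, 0.0, 0))
        assert len(out) == 0

    def test_counts_sum_to_set_sizes(self):
        aset = toy_annotations()
        inf = influence_set("MNX", build_syn_graph(aset),
                            build_desmo_graph(aset))
        out = module_projection(inf, self.partition_for(inf, 2))
        assert out["n_muscles"].sum() == inf.n_muscles
        assert out["n_partners"].sum() == inf.n_partners
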