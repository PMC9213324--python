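"""HGT-consistent labellings: verification, construction, existence,
horizontal arcs, base trees, crowns, and the all-but-one rule."""

from fractions import Fraction

import networkx as nx
import pytest

from orchardnet.network import Network, validate, reticulation_number
from orchardnet.cherries import CherrySequence, is_orchard, reconstruct_from_sequence
from orchardnet.enewick import parse_enewick
from orchardnet.labelling import (
    verify_labelling,
    labelling_from_sequence,
    labelling_exists,
    horizontal_arcs,
    base_tree,
    contains_crown,
    allbutone_labelling_exists,
)
from orchardnet import synth

from conftest import ALLBUTONE_WITNESS


class TestVerifyLabelling:
    def test_strict_topological_order_on_tree(self):
        tree = synth.random_orchard(synth.GeneratorConfig(n=5, k=0, seed=4))
        t = {v: Fraction(i) for i, v in enumerate(nx.topological_sort(tree.graph))}
        assert verify_labelling(tree, t) == []

    def test_crown_rejects_every_candidate(self, crown2):
        # a handful of candidates, including ones honouring single equalities
        g = crown2.graph
        order = list(nx.topological_sort(g))
        candidates = [{v: Fraction(i) for i, v in enumerate(order)}]
        retics = [v for v in g if g.in_degree(v) == 2]
        for r in retics:
            t = {v: Fraction(i) for i, v in enumerate(order)}
            t[r] = t[sorted(g.predecessors(r))[0]]
            candidates.append(t)
        for t in candidates:
            assert verify_labelling(crown2, t) != []

    def test_partial_labelling_raises(self):
        net = Network.from_arcs([(0, 1), (1, 2), (1, 3)], {2: "a", 3: "b"})
        with pytest.raises(ValueError, match="partial"):
            verify_labelling(net, {0: Fraction(0)})

    def test_each_property_reported_with_witness(self):
        net = Network.from_arcs([(0, 1), (1, 2), (1, 3)], {2: "a", 3: "b"})
        t = {0: Fraction(2), 1: Fraction(1), 2: Fraction(1), 3: Fraction(1)}
        report = "\n".join(verify_labelling(net, t))
        assert "P1" in report and "P2" in report


class TestLabellingFromSequence:
    def test_single_cherry_labels(self):
        seq = CherrySequence.from_pairs([("a", "b")])
        net = reconstruct_from_sequence(seq)
        t = labelling_from_sequence(net, seq)
        assert t[net.root] == 0
        internal = net.child(net.root)
        assert t[internal] == 1
        assert sorted(t[leaf] for leaf in net.leaves) == [2, 3]
        assert verify_labelling(net, t) == []

    def test_example_label_multiplicity(self, gamma_net):
        net, seq = gamma_net
        t = labelling_from_sequence(net, seq)
        assert verify_labelling(net, t) == []
        values = list(t.values())
        assert max(values.count(v) for v in set(values)) <= 2

    def test_equal_labels_only_on_tree_parent_reticulation_child(self, gamma_net):
        net, seq = gamma_net
        t = labelling_from_sequence(net, seq)
        by_value = {}
        for v, val in t.items():
            by_value.setdefault(val, []).append(v)
        for val, nodes in by_value.items():
            if len(nodes) == 1:
                continue
            a, b = nodes
            parent, child = (a, b) if net.graph.has_edge(a, b) else (b, a)
            assert net.graph.has_edge(parent, child)
            assert net.graph.in_degree(parent) == 1 and net.graph.out_degree(parent) == 2
            assert net.graph.in_degree(child) == 2

    def test_tree_labels_all_distinct(self):
        tree = synth.random_orchard(synth.GeneratorConfig(n=6, k=0, seed=8))
        ok, seq = is_orchard(tree)
        t = labelling_from_sequence(tree, seq)
        assert len(set(t.values())) == len(t)

    def test_wrong_sequence_raises(self, gamma_net):
        net, _ = gamma_net
        bad = CherrySequence.from_pairs([("1", "13")])
        with pytest.raises(ValueError, match="not reducible"):
            labelling_from_sequence(net, bad)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_orchard_labelling_verifies(self, seed):
        net = synth.random_orchard(synth.GeneratorConfig(n=3 + seed % 5,
                                                         k=seed % 3, seed=seed))
        ok, seq = is_orchard(net)
        assert verify_labelling(net, labelling_from_sequence(net, seq)) == []


class TestLabellingExists:
    def test_tree_always_admits_labelling(self):
        tree = synth.random_orchard(synth.GeneratorConfig(n=5, k=0, seed=3))
        ok, t, assignment = labelling_exists(tree)
        assert ok and assignment == {}
        assert verify_labelling(tree, t) == []

    def test_crown_admits_none(self, crown2):
        ok, t, assignment = labelling_exists(crown2)
        assert (ok, t, assignment) == (False, None, None)

    def test_witness_labelling_always_verifies(self):
        for seed in range(10):
            net = synth.random_network(synth.GeneratorConfig(n=4, k=2, seed=seed))
            ok, t, assignment = labelling_exists(net)
            if ok:
                assert verify_labelling(net, t) == []
                for r, p in assignment.items():
                    assert t[r] == t[p] and net.graph.has_edge(p, r)

    @pytest.mark.parametrize("seed", range(40))
    def test_agrees_with_cherry_picking_oracle(self, seed):
        net = synth.random_network(synth.GeneratorConfig(n=3 + seed % 4,
                                                         k=seed % 3, seed=seed))
        assert labelling_exists(net)[0] == is_orchard(net)[0]


class TestHorizontalArcsAndBaseTree:
    def test_tree_has_no_horizontal_arcs_and_is_own_base(self):
        tree = synth.random_orchard(synth.GeneratorConfig(n=5, k=0, seed=6))
        ok, seq = is_orchard(tree)
        t = labelling_from_sequence(tree, seq)
        assert horizontal_arcs(tree, t) == set()
        assert base_tree(tree, t).graph.number_of_nodes() == tree.graph.number_of_nodes()

    def test_example_has_exactly_two_horizontal_arcs(self, gamma_net):
        net, seq = gamma_net
        t = labelling_from_sequence(net, seq)
        arcs = horizontal_arcs(net, t)
        assert len(arcs) == 2
        assert all(net.graph.in_degree(v) == 2 for _, v in arcs)

    @pytest.mark.parametrize("seed", range(8))
    def test_one_horizontal_arc_per_reticulation(self, seed):
        k = 1 + seed % 3
        net = synth.random_orchard(synth.GeneratorConfig(n=4, k=k, seed=seed))
        ok, seq = is_orchard(net)
        t = labelling_from_sequence(net, seq)
        assert len(horizontal_arcs(net, t)) == k

    def test_example_base_tree_is_a_tree_on_all_taxa(self, gamma_net):
        net, seq = gamma_net
        t = labelling_from_sequence(net, seq)
        tree = base_tree(net, t)
        assert validate(tree) == []
        assert reticulation_number(tree) == 0
        assert tree.taxon_set() == net.taxon_set()

    def test_invalid_labelling_rejected(self, gamma_net):
        net, _ = gamma_net
        t = {v: Fraction(0) for v in net.graph}
        with pytest.raises(ValueError, match="not HGT-consistent"):
            horizontal_arcs(net, t)


class TestCrownDetection:
    def test_crown_fixture_witness(self, crown2):
        found, witness = contains_crown(crown2)
        assert found and len(witness) == 4

    def test_larger_crowns_found(self):
        for m in (3, 4):
            found, witness = contains_crown(synth.crown_network(m))
            assert found and len(witness) == 2 * m

    def test_trees_have_no_crown(self):
        tree = synth.random_orchard(synth.GeneratorConfig(n=6, k=0, seed=5))
        assert contains_crown(tree) == (False, None)

    @pytest.mark.parametrize("seed", range(25))
    def test_crown_implies_no_labelling(self, seed):
        net = synth.random_network(synth.GeneratorConfig(n=3 + seed % 3,
                                                         k=1 + seed % 2, seed=seed))
        if contains_crown(net)[0]:
            assert not labelling_exists(net)[0]


class TestAllButOneRule:
    def test_agrees_with_binary_labelling(self):
        for seed in range(8):
            net = synth.random_network(synth.GeneratorConfig(n=4, k=seed % 3, seed=seed))
            assert allbutone_labelling_exists(net) == labelling_exists(net)[0]

    def test_tree_always_satisfies_rule(self):
        tree = synth.random_orchard(synth.GeneratorConfig(n=5, k=0, seed=7))
        assert allbutone_labelling_exists(tree)

    def test_orchard_witness_fails_rule(self):
        """An orchard network with a 3-parent reticulation for which no
        all-but-one labelling exists: the rule does not characterize
        non-binary orchard networks."""
        net = parse_enewick(ALLBUTONE_WITNESS)
        assert validate(net) == []
        assert max(net.graph.in_degree(v) for v in net.graph) == 3
        assert is_orchard(net)[0]
        assert not allbutone_labelling_exists(net)
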