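"""Top structures, reorientation, lifting, gathering, tree sorting, and
the full certified path between orchard networks."""

import itertools
import math
import random

import networkx as nx
import pytest

from orchardnet.network import validate, is_isomorphic, reticulation_number
from orchardnet.cherries import is_orchard
from orchardnet.labelling import labelling_from_sequence
from orchardnet import space, synth
from orchardnet.space import (
    NEAT,
    REVERSED,
    top_structure,
    neat_moves,
    reorient_prefix,
    raise_triangle,
    lift_reticulation,
    gather_leaves,
    tree_rnni_path,
    orchard_path,
    diameter_bound,
    _flip_prefix,
    _normalize_pattern,
)
from orchardnet.moves import rnni_neighbors

from conftest import triangle_case1, triangle_case2_head, triangle_case2_tail


class TestTopStructure:
    def test_tree_has_empty_top_structure(self):
        tree = synth.random_orchard(synth.GeneratorConfig(n=5, k=0, seed=1))
        assert top_structure(tree).k_top == 0

    @pytest.mark.parametrize("pattern", [
        ("neat",), ("neat", "neat"), ("neat", "reversed"),
        ("neat", "neat", "reversed", "neat"),
    ])
    def test_fixture_pattern_recovered(self, pattern):
        net = synth.top_stack_fixture(len(pattern), list(pattern))
        ts = top_structure(net)
        assert ts.k_top == len(pattern)
        assert _normalize_pattern(ts.orientation) == _normalize_pattern(list(pattern))

    def test_reticulation_not_adjacent_to_root_child_not_counted(self):
        # one reticulation buried under a tree edge: k_top must be 0
        net = triangle_case1()
        assert reticulation_number(net) == 1
        assert top_structure(net).k_top == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_top_horizontal_arcs_have_equal_labels(self, seed):
        """Any verified labelling makes every top horizontal arc
        horizontal."""
        net = synth.random_orchard(synth.GeneratorConfig(n=4, k=2, seed=seed))
        ts = top_structure(net)
        ok, seq = is_orchard(net)
        t = labelling_from_sequence(net, seq)
        for x, y in ts.horizontal:
            assert t[x] == t[y]


class TestNeatMoves:
    def test_all_neat_needs_no_flip(self):
        assert neat_moves([NEAT, NEAT, NEAT]) == []

    def test_mixed_four_stack_needs_two_flips(self):
        assert len(neat_moves([NEAT, NEAT, REVERSED, NEAT])) == 2

    def test_all_reversed_needs_one_flip(self):
        for k in (1, 2, 5):
            assert neat_moves([REVERSED] * k) == [k]

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_schedule_works_and_is_minimal(self, k):
        for pattern in itertools.product([NEAT, REVERSED], repeat=k):
            pattern = list(pattern)
            flips = neat_moves(pattern)
            state = list(pattern)
            for f in flips:
                state = _flip_prefix(state, f)
            assert state == [NEAT] * k
            # brute-force minimality over all shorter flip schedules
            for length in range(len(flips)):
                assert not any(
                    _apply_all(pattern, combo) == [NEAT] * k
                    for combo in itertools.product(range(1, k + 1), repeat=length)
                )


def _apply_all(pattern, combo):
    state = list(pattern)
    for f in combo:
        state = _flip_prefix(state, f)
    return state


class TestReorientPrefix:
    def test_single_move_returned_and_is_a_neighbor(self):
        net = synth.top_stack_fixture(3, [NEAT, NEAT, NEAT])
        result, move = reorient_prefix(net, 2)
        neighbors = rnni_neighbors(net)
        assert any(is_isomorphic(result, nb) for _, nb in neighbors)

    def test_flips_exactly_the_prefix(self):
        net = synth.top_stack_fixture(4, [NEAT, NEAT, REVERSED, NEAT])
        result, _ = reorient_prefix(net, 2)
        got = _normalize_pattern(top_structure(result).orientation)
        want = _normalize_pattern(_flip_prefix([NEAT, NEAT, REVERSED, NEAT], 2))
        assert got == want

    def test_double_application_is_involution(self):
        net = synth.top_stack_fixture(4, [NEAT, REVERSED, NEAT, NEAT])
        once, _ = reorient_prefix(net, 3)
        twice, _ = reorient_prefix(once, 3)
        assert is_isomorphic(twice, net)

    def test_k_prime_beyond_k_top_raises(self):
        net = synth.top_stack_fixture(2, [NEAT, NEAT])
        with pytest.raises(ValueError, match="exceeds"):
            reorient_prefix(net, 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_result_stays_orchard(self, seed):
        net = synth.random_orchard(synth.GeneratorConfig(n=4, k=2, seed=seed))
        ts = top_structure(net)
        if ts.k_top >= 1:
            result, _ = reorient_prefix(net, 1)
            assert is_orchard(result)[0]


class TestRaiseTriangle:
    def test_tree_node_case_two_moves_one_level(self):
        net = triangle_case1()
        r = 5
        t = space._constructive_labelling(net)
        before = len(nx.ancestors(net.graph, r))
        result, moves, outcome = raise_triangle(net, r, t)
        assert outcome == "raised"
        assert len(moves) == 2
        assert len(nx.ancestors(result.graph, r)) == before - 1
        assert is_orchard(result)[0]

    def test_reticulation_endpoint_case_three_moves_to_top(self):
        net = triangle_case2_head()
        r = 6
        t = space._constructive_labelling(net)
        assert top_structure(net).k_top == 1
        result, moves, outcome = raise_triangle(net, r, t)
        assert outcome == "topped"
        assert len(moves) == 3
        assert top_structure(result).k_top == 2

    def test_tail_endpoint_case_four_moves_to_top(self):
        net = triangle_case2_tail()
        r = 6
        t = space._constructive_labelling(net)
        assert top_structure(net).k_top == 1
        result, moves, outcome = raise_triangle(net, r, t)
        assert outcome == "topped"
        assert len(moves) == 4
        assert top_structure(result).k_top == 2


class TestLiftReticulation:
    @pytest.mark.parametrize("seed", range(10))
    def test_lift_increments_k_top_within_2n_moves(self, seed):
        rng = random.Random(seed)
        n, k = rng.randint(4, 7), rng.randint(1, 3)
        net = synth.random_orchard(synth.GeneratorConfig(n=n, k=k, seed=seed))
        cur = net
        while top_structure(cur).k_top < k:
            before = top_structure(cur).k_top
            cur, moves = lift_reticulation(cur)
            assert top_structure(cur).k_top == before + 1
            assert len(moves) <= 2 * n
            assert validate(cur) == [] and is_orchard(cur)[0]

    def test_all_at_top_raises(self):
        net = synth.top_stack_fixture(2, [NEAT, NEAT])
        with pytest.raises(ValueError, match="already at the top"):
            lift_reticulation(net)


class TestGatherLeaves:
    def _canonical(self, n, k, seed):
        net = synth.random_orchard(synth.GeneratorConfig(n=n, k=k, seed=seed))
        walk = space._Walk(net)
        while top_structure(walk.net).k_top < k:
            space._lift(walk)
        for kp in neat_moves(top_structure(walk.net).orientation):
            walk.emit(space._reorient_move(walk.net, top_structure(walk.net), kp), {})
        return walk.net

    @pytest.mark.parametrize("seed", range(8))
    def test_anchor_becomes_child_of_head_within_bound(self, seed):
        n, k = 4 + seed % 3, 1 + seed % 2
        net = self._canonical(n, k, seed)
        ts = top_structure(net)
        x, y = ts.horizontal[-1]
        below = [net.taxa[v] for v in nx.descendants(net.graph, y) if v in net.taxa]
        anchor = sorted(below)[0]
        path_len = nx.shortest_path_length(net.graph, net.child(y),
                                           net.leaf_of(anchor)) + 1
        result, moves = gather_leaves(net, anchor)
        assert len(moves) == 2 * (path_len - 1)
        assert len(moves) <= 2 * n - 4
        ts2 = top_structure(result)
        assert ts2.k_top == k
        assert result.taxa[result.child(ts2.horizontal[-1][1])] == anchor

    def test_leaf_already_in_place_needs_no_moves(self):
        net = synth.top_stack_fixture(2, [NEAT, NEAT])
        ts = top_structure(net)
        anchor = net.taxa[net.child(ts.horizontal[-1][1])]
        _, moves = gather_leaves(net, anchor)
        assert moves == []

    def test_wrong_side_leaf_rejected(self):
        net = synth.top_stack_fixture(2, [NEAT, NEAT])
        ts = top_structure(net)
        x, _ = ts.horizontal[-1]
        wrong = net.taxa[space._other_child(net, x, ts.horizontal[-1][1])]
        with pytest.raises(ValueError, match="not below the head"):
            gather_leaves(net, wrong)


class TestTreePath:
    @pytest.mark.parametrize("n,seed", [(4, 1), (5, 2), (6, 3), (8, 4), (12, 5)])
    def test_intermediates_are_trees_and_bound_holds(self, n, seed):
        t1 = synth.random_orchard(synth.GeneratorConfig(n=n, k=0, seed=seed))
        t2 = synth.random_orchard(synth.GeneratorConfig(n=n, k=0, seed=seed + 100))
        path = tree_rnni_path(t1, t2)
        nets = path.replay(verify=True)
        assert is_isomorphic(nets[-1], t2)
        for net in nets:
            assert validate(net) == []
            assert reticulation_number(net) == 0
            assert net.taxon_set() == t1.taxon_set()
        assert len(path) <= 2 * n + n * math.ceil(math.log2(n))

    def test_isomorphic_inputs_allowed(self):
        t1 = synth.random_orchard(synth.GeneratorConfig(n=5, k=0, seed=9))
        path = tree_rnni_path(t1, t1.copy())
        nets = path.replay(verify=True)
        assert is_isomorphic(nets[-1], t1)

    def test_taxon_mismatch_raises(self):
        t1 = synth.random_orchard(synth.GeneratorConfig(n=4, k=0, seed=1))
        t2 = synth.random_orchard(
            synth.GeneratorConfig(n=4, k=0, seed=1, taxa=("w", "x", "y", "z")))
        with pytest.raises(ValueError, match="same taxa"):
            tree_rnni_path(t1, t2)


class TestOrchardPath:
    @pytest.mark.parametrize("seed", range(10))
    def test_certified_path_within_bound(self, seed):
        rng = random.Random(seed)
        n, k = rng.randint(4, 6), rng.randint(1, 2)
        n1 = synth.random_orchard(synth.GeneratorConfig(n=n, k=k, seed=300 + 2 * seed))
        n2 = synth.random_orchard(synth.GeneratorConfig(n=n, k=k, seed=301 + 2 * seed))
        path = orchard_path(n1, n2)
        nets = path.replay(verify=True)
        assert is_isomorphic(nets[-1], n2)
        assert len(path) <= diameter_bound(n, k)
        for net in nets:
            assert validate(net) == []

    def test_isomorphic_inputs(self):
        n1 = synth.random_orchard(synth.GeneratorConfig(n=4, k=1, seed=17))
        path = orchard_path(n1, n1.copy())
        assert is_isomorphic(path.replay(verify=True)[-1], n1)

    def test_mismatched_reticulation_number_raises(self):
        n1 = synth.random_orchard(synth.GeneratorConfig(n=4, k=1, seed=1))
        n2 = synth.random_orchard(synth.GeneratorConfig(n=4, k=2, seed=1))
        with pytest.raises(ValueError, match="reticulation numbers differ"):
            orchard_path(n1, n2)

    def test_non_orchard_input_raises(self, crown2):
        other = synth.random_orchard(
            synth.GeneratorConfig(n=2, k=1, seed=1, taxa=("x1", "x2")))
        with pytest.raises(ValueError, match="not orchard"):
            orchard_path(crown2, other)


class TestDiameterBound:
    def test_formula_values(self):
        assert diameter_bound(2, 0) == 6
        assert diameter_bound(13, 2) == 104 + 13 * 4 + 4 + 70

    def test_monotone_in_both_arguments(self):
        for n, k in itertools.product(range(2, 8), range(0, 4)):
            assert diameter_bound(n + 1, k) >= diameter_bound(n, k)
            assert diameter_bound(n, k + 1) >= diameter_bound(n, k)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            diameter_bound(1, 0)
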