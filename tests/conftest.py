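import itertools
from typing import Iterator, List

import pytest

from orchardnet.network import Network
from orchardnet.cherries import CherrySequence, reconstruct_from_sequence
from orchardnet import synth


@pytest.fixture(scope="session")
def gamma_net():
    """The 13-taxon, 2-reticulation gamma-proteobacteria network and its
    14-pair cherry-picking sequence."""
    return synth.gamma_proteobacteria_network()


@pytest.fixture(scope="session")
def crown2() -> Network:
    return synth.crown_network(2)


def triangle_case1() -> Network:
    """Triangle (w,p),(w,r),(p,r) whose apex parent q is a tree node off
    the top structure: root->v_rho->(q, z); q->(w, v); w->(p, r);
    p->(r, d); r->c."""
    arcs = [(0, 1), (1, 2), (1, 10), (2, 3), (2, 11), (3, 4), (3, 5),
            (4, 5), (4, 12), (5, 13)]
    return Network.from_arcs(arcs, {10: "z", 11: "v", 12: "d", 13: "c"}).check()


def triangle_case2_head() -> Network:
    """Triangle below the head y of the lowest top horizontal arc:
    root->v_rho->(x, y); x->(y, a); y->w; w->(p, r); p->(r, d); r->c."""
    arcs = [(0, 1), (1, 2), (1, 3), (2, 3), (2, 10), (3, 4), (4, 5),
            (4, 6), (5, 6), (5, 11), (6, 12)]
    return Network.from_arcs(arcs, {10: "a", 11: "d", 12: "c"}).check()


def triangle_case2_tail() -> Network:
    """Triangle below the tail x of the lowest top horizontal arc (one
    extra reorientation needed): root->v_rho->(x, y); x->(y, w);
    y->b; w->(p, r); p->(r, d); r->c."""
    arcs = [(0, 1), (1, 2), (1, 3), (2, 3), (2, 4), (3, 10), (4, 5),
            (4, 6), (5, 6), (5, 11), (6, 12)]
    return Network.from_arcs(arcs, {10: "b", 11: "d", 12: "c"}).check()


# orchard network that admits no all-but-one labelling (searched witness;
# no closed-form example of this phenomenon is available)
ALLBUTONE_WITNESS = "((((((t1,t2))#H2,t3))#H1,(#H1,(#H2,#H1))));"


def exhaustive_sequences(taxa: List[str], k: int) -> Iterator[CherrySequence]:
    """Every cherry-picking sequence on the given taxa with exactly k
    reticulated pairs, enumerated in construction order."""
    n = len(taxa)
    m = n - 1 + k

    def rec(done, present, remaining_new, retic_left, pos):
        if pos > m:
            if not remaining_new and not retic_left:
                yield list(done)
            return
        steps_left = m - pos + 1
        if remaining_new:
            x = remaining_new[0]
            for y in present:
                yield from rec(done + [(x, y)], present + [x],
                               remaining_new[1:], retic_left, pos + 1)
        if retic_left and len(present) >= 2 and steps_left > len(remaining_new):
            for x, y in itertools.permutations(present, 2):
                yield from rec(done + [(x, y)], present,
                               remaining_new, retic_left - 1, pos + 1)

    for final in taxa:
        rest = [t for t in taxa if t != final]
        for order in itertools.permutations(rest):
            for cons in rec([], [final], list(order), k, 1):
                yield CherrySequence.from_pairs(list(reversed(cons)), final)


def exhaustive_networks(taxa: List[str], k: int) -> Iterator[Network]:
    for seq in exhaustive_sequences(taxa, k):
        yield reconstruct_from_sequence(seq)
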