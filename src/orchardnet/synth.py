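"""Seeded generators and worked-example fixtures.

Random orchard networks are produced generatively: a random valid
cherry-picking sequence is drawn and replayed in reverse, which yields
a binary orchard network with exactly the requested number of leaves
and reticulations.  A separate generator adds random reticulation arcs
to a random tree and serves as a negative control (its output need not
be orchard).  All randomness is integer-only and driven by a single
seed, so identical configurations reproduce isomorphic networks across
runs and platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx

from orchardnet.network import Network
from orchardnet.cherries import CherrySequence, ReduciblePair, reconstruct_from_sequence


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    k: int
    seed: int
    taxa: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.n < 1 or self.k < 0:
            raise ValueError(f"need n >= 1 and k >= 0, got (n={self.n}, k={self.k})")
        if self.n == 1 and self.k > 0:
            raise ValueError("a single-leaf binary network cannot carry reticulations")
        if self.taxa is not None and len(self.taxa) != self.n:
            raise ValueError(f"taxa list has {len(self.taxa)} names for n={self.n}")

    def taxon_names(self) -> List[str]:
        if self.taxa is not None:
            return list(self.taxa)
        width = len(str(self.n))
        return [f"t{i:0{width}d}" for i in range(1, self.n + 1)]


def random_sequence(cfg: GeneratorConfig) -> CherrySequence:
    """A random valid cherry-picking sequence on n taxa with k
    reticulated pairs.

    Built in reverse-reduction (construction) order: n - 1 steps each
    introduce a new taxon as a cherry, k steps draw an ordered pair of
    already-present taxa as a reticulated cherry; the k reticulated
    steps are placed uniformly among the slots after the first cherry
    step, where at least two leaves are present.
    """
    rng = random.Random(cfg.seed)
    names = cfg.taxon_names()
    if cfg.n < 2:
        raise ValueError("a cherry-picking sequence needs at least 2 taxa")
    order = list(names)
    rng.shuffle(order)
    final, newcomers = order[0], order[1:]
    m = cfg.n - 1 + cfg.k
    retic_slots = set(rng.sample(range(2, m + 1), cfg.k)) if cfg.k else set()
    present = [final]
    construction: List[ReduciblePair] = []
    next_new = iter(newcomers)
    for step in range(1, m + 1):
        if step in retic_slots:
            x, y = rng.sample(present, 2)
            construction.append(ReduciblePair(x, y))
        else:
            x = next(next_new)
            y = present[rng.randrange(len(present))]
            construction.append(ReduciblePair(x, y))
            present.append(x)
    return CherrySequence(list(reversed(construction)), final)


def random_orchard(cfg: GeneratorConfig) -> Network:
    """A seeded random binary orchard network with n leaves and k
    reticulations, reconstructed from a random cherry-picking sequence."""
    if cfg.n == 1:
        return Network.from_arcs([(0, 1)], {1: cfg.taxon_names()[0]})
    return reconstruct_from_sequence(random_sequence(cfg))


def crown_network(m: int = 2) -> Network:
    """A tree-based network containing a crown on 2m nodes; it admits
    no HGT-consistent labelling and is not orchard.

    Tree nodes u_1..u_m hang from a caterpillar below the root child;
    reticulations v_1..v_m receive arcs (u_i, v_i) and (u_i, v_{i+1})
    cyclically, each with a pendant leaf.
    """
    if m < 2:
        raise ValueError(f"a crown needs m >= 2, got {m}")
    net = Network.from_arcs([(0, 1)], {})
    g = net.graph
    nxt = 2
    us: List[int] = []
    anchor = 1
    for i in range(m):
        if i < m - 2:
            u, w = nxt, nxt + 1
            nxt += 2
            g.add_edge(anchor, u)
            g.add_edge(anchor, w)
            us.append(u)
            anchor = w
        else:
            u = nxt
            nxt += 1
            g.add_edge(anchor, u)
            us.append(u)
    vs = list(range(nxt, nxt + m))
    nxt += m
    for i in range(m):
        g.add_edge(us[i], vs[i])
        g.add_edge(us[i], vs[(i + 1) % m])
    for i, v in enumerate(vs):
        leaf = nxt
        nxt += 1
        g.add_edge(v, leaf)
        net.taxa[leaf] = f"x{i + 1}"
    return net.check()


GAMMA_PROTEOBACTERIA_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("1", "2"), ("3", "4"), ("2", "4"), ("5", "6"), ("4", "6"),
    ("7", "8"), ("9", "8"), ("10", "6"), ("6", "8"), ("8", "9"),
    ("9", "10"), ("11", "12"), ("12", "13"), ("10", "13"),
)


def gamma_proteobacteria_network() -> Tuple[Network, CherrySequence]:
    """A classic 13-taxon gamma-proteobacteria phylogeny with two
    reticulate events, reconstructed from its known 14-pair
    cherry-picking sequence."""
    seq = CherrySequence.from_pairs(GAMMA_PROTEOBACTERIA_PAIRS, final_taxon="13")
    return reconstruct_from_sequence(seq), seq


def top_stack_fixture(k: int, orientation: Sequence[str]) -> Network:
    """A binary orchard network on two taxa with exactly k reticulations
    at the top in the requested orientation pattern (``"neat"``: the
    horizontal arc points from the a-path to the b-path)."""
    if k < 1:
        raise ValueError(f"need k >= 1, got {k}")
    if len(orientation) != k:
        raise ValueError(f"orientation pattern has {len(orientation)} entries for k={k}")
    net = Network.from_arcs([(0, 1)], {})
    g = net.graph
    a = [2 + i for i in range(k)]
    b = [2 + k + i for i in range(k)]
    g.add_edge(1, a[0])
    g.add_edge(1, b[0])
    for i in range(k - 1):
        g.add_edge(a[i], a[i + 1])
        g.add_edge(b[i], b[i + 1])
    for i, o in enumerate(orientation):
        if o == "neat":
            g.add_edge(a[i], b[i])
        elif o == "reversed":
            g.add_edge(b[i], a[i])
        else:
            raise ValueError(f"unknown orientation entry {o!r}")
    leaf_a, leaf_b = 2 + 2 * k, 3 + 2 * k
    g.add_edge(a[-1], leaf_a)
    g.add_edge(b[-1], leaf_b)
    net.taxa[leaf_a] = "a"
    net.taxa[leaf_b] = "b"
    return net.check()


def random_network(cfg: GeneratorConfig, max_tries: int = 10_000) -> Network:
    """A random binary tree with k random reticulation arcs inserted;
    not necessarily orchard (negative-control generator)."""
    rng = random.Random(cfg.seed)
    names = cfg.taxon_names()
    net = Network.from_arcs([(0, 1)], {1: names[0]})
    g = net.graph
    nxt = 2
    for name in names[1:]:
        arcs = sorted(g.edges())
        u, v = arcs[rng.randrange(len(arcs))]
        mid, leaf = nxt, nxt + 1
        nxt += 2
        g.remove_edge(u, v)
        g.add_edge(u, mid)
        g.add_edge(mid, v)
        g.add_edge(mid, leaf)
        net.taxa[leaf] = name
    inserted = 0
    for _ in range(max_tries):
        if inserted == cfg.k:
            break
        arcs = sorted(g.edges())
        (u1, v1), (u2, v2) = (arcs[rng.randrange(len(arcs))] for _ in range(2))
        if (u1, v1) == (u2, v2):
            continue
        s, t = nxt, nxt + 1
        g.remove_edge(u1, v1)
        g.add_edge(u1, s)
        g.add_edge(s, v1)
        g.remove_edge(u2, v2)
        g.add_edge(u2, t)
        g.add_edge(t, v2)
        g.add_edge(s, t)
        if nx.is_directed_acyclic_graph(g):
            nxt += 2
            inserted += 1
        else:  # roll back
            g.remove_node(s)
            g.remove_node(t)
            g.add_edge(u1, v1)
            g.add_edge(u2, v2)
    if inserted < cfg.k:
        raise RuntimeError(
            f"could not place {cfg.k} reticulation arcs after {max_tries} attempts"
        )
    return net.check()
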