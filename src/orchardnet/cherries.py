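"""Cherry-picking machinery for orchard networks.

A *cherry* (x, y) is an ordered pair of leaves with a common parent; a
*reticulated cherry* (x, y) has the parent of x a reticulation that is a
child of the parent of y.  Repeatedly *reducing* such pairs either
deletes the leaf x (cherry) or the reticulation arc (p_y, p_x)
(reticulated cherry), suppressing any resulting indegree-1/outdegree-1
nodes.  A network is *orchard* when some sequence of reductions leaves a
single-leaf tree; greedily picking any reducible pair is safe because
reducing a pair of an orchard network yields an orchard network.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from orchardnet.network import Network, reticulation_number

CHERRY = "cherry"
RETICULATED = "reticulated_cherry"


@dataclass(frozen=True)
class ReduciblePair:
    x: str
    y: str
    kind: Optional[str] = None  # CHERRY, RETICULATED, or unknown on input

    def __post_init__(self):
        if self.x == self.y:
            raise ValueError(f"pair must name two distinct taxa, got ({self.x}, {self.x})")

    def __iter__(self):
        return iter((self.x, self.y))


@dataclass
class CherrySequence:
    """Ordered reducible pairs; ``final_taxon`` is the surviving leaf.

    When not given, the final taxon is inferred as the second element of
    the last pair, matching the reverse-reattachment construction.
    """

    pairs: List[ReduciblePair] = field(default_factory=list)
    final_taxon: Optional[str] = None

    def __post_init__(self):
        if self.final_taxon is None and self.pairs:
            self.final_taxon = self.pairs[-1].y

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @classmethod
    def from_pairs(cls, pairs, final_taxon: Optional[str] = None) -> "CherrySequence":
        return cls([p if isinstance(p, ReduciblePair) else ReduciblePair(*p) for p in pairs],
                   final_taxon)

    @classmethod
    def parse(cls, text: str) -> "CherrySequence":
        """Parse either one "x,y" pair per line or inline "(x, y)(u, v)..."."""
        text = text.strip()
        pairs: List[Tuple[str, str]] = []
        if "(" in text:
            for m in re.finditer(r"\(\s*([^,()]+?)\s*,\s*([^,()]+?)\s*\)", text):
                pairs.append((m.group(1), m.group(2)))
        else:
            for line in text.splitlines():
                line = line.strip()
                if not line:
                    continue
                x, y = (part.strip() for part in line.split(","))
                pairs.append((x, y))
        return cls.from_pairs(pairs)

    def render(self) -> str:
        return "".join(f"({p.x}, {p.y})" for p in self.pairs)


def find_reducible_pairs(network: Network) -> List[ReduciblePair]:
    """All reducible pairs, sorted by (x, y) with cherries before
    reticulated cherries; cherries appear in both orders."""
    g = network.graph
    leaf_parent = {network.taxa[v]: network.parent(v) for v in network.leaves}
    out: List[ReduciblePair] = []
    names = sorted(leaf_parent)
    for x in names:
        for y in names:
            if x == y:
                continue
            px, py = leaf_parent[x], leaf_parent[y]
            if px == py:
                out.append(ReduciblePair(x, y, CHERRY))
            elif g.in_degree(px) >= 2 and g.has_edge(py, px):
                out.append(ReduciblePair(x, y, RETICULATED))
    out.sort(key=lambda p: (p.x, p.y, p.kind != CHERRY))
    return out


def _classify(network: Network, x: str, y: str) -> Optional[str]:
    g = network.graph
    try:
        lx, ly = network.leaf_of(x), network.leaf_of(y)
    except KeyError:
        return None
    px, py = network.parent(lx), network.parent(ly)
    if px == py:
        return CHERRY
    if g.in_degree(px) >= 2 and g.has_edge(py, px):
        return RETICULATED
    return None


def _suppress_if_unary(network: Network, v) -> None:
    g = network.graph
    if v in g and g.in_degree(v) == 1 and g.out_degree(v) == 1:
        (p,), (c,) = g.predecessors(v), g.successors(v)
        g.remove_node(v)
        if g.has_edge(p, c):
            raise ValueError(f"suppressing node {v} would create a parallel arc {p}->{c}")
        g.add_edge(p, c)


def reduce_pair(network: Network, pair: ReduciblePair) -> Network:
    """Reduce one currently-reducible pair; raises if it is not reducible."""
    kind = _classify(network, pair.x, pair.y)
    if kind is None:
        raise ValueError(f"({pair.x}, {pair.y}) is not a reducible pair")
    if pair.kind is not None and pair.kind != kind:
        raise ValueError(
            f"({pair.x}, {pair.y}) is a {kind}, but the pair is declared {pair.kind}"
        )
    out = network.copy()
    g = out.graph
    lx, ly = out.leaf_of(pair.x), out.leaf_of(pair.y)
    px, py = out.parent(lx), out.parent(ly)
    if kind == CHERRY:
        g.remove_node(lx)
        del out.taxa[lx]
        _suppress_if_unary(out, px)
    else:
        g.remove_edge(py, px)
        _suppress_if_unary(out, px)
        _suppress_if_unary(out, py)
    return out


def reduce_by_sequence(network: Network, seq: CherrySequence, strict: bool = True) -> Network:
    """Apply the pairs of ``seq`` in order; returns the reduced network.

    In strict mode (default) every pair must be reducible when reached;
    in lenient mode inapplicable pairs are skipped.
    """
    current = network
    for i, pair in enumerate(seq):
        if _classify(current, pair.x, pair.y) is None:
            if strict:
                raise ValueError(
                    f"pair #{i} ({pair.x}, {pair.y}) is not reducible at its step"
                )
            continue
        current = reduce_pair(current, pair)
    return current


def is_orchard(network: Network) -> Tuple[bool, Optional[CherrySequence]]:
    """Greedy orchard test; returns the recorded reduction sequence.

    At each step the lexicographically smallest reducible pair is picked
    (cherries preferred on ties), which is safe because orchardness is
    closed under reduction of any reducible pair.  For a binary orchard
    network with n leaves and k reticulations the recorded sequence has
    the minimal length n + k - 1.
    """
    current = network
    recorded: List[ReduciblePair] = []
    while True:
        if len(current.leaves) == 1 and reticulation_number(current) == 0:
            final = current.taxa[current.leaves[0]]
            return True, CherrySequence(recorded, final)
        pairs = find_reducible_pairs(current)
        if not pairs:
            return False, None
        recorded.append(pairs[0])
        current = reduce_pair(current, pairs[0])


def reconstruct_from_sequence(seq: CherrySequence) -> Network:
    """Rebuild the unique binary network reduced by ``seq``.

    Starting from the one-leaf tree on the final taxon, the pairs are
    reattached in reverse order: a pair whose first taxon is absent adds
    it as a cherry on the second taxon's pendant arc; a pair whose first
    taxon is present adds a reticulation arc from the second taxon's
    pendant arc into the first taxon's pendant arc.
    """
    if not seq.pairs:
        raise ValueError("cannot reconstruct from an empty sequence")
    final = seq.final_taxon
    if final is None:
        raise ValueError("sequence has no final taxon")
    net = Network.from_arcs([(0, 1)], {1: final})
    for i in range(len(seq.pairs) - 1, -1, -1):
        pair = seq.pairs[i]
        x, y = pair.x, pair.y
        if x == y:
            raise ValueError(f"pair #{i} names the same taxon twice: ({x}, {y})")
        g = net.graph
        try:
            ly = net.leaf_of(y)
        except KeyError:
            raise ValueError(
                f"pair #{i} ({x}, {y}): taxon {y!r} absent at its reverse step"
            ) from None
        try:
            lx: Optional[int] = net.leaf_of(x)
        except KeyError:
            lx = None
        if lx is None:
            # cherry reattachment on the arc into y
            t = net.fresh_node()
            leaf = t + 1
            p = net.parent(ly)
            g.remove_edge(p, ly)
            g.add_edge(p, t)
            g.add_edge(t, ly)
            g.add_edge(t, leaf)
            net.taxa[leaf] = x
        else:
            # reticulated-cherry reattachment: new reticulation above x,
            # fed from a new tree node above y
            px = net.fresh_node()
            p = net.parent(lx)
            g.remove_edge(p, lx)
            g.add_edge(p, px)
            g.add_edge(px, lx)
            py = net.fresh_node()
            q = net.parent(ly)
            g.remove_edge(q, ly)
            g.add_edge(q, py)
            g.add_edge(py, ly)
            g.add_edge(py, px)
    return net
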