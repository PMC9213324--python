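"""rSPR and rNNI rearrangement moves on binary networks.

The move (p, x, c) --e--> (z, w) detaches the arc triple around x and
regrafts it: the arcs (p, x), (x, c), (z, w) are replaced by (p, c),
(z, x), (x, w), where e is the third arc at x (keeping x attached to
its far endpoint y) and p, c are the parent and child of x other than
y.  When e = (y, x) the head of e is being moved; when e = (x, y) the
tail.  The move is rNNI (local) iff {p, c} and {z, w} intersect.  A
move is *valid* when the resulting graph is again a network; the only
possible failures are a directed cycle or a parallel arc, and a graph
that admits an HGT-consistent labelling can have neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx

from orchardnet.network import Network, Node, Arc, validate, is_isomorphic


@dataclass(frozen=True)
class RNNIMove:
    p: Node
    x: Node
    c: Node
    e: Arc
    z: Node
    w: Node

    @property
    def moved_end(self) -> str:
        """'head' if e = (y, x), 'tail' if e = (x, y)."""
        if self.e[1] == self.x:
            return "head"
        if self.e[0] == self.x:
            return "tail"
        raise ValueError(f"arc e={self.e} is not incident to x={self.x}")

    @property
    def is_rnni(self) -> bool:
        return bool({self.p, self.c} & {self.z, self.w})

    def inverse(self) -> "RNNIMove":
        """The move undoing this one on the result network."""
        return RNNIMove(p=self.z, x=self.x, c=self.w, e=self.e, z=self.p, w=self.c)

    def render(self) -> str:
        """Human-readable arrow notation."""
        return f"({self.p},{self.x},{self.c}) --{self.e}--> ({self.z},{self.w})"

    def to_json(self) -> dict:
        return {"p": self.p, "x": self.x, "c": self.c,
                "e": list(self.e), "z": self.z, "w": self.w}

    @classmethod
    def from_json(cls, d: dict) -> "RNNIMove":
        return cls(p=d["p"], x=d["x"], c=d["c"], e=tuple(d["e"]), z=d["z"], w=d["w"])


@dataclass
class MoveResult:
    graph: Optional[Network]  # None when the move would create a parallel arc
    valid: bool
    violation: Optional[str]  # None, "cycle", or "parallel_arc"


def _check_incidences(network: Network, m: RNNIMove) -> None:
    g = network.graph
    for arc, name in [((m.p, m.x), "(p,x)"), ((m.x, m.c), "(x,c)"), ((m.z, m.w), "(z,w)")]:
        if not g.has_edge(*arc):
            raise ValueError(f"move names absent arc {name}={arc}")
    if not g.has_edge(*m.e):
        raise ValueError(f"move names absent arc e={m.e}")
    if m.x not in m.e:
        raise ValueError(f"arc e={m.e} is not incident to x={m.x}")
    y = m.e[0] if m.e[1] == m.x else m.e[1]
    if y in (m.p, m.c):
        raise ValueError(f"e={m.e} must be the third arc at x, avoiding p and c")
    deg = g.in_degree(m.x) + g.out_degree(m.x)
    if deg != 3:
        raise ValueError(f"x={m.x} has total degree {deg}, expected 3")


def apply_move(network: Network, m: RNNIMove) -> MoveResult:
    """Apply a move atomically and validate the outcome.

    Raises on broken incidences; returns an invalid :class:`MoveResult`
    (never a mutated network) when the replacement would create a
    parallel arc or a directed cycle.  Degenerate targets
    (z, w) = (p, x) or (x, c) are rejected as invalid.
    """
    _check_incidences(network, m)
    if (m.z, m.w) in ((m.p, m.x), (m.x, m.c)):
        raise ValueError(f"degenerate move target (z,w)={(m.z, m.w)} overlaps the moved frame")
    g = network.graph.copy()
    g.remove_edge(m.p, m.x)
    g.remove_edge(m.x, m.c)
    g.remove_edge(m.z, m.w)
    for u, v in [(m.p, m.c), (m.z, m.x), (m.x, m.w)]:
        if u == v or g.has_edge(u, v):
            return MoveResult(graph=None, valid=False, violation="parallel_arc")
        g.add_edge(u, v)
    result = Network(g, dict(network.taxa))
    if not nx.is_directed_acyclic_graph(g):
        return MoveResult(graph=result, valid=False, violation="cycle")
    report = validate(result)
    if report:
        # degrees are preserved by construction; anything here is a defect
        raise AssertionError("move produced an acyclic non-network: " + "; ".join(report))
    return MoveResult(graph=result, valid=True, violation=None)


def is_valid_by_labelling(network: Network, m: RNNIMove, t_candidate: Dict) -> bool:
    """Certify a move by exhibiting an HGT-consistent labelling of the
    result; a certified move is always valid."""
    from orchardnet.labelling import verify_labelling

    outcome = apply_move(network, m)
    if outcome.graph is None:
        return False  # a graph with parallel arcs admits no HGT-consistent labelling
    try:
        report = verify_labelling(outcome.graph, t_candidate)
    except ValueError:
        return False
    return not report


def enumerate_moves(network: Network, rnni_only: bool = True) -> List[RNNIMove]:
    """All applicable (not necessarily valid) moves over the incidence
    tuples of the network."""
    g = network.graph
    moves: List[RNNIMove] = []
    for x in g:
        indeg, outdeg = g.in_degree(x), g.out_degree(x)
        if indeg + outdeg != 3:
            continue
        frames: List[Tuple[Node, Node, Arc]] = []
        if indeg == 1 and outdeg == 2:
            p = next(g.predecessors(x))
            c1, c2 = sorted(g.successors(x))
            frames.append((p, c1, (x, c2)))
            frames.append((p, c2, (x, c1)))
        else:  # reticulation: indeg 2, outdeg 1
            p1, p2 = sorted(g.predecessors(x))
            c = next(g.successors(x))
            frames.append((p1, c, (p2, x)))
            frames.append((p2, c, (p1, x)))
        for p, c, e in frames:
            for z, w in g.edges():
                if (z, w) in ((p, x), (x, c)):
                    continue
                if rnni_only and not ({p, c} & {z, w}):
                    continue
                moves.append(RNNIMove(p=p, x=x, c=c, e=e, z=z, w=w))
    return moves


def rnni_neighbors(network: Network) -> List[Tuple[RNNIMove, Network]]:
    """All valid rNNI moves with their results, deduplicated up to
    isomorphism of the result."""
    out: List[Tuple[RNNIMove, Network]] = []
    for m in enumerate_moves(network, rnni_only=True):
        res = apply_move(network, m)
        if not res.valid:
            continue
        if any(is_isomorphic(res.graph, seen) for _, seen in out):
            continue
        out.append((m, res.graph))
    return out
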