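"""Connectivity of binary orchard-network space under rNNI moves.

The constructive pipeline transforms any binary orchard network into a
canonical form — all reticulations stacked neatly at the top, a chosen
anchor leaf directly below the head of the lowest horizontal arc, and
the remaining taxa in a sorted pendant caterpillar — and concatenates
the two half-paths.  Every emitted move carries an HGT-consistent
labelling of its result as a certificate, so every intermediate graph
is a valid binary orchard network.  The total length is bounded by
4kn + n*ceil(log2 n) + 2k + 6n - 8 for n leaves and k reticulations;
paths are upper-bound constructions, never claimed minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from orchardnet.network import (
    Network,
    Node,
    Arc,
    validate,
    is_binary,
    reticulation_number,
    is_isomorphic,
)
from orchardnet.cherries import is_orchard
from orchardnet.labelling import (
    HGTLabelling,
    verify_labelling,
    labelling_from_sequence,
)
from orchardnet.moves import RNNIMove, apply_move

NEAT = "neat"
REVERSED = "reversed"


@dataclass
class TopStructure:
    """The maximal stack of reticulations directly below the root child.

    ``a_path`` and ``b_path`` start at the root child v_rho and descend
    one node per level; ``horizontal`` holds the level arcs (x_i, y_i)
    with {x_i, y_i} = {a_i, b_i}.  The a-side is canonically the side
    carrying the tail of the highest horizontal arc, so ``orientation``
    (``"neat"`` when x_i lies on the a-path) always starts neat when
    k_top >= 1.
    """

    k_top: int
    a_path: List[Node]  # [v_rho, a_1, ..., a_k]
    b_path: List[Node]
    horizontal: List[Arc]
    orientation: List[str]

    def top_reticulations(self) -> Set[Node]:
        return {y for _, y in self.horizontal}


@dataclass
class MovePath:
    """A certified rNNI walk: replaying ``moves`` from ``source`` visits
    only valid binary orchard networks, witnessed by ``certificates``
    (one verified HGT-consistent labelling per resulting graph)."""

    source: Network
    moves: List[RNNIMove] = field(default_factory=list)
    certificates: List[HGTLabelling] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.moves)

    def replay(self, verify: bool = True) -> List[Network]:
        """All intermediate networks, source first; optionally check
        validity and certificates at every step."""
        nets = [self.source]
        for i, m in enumerate(self.moves):
            res = apply_move(nets[-1], m)
            if res.graph is None or (verify and not res.valid):
                raise ValueError(f"move #{i} is not valid when replayed")
            if verify and self.certificates:
                report = verify_labelling(res.graph, self.certificates[i])
                if report:
                    raise ValueError(
                        f"certificate for move #{i} fails: " + "; ".join(report)
                    )
            nets.append(res.graph)
        return nets


def diameter_bound(n: int, k: int) -> int:
    """Upper bound on the rNNI diameter of the space of binary orchard
    networks with n leaves and k reticulations."""
    if n < 2:
        raise ValueError(f"need at least 2 leaves, got n={n}")
    if k < 0:
        raise ValueError(f"reticulation count must be nonnegative, got k={k}")
    return 4 * k * n + n * math.ceil(math.log2(n)) + 2 * k + 6 * n - 8


def top_structure(network: Network) -> TopStructure:
    """Identify the maximal top structure of a binary orchard network.

    Descends greedily from the root child, extending level by level as
    long as the two path continuations are distinct and joined by an
    arc; maximality then follows from the definition's stopping clause.
    """
    g = network.graph
    v_rho = network.child(network.root)
    empty = TopStructure(0, [v_rho], [v_rho], [], [])
    if g.out_degree(v_rho) != 2:
        return empty
    c1, c2 = sorted(g.successors(v_rho))
    if g.has_edge(c1, c2):
        x1, y1 = c1, c2
    elif g.has_edge(c2, c1):
        x1, y1 = c2, c1
    else:
        return empty
    a_path, b_path = [v_rho, x1], [v_rho, y1]
    horizontal: List[Arc] = [(x1, y1)]
    while True:
        a_i, b_i = a_path[-1], b_path[-1]
        x_i, y_i = horizontal[-1]
        next_a = _path_continuation(network, a_i, y_i if a_i == x_i else None)
        next_b = _path_continuation(network, b_i, y_i if b_i == x_i else None)
        if next_a is None or next_b is None or next_a == next_b:
            break
        if next_a in a_path + b_path or next_b in a_path + b_path:
            break
        if g.has_edge(next_a, next_b):
            arc = (next_a, next_b)
        elif g.has_edge(next_b, next_a):
            arc = (next_b, next_a)
        else:
            break
        if g.in_degree(arc[1]) != 2:
            break
        a_path.append(next_a)
        b_path.append(next_b)
        horizontal.append(arc)
    orientation = [NEAT if x == a else REVERSED
                   for (x, _), a in zip(horizontal, a_path[1:])]
    return TopStructure(len(horizontal), a_path, b_path, horizontal, orientation)


def _path_continuation(network: Network, node: Node, horiz_head: Optional[Node]) -> Optional[Node]:
    """The child of a top-structure node along its own path: the only
    child of a reticulation, or the tree-node child avoiding the
    horizontal arc's head."""
    g = network.graph
    children = list(g.successors(node))
    if g.in_degree(node) >= 2:
        nxt = children[0] if children else None
    else:
        rest = [c for c in children if c != horiz_head]
        nxt = rest[0] if len(rest) == 1 else None
    if nxt is None or g.out_degree(nxt) == 0:
        return None
    return nxt


def neat_moves(orientation: Sequence[str]) -> List[int]:
    """Minimal schedule of prefix flips making an orientation pattern
    all-neat.

    Each entry of the returned list is a prefix length k'; flipping the
    highest k' arcs reverses entries 1..k' of the pattern.  Scanning
    from the lowest arc upward and flipping at each boundary into a
    reversed block is optimal: any flip schedule must touch every such
    boundary.
    """
    flips: List[int] = []
    parity = 0
    for i in range(len(orientation) - 1, -1, -1):
        effective = orientation[i] if parity % 2 == 0 else _flip(orientation[i])
        if effective == REVERSED:
            flips.append(i + 1)
            parity += 1
        elif effective != NEAT:
            raise ValueError(f"unknown orientation entry {orientation[i]!r}")
    return flips


def _flip(entry: str) -> str:
    return REVERSED if entry == NEAT else NEAT


def _flip_prefix(pattern: List[str], k_prime: int) -> List[str]:
    return [_flip(p) if i < k_prime else p for i, p in enumerate(pattern)]


def _normalize_pattern(pattern: List[str]) -> List[str]:
    """Patterns are meaningful up to swapping the two path names."""
    if pattern and pattern[0] == REVERSED:
        return [_flip(p) for p in pattern]
    return list(pattern)


def reorient_prefix(network: Network, k_prime: int) -> Tuple[Network, RNNIMove]:
    """Reorient the highest k' horizontal arcs at the top with one rNNI
    move.

    The move detaches the level-k' reticulation's continuation and
    crosses it with the opposite path's continuation, which exchanges
    everything hanging below level k' between the two sides; the result
    is isomorphic to the network with arcs 1..k' reversed.  Correctness
    is enforced a posteriori: the result must be a valid orchard network
    whose recomputed orientation pattern is the flipped one.
    """
    ts = top_structure(network)
    if not 1 <= k_prime <= ts.k_top:
        raise ValueError(f"k'={k_prime} exceeds k_top={ts.k_top}")
    move = _reorient_move(network, ts, k_prime)
    res = apply_move(network, move)
    if not res.valid:
        raise AssertionError(f"reorientation move is invalid: {res.violation}")
    new_ts = top_structure(res.graph)
    expected = _normalize_pattern(_flip_prefix(ts.orientation, k_prime))
    if new_ts.k_top != ts.k_top or _normalize_pattern(new_ts.orientation) != expected:
        raise AssertionError(
            f"reorientation produced pattern {new_ts.orientation} "
            f"(k_top={new_ts.k_top}), expected flip of top {k_prime}"
        )
    ok, _ = is_orchard(res.graph)
    if not ok:
        raise AssertionError("reorientation left orchard space")
    return res.graph, move


def _reorient_move(network: Network, ts: TopStructure, k_prime: int) -> RNNIMove:
    x, y = ts.horizontal[k_prime - 1]
    y_side = ts.a_path if ts.a_path[k_prime] == y else ts.b_path
    prev = y_side[k_prime - 1]
    c = network.child(y)  # continuation (or pendant root) below the head
    w = next(ch for ch in network.children(x) if ch != y)
    return RNNIMove(p=x, x=y, c=c, e=(prev, y), z=x, w=w)


# ---------------------------------------------------------------------------
# moving reticulations to the top
# ---------------------------------------------------------------------------


def _constructive_labelling(network: Network) -> HGTLabelling:
    ok, seq = is_orchard(network)
    if not ok:
        raise ValueError("network is not orchard")
    return labelling_from_sequence(network, seq)


def _just_above(t: HGTLabelling, value: Fraction) -> Fraction:
    """A fresh label strictly between ``value`` and the next distinct
    label; collides with no existing label, so new equalities arise only
    where deliberately assigned."""
    above = [v for v in set(t.values()) if v > value]
    return (value + min(above)) / 2 if above else value + 1


def _just_below(t: HGTLabelling, value: Fraction) -> Fraction:
    below = [v for v in set(t.values()) if v < value]
    return (value + max(below)) / 2 if below else value - 1


class _Walk:
    """Mutable state of a certified move sequence: the current network,
    a maintained exact labelling, and the accumulated moves."""

    def __init__(self, network: Network, t: Optional[HGTLabelling] = None):
        self.net = network
        self.t = dict(t) if t is not None else _constructive_labelling(network)
        report = verify_labelling(self.net, self.t)
        if report:
            raise ValueError("initial labelling invalid: " + "; ".join(report))
        self.initial_t: HGTLabelling = dict(self.t)
        self.moves: List[RNNIMove] = []
        self.certificates: List[HGTLabelling] = []

    def emit_relabel(self, move: RNNIMove) -> None:
        """Apply a move and certify it with a freshly derived
        constructive labelling instead of an incremental update."""
        res = apply_move(self.net, move)
        if not res.valid:
            raise AssertionError(
                f"constructed move {move.render()} invalid: {res.violation}"
            )
        self.net = res.graph
        self.t = _constructive_labelling(self.net)
        self.moves.append(move)
        self.certificates.append(dict(self.t))

    def emit(self, move: RNNIMove, updates: Dict[Node, Fraction]) -> None:
        res = apply_move(self.net, move)
        if not res.valid:
            raise AssertionError(
                f"constructed move {move.render()} invalid: {res.violation}"
            )
        self.t.update(updates)
        report = verify_labelling(res.graph, self.t)
        if report:
            raise AssertionError(
                f"labelling update for {move.render()} fails: " + "; ".join(report)
            )
        self.net = res.graph
        self.moves.append(move)
        self.certificates.append(dict(self.t))


def _contemporaneous_parent(walk_t: HGTLabelling, network: Network, r: Node) -> Tuple[Node, Node]:
    """(p, u): the parent with equal label, and the other parent."""
    pa, pb = network.parents(r)
    if walk_t[pa] == walk_t[r]:
        return pa, pb
    if walk_t[pb] == walk_t[r]:
        return pb, pa
    raise AssertionError(f"reticulation {r} has no contemporaneous parent")


def _other_child(network: Network, v: Node, avoid: Node) -> Node:
    rest = [c for c in network.children(v) if c != avoid]
    if len(rest) != 1:
        raise AssertionError(f"node {v} has no unique child avoiding {avoid}")
    return rest[0]


def _head_up(walk: _Walk, r: Node) -> None:
    """Move the head of the horizontal arc into r one step up (the case
    t(u) > t(q): the non-contemporaneous parent u is a tree node)."""
    net, t = walk.net, walk.t
    p, u = _contemporaneous_parent(t, net, r)
    s = net.parent(u)
    v = _other_child(net, u, r)
    c = net.child(r)
    if v == c:
        raise AssertionError("u and r share a child; r was not the lowest reticulation")
    base = t[u]
    newval = _just_above(t, base)
    updates = {p: base, r: base, u: newval}
    if net.is_reticulation(v) and t[v] == base:
        updates[v] = newval  # a horizontal child of u stays contemporaneous
    walk.emit(RNNIMove(p=u, x=r, c=c, e=(p, r), z=s, w=u), updates)


def _tail_up(walk: _Walk, r: Node) -> None:
    """Move the tail of the horizontal arc into r one step up (the case
    t(q) > t(u): the grandparent q of r through p is a tree node)."""
    net, t = walk.net, walk.t
    p, u = _contemporaneous_parent(t, net, r)
    q = net.parent(p)
    gq = net.parent(q)
    d = _other_child(net, p, r)
    dq = _other_child(net, q, p)
    base = t[q]
    newval = _just_above(t, base)
    updates = {p: base, r: base, q: newval}
    if net.is_reticulation(dq) and t[dq] == base:
        updates[dq] = newval
    walk.emit(RNNIMove(p=q, x=p, c=d, e=(p, r), z=gq, w=q), updates)


def _raise_triangle(walk: _Walk, r: Node) -> str:
    """The triangle case: r sits in a triangle (a, p), (a, r), (p, r).

    If the parent q2 of the apex a is not on a top horizontal arc
    (hence a tree node), two moves re-form the triangle one level up
    ("raised").  Otherwise q2 is the endpoint of the lowest top
    horizontal arc, and at most four moves (one prefix reorientation if
    q2 is its tail, then three) put r at the top ("topped").
    """
    net, t = walk.net, walk.t
    p, a = _contemporaneous_parent(t, net, r)
    if net.parent(p) != a:
        raise AssertionError("r is not in a triangle")
    ts = top_structure(net)
    q2 = net.parent(a)
    endpoints = set()
    if ts.k_top:
        xk, yk = ts.horizontal[-1]
        endpoints = {n for arc in ts.horizontal for n in arc}
    if q2 not in endpoints:
        # case raised: q2 is a tree node off the top structure
        if net.is_reticulation(q2):
            raise AssertionError("reticulation above the triangle apex is not at the top")
        v = _other_child(net, q2, a)
        c = net.child(r)
        val1 = _just_below(t, min(t[a], t[v]))
        if val1 <= t[q2]:
            raise AssertionError("no room below the triangle apex label")
        walk.emit(RNNIMove(p=q2, x=a, c=p, e=(a, r), z=q2, w=v), {a: val1})
        val2 = _just_below(walk.t, val1)
        walk.emit(RNNIMove(p=q2, x=a, c=r, e=(a, v), z=r, w=c), {p: val2, r: val2})
        return "raised"
    # case topped: q2 lies on the lowest top horizontal arc
    if not net.is_reticulation(q2):
        if q2 != xk:
            raise AssertionError("tree-node endpoint above the apex is not the lowest tail")
        move = _reorient_move(net, ts, ts.k_top)
        walk.emit(move, {})  # crossing the pendants preserves the labelling
        net = walk.net
        q2 = net.parent(a)
        if not net.is_reticulation(q2):
            raise AssertionError("reorientation failed to make q2 a reticulation")
    s, _ = _contemporaneous_parent(walk.t, net, q2)
    v = _other_child(net, s, q2)
    c = net.child(r)
    t = walk.t
    V = _just_below(t, min(t[a], t[v]))
    if V <= t[s]:
        raise AssertionError("no room for the apex label above the top arc")
    walk.emit(RNNIMove(p=q2, x=a, c=p, e=(a, r), z=s, w=q2), {a: V, q2: V})
    newa = _just_above(walk.t, walk.t[s])
    walk.emit(RNNIMove(p=s, x=a, c=q2, e=(a, r), z=s, w=v),
              {q2: walk.t[s], a: newa})
    val3 = _just_below(walk.t, walk.t[a])
    walk.emit(RNNIMove(p=s, x=a, c=r, e=(a, v), z=r, w=c), {p: val3, r: val3})
    return "topped"


def raise_triangle(
    network: Network, r: Node, t: HGTLabelling
) -> Tuple[Network, List[RNNIMove], str]:
    """Public entry for the triangle step; ``t`` must be a verified
    HGT-consistent labelling with t(parent)=t(r) inside the triangle."""
    walk = _Walk(network, t)
    outcome = _raise_triangle(walk, r)
    return walk.net, walk.moves, outcome


def _smallest_taxon_below(network: Network, v: Node) -> str:
    g = network.graph
    best = None
    for d in nx.descendants(g, v) | {v}:
        name = network.taxa.get(d)
        if name is not None and (best is None or name < best):
            best = name
    return best or ""


def lift_reticulation(network: Network) -> Tuple[Network, List[RNNIMove]]:
    """Increase the number of reticulations at the top by one.

    Chooses the reticulation not at the top with the smallest label in
    a freshly derived constructive labelling and walks it upward: each
    iteration moves the head or the tail of its horizontal arc one step
    up, or handles the triangle case, until the reticulation reaches
    the top.  Emits at most 2n moves.
    """
    walk = _Walk(network)
    _lift(walk)
    return walk.net, walk.moves


def _lift(walk: _Walk) -> None:
    net = walk.net
    ts0 = top_structure(net)
    k0 = ts0.k_top
    if k0 >= reticulation_number(net):
        raise ValueError("all reticulations are already at the top")
    non_top = [v for v in net.reticulations() if v not in ts0.top_reticulations()]
    r = min(non_top, key=lambda v: (walk.t[v], _smallest_taxon_below(net, v), v))
    n_leaves = len(net.leaves)
    guard = 2 * (n_leaves + reticulation_number(net)) + 8
    for _ in range(guard):
        ts = top_structure(walk.net)
        if ts.k_top > k0:
            return
        if r in ts.top_reticulations():
            return
        above_before = len(nx.ancestors(walk.net.graph, r))
        p, u = _contemporaneous_parent(walk.t, walk.net, r)
        q = walk.net.parent(p)
        if u == q:
            outcome = _raise_triangle(walk, r)
            if outcome == "topped":
                new_k = top_structure(walk.net).k_top
                if new_k <= k0:
                    raise AssertionError("triangle topping did not raise k_top")
                return
        elif walk.t[u] > walk.t[q]:
            _head_up(walk, r)
        elif walk.t[q] > walk.t[u]:
            _tail_up(walk, r)
        else:
            raise AssertionError(
                "equal labels on distinct non-adjacent nodes above a reticulation"
            )
        above_after = len(nx.ancestors(walk.net.graph, r))
        if above_after >= above_before:
            raise AssertionError("lift iteration made no upward progress")
    raise AssertionError("reticulation lifting did not terminate within its bound")


# ---------------------------------------------------------------------------
# gathering the leaves below one side of the top stack
# ---------------------------------------------------------------------------


def _leaf_node(network: Network, taxon: str) -> Node:
    return network.leaf_of(taxon)


def _gather(walk: _Walk, taxon: str) -> None:
    """Walk the anchor leaf up to sit directly below the head of the
    lowest horizontal arc, pushing every other leaf to the tail side.

    For each spine node u_i on the path from the head y down to the
    leaf, two moves lift u_i over y onto the tail side: first u_i is
    interposed on the horizontal arc, then it is pushed below the tail's
    pendant side.  2(m-1) moves for a path of length m.
    """
    net = walk.net
    ts = top_structure(net)
    if ts.k_top != reticulation_number(net) or ts.k_top == 0:
        raise ValueError("gathering requires every reticulation at the top")
    x, y = ts.horizontal[-1]
    target = _leaf_node(net, taxon)
    below_y = nx.descendants(net.graph, y)
    if target not in below_y:
        raise ValueError(f"leaf {taxon!r} is not below the head of the lowest horizontal arc")
    # unique path y -> leaf (everything below the top stack is a tree)
    path: List[Node] = []
    cur = net.child(y)
    while True:
        path.append(cur)
        if cur == target:
            break
        nxt = [c for c in net.children(cur)
               if c == target or target in nx.descendants(net.graph, c)]
        cur = nxt[0]
    u0 = _other_child(net, x, y)
    for i in range(1, len(path)):
        u_i, u_next = path[i - 1], path[i]
        v_i = _other_child(walk.net, u_i, u_next)
        val = _just_above(walk.t, walk.t[x])
        walk.emit(
            RNNIMove(p=y, x=u_i, c=u_next, e=(u_i, v_i), z=x, w=y),
            {u_i: val, y: val},
        )
        prev = u0 if i == 1 else path[i - 2]
        walk.emit(
            RNNIMove(p=x, x=u_i, c=y, e=(u_i, v_i), z=x, w=prev),
            {y: walk.t[x]},
        )


def gather_leaves(network: Network, taxon: str) -> Tuple[Network, List[RNNIMove]]:
    """Make ``taxon`` the only leaf below the head of the lowest
    horizontal arc at the top; at most 2n - 4 moves."""
    walk = _Walk(network)
    _gather(walk, taxon)
    return walk.net, walk.moves


# ---------------------------------------------------------------------------
# sorting pendant trees
# ---------------------------------------------------------------------------


def _flatten(walk: _Walk, sub_root: Node) -> None:
    """Rotate the pendant subtree at ``sub_root`` into a caterpillar.

    Each move inserts one internal node into the growing spine, so at
    most (number of internal nodes - 1) moves are used.
    """
    v = sub_root
    while True:
        children = walk.net.children(v)
        if not children:
            return
        internal = [c for c in children if walk.net.children(c)]
        if not internal:
            return  # bottom cherry (or pendant leaf)
        if len(internal) == 1:
            v = internal[0]
            continue
        a, b = sorted(internal, key=lambda c: _smallest_taxon_below(walk.net, c))
        a1, a2 = sorted(walk.net.children(a),
                        key=lambda c: _smallest_taxon_below(walk.net, c))
        walk.emit_relabel(RNNIMove(p=v, x=a, c=a1, e=(a, a2), z=v, w=b))


def _spine_order(network: Network, sub_root: Node) -> List[str]:
    """Leaf taxa of a caterpillar, top of the spine first."""
    order: List[str] = []
    v = sub_root
    while True:
        children = network.children(v)
        if not children:
            order.append(network.taxa[v])
            return order
        leaves = [c for c in children if not network.children(c)]
        internal = [c for c in children if network.children(c)]
        if len(internal) > 1:
            raise ValueError("subtree is not a caterpillar")
        if internal:
            order.extend(sorted(network.taxa[c] for c in leaves))
            v = internal[0]
        else:
            order.extend(sorted(network.taxa[c] for c in leaves))
            return order


def _block_top(network: Network, root: Node, key) -> Tuple[int, Node, Optional[Node]]:
    """(top key, top leaf, rest-root) of a sorted caterpillar block."""
    if not network.children(root):
        return key(root), root, None
    children = network.children(root)
    leaves = [c for c in children if not network.children(c)]
    if not leaves:
        raise AssertionError("sorted block has no leaf child")
    top = min(leaves, key=key)
    rest = [c for c in children if c != top]
    return key(top), top, rest[0]


def _zipper_sort(walk: _Walk, sub_root: Node, key) -> None:
    """Sort the pendant subtree at ``sub_root`` into the caterpillar
    ordered by ``key``, merging sorted sub-blocks bottom-up.

    At each junction the block with the smaller top element repeatedly
    yields its top leaf to the spine (one move per leaf) until one side
    is exhausted — a zipper merge following the shape of the input tree
    as its merge schedule.
    """

    def sort_block(v: Node) -> None:
        children = walk.net.children(v)
        if not children:
            return
        for c in children:
            sort_block(c)
        u = v
        while True:
            ca, cb = walk.net.children(u)
            ka, ta, ra = _block_top(walk.net, ca, key)
            kb, tb, rb = _block_top(walk.net, cb, key)
            if ka < kb:
                chosen, top, rest, other = ca, ta, ra, cb
            else:
                chosen, top, rest, other = cb, tb, rb, ca
            if rest is None:
                return  # chosen side is a bare leaf already above the other block
            walk.emit_relabel(
                RNNIMove(p=u, x=chosen, c=top, e=(chosen, rest), z=u, w=other)
            )
            u = chosen

    sort_block(sub_root)


def _match_nodes(source: Network, target: Network) -> Dict[Node, Node]:
    """An isomorphism mapping (source node -> target node) respecting
    taxon labels; raises if none exists."""
    g1, g2 = source.graph.copy(), target.graph.copy()
    for v in g1:
        g1.nodes[v]["taxon"] = source.taxa.get(v)
    for v in g2:
        g2.nodes[v]["taxon"] = target.taxa.get(v)
    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        g1, g2, node_match=lambda a, b: a.get("taxon") == b.get("taxon")
    )
    if not matcher.is_isomorphic():
        raise AssertionError("canonical-form networks are not isomorphic")
    return dict(matcher.mapping)


def _translate_move(move: RNNIMove, phi: Dict[Node, Node]) -> RNNIMove:
    return RNNIMove(
        p=phi[move.p], x=phi[move.x], c=phi[move.c],
        e=(phi[move.e[0]], phi[move.e[1]]), z=phi[move.z], w=phi[move.w],
    )


def _bridge(walk1: _Walk, walk2: _Walk, source: Network) -> MovePath:
    """Concatenate walk1 with the reversal of walk2, translating the
    reversed moves onto walk1's node identifiers."""
    phi = _match_nodes(walk2.net, walk1.net)
    moves = list(walk1.moves)
    certificates = [dict(c) for c in walk1.certificates]
    labellings2 = [walk2.initial_t] + walk2.certificates
    for j in range(len(walk2.moves) - 1, -1, -1):
        moves.append(_translate_move(walk2.moves[j].inverse(), phi))
        certificates.append({phi[v]: lbl for v, lbl in labellings2[j].items()})
    return MovePath(source=source, moves=moves, certificates=certificates)


def tree_rnni_path(t1: Network, t2: Network) -> MovePath:
    """A certified rNNI path between two phylogenetic trees on the same
    taxa, via a shared sorted caterpillar.

    One side is flattened to a caterpillar (at most n - 2 moves); the
    other is zipper-merge-sorted into that caterpillar's leaf order.
    """
    if t1.taxon_set() != t2.taxon_set():
        raise ValueError("trees are not on the same taxa")
    for t in (t1, t2):
        if reticulation_number(t) != 0:
            raise ValueError("tree path requires reticulation-free networks")
    walk2 = _Walk(t2)
    root2 = walk2.net.child(walk2.net.root)
    _flatten(walk2, root2)
    order = _spine_order(walk2.net, root2)
    rank = {taxon: i for i, taxon in enumerate(order)}
    walk1 = _Walk(t1)
    root1 = walk1.net.child(walk1.net.root)
    _zipper_sort(walk1, root1, key=lambda v: rank[walk1.net.taxa[v]])
    return _bridge(walk1, walk2, t1)


# ---------------------------------------------------------------------------
# the full path between two orchard networks
# ---------------------------------------------------------------------------


def _canonicalize(walk: _Walk, k: int, anchor: str) -> Node:
    """Drive one network to canonical form: k reticulations neatly at
    the top, the anchor leaf just below the head of the lowest
    horizontal arc; returns the pendant root holding the other taxa."""
    while top_structure(walk.net).k_top < k:
        _lift(walk)
    if k == 0:
        return walk.net.child(walk.net.root)
    ts = top_structure(walk.net)
    for k_prime in neat_moves(ts.orientation):
        move = _reorient_move(walk.net, top_structure(walk.net), k_prime)
        walk.emit(move, {})  # crossing two equal-labelled tails keeps t valid
    ts = top_structure(walk.net)
    if any(o != NEAT for o in ts.orientation):
        raise AssertionError("orientation phase did not reach the neat pattern")
    x, y = ts.horizontal[-1]
    anchor_node = _leaf_node(walk.net, anchor)
    if anchor_node not in nx.descendants(walk.net.graph, y):
        move = _reorient_move(walk.net, ts, ts.k_top)  # swap the two pendants
        walk.emit(move, {})
        ts = top_structure(walk.net)
        x, y = ts.horizontal[-1]
        if anchor_node not in nx.descendants(walk.net.graph, y):
            raise AssertionError("anchor leaf is still on the tail side")
    _gather(walk, anchor)
    ts = top_structure(walk.net)
    x, y = ts.horizontal[-1]
    return _other_child(walk.net, x, y)


def orchard_path(n1: Network, n2: Network) -> MovePath:
    """A certified rNNI path between two binary orchard networks with
    the same taxa and reticulation number.

    Both networks are driven to the same canonical form — reticulations
    stacked neatly at the top, the lexicographically smallest taxon
    alone below the lowest head, remaining taxa in a sorted pendant
    caterpillar — and the two half-paths are concatenated.  The length
    never exceeds diameter_bound(n, k); every intermediate network
    carries a verified HGT-consistent labelling.
    """
    for net in (n1, n2):
        report = validate(net)
        if report:
            raise ValueError("input is not a valid network: " + "; ".join(report))
        if not is_binary(net):
            raise ValueError("orchard paths are defined for binary networks")
        ok, _ = is_orchard(net)
        if not ok:
            raise ValueError("input network is not orchard")
    if n1.taxon_set() != n2.taxon_set():
        raise ValueError("networks are not on the same taxa")
    k = reticulation_number(n1)
    if k != reticulation_number(n2):
        raise ValueError(
            f"reticulation numbers differ: {k} vs {reticulation_number(n2)}"
        )
    anchor = min(n1.taxon_set())
    walk1, walk2 = _Walk(n1), _Walk(n2)
    pend1 = _canonicalize(walk1, k, anchor)
    pend2 = _canonicalize(walk2, k, anchor)
    _flatten(walk2, pend2)
    order = _spine_order(walk2.net, pend2)
    rank = {taxon: i for i, taxon in enumerate(order)}
    _zipper_sort(walk1, pend1, key=lambda v: rank[walk1.net.taxa[v]])
    return _bridge(walk1, walk2, n1)
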