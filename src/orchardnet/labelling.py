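"""HGT-consistent labellings of phylogenetic networks.

A labelling t of the nodes is *HGT-consistent* when (P1) labels weakly
increase along every arc, with equality permitted only into
reticulations; (P2) every node with children has a strictly later
child; and (P3) every reticulation is contemporaneous with exactly one
of its parents.  Arcs with equal endpoint labels are *horizontal* and
model instantaneous lateral transfers; deleting them and suppressing
degree-two nodes yields a *base tree*, so a network admitting such a
labelling is a tree with added horizontal arcs.  A binary network is
orchard exactly when it admits an HGT-consistent labelling; a *crown*
(a cyclic alternating structure u_i -> v_i, u_i -> v_{i+1}) obstructs
any such labelling.

Labels are exact rationals throughout: only their order and equality
pattern carries meaning, and exact arithmetic removes every tolerance
question from verification.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

from orchardnet.network import Network, Node, Arc, validate
from orchardnet.cherries import (
    CherrySequence,
    CHERRY,
    _classify,
    reduce_pair,
)

HGTLabelling = Dict[Node, Fraction]
HorizontalAssignment = Dict[Node, Node]  # reticulation -> contemporaneous parent


def verify_labelling(network: Network, t: HGTLabelling) -> List[str]:
    """Diagnose a candidate labelling against Properties 1-3.

    The graph may be any directed graph with indegree and outdegree at
    most 2 and total degree at most 3 (the scope in which validity of
    rearrangement moves is argued), not only a valid network.  Returns
    the empty list iff the labelling is HGT-consistent; raises if ``t``
    is not defined on every node.
    """
    g = network.graph
    missing = [v for v in g if v not in t]
    if missing:
        raise ValueError(f"labelling is partial: missing nodes {sorted(missing)}")
    for v in g:
        if g.in_degree(v) > 2 or g.out_degree(v) > 2 or g.in_degree(v) + g.out_degree(v) > 3:
            raise ValueError(
                f"node {v} has degrees ({g.in_degree(v)}, {g.out_degree(v)}); "
                "labelling verification is defined for total degree <= 3"
            )
    report: List[str] = []
    for u, v in g.edges():
        if t[u] > t[v]:
            report.append(f"P1: arc ({u}, {v}) has t({u}) > t({v})")
        elif t[u] == t[v] and g.in_degree(v) != 2:
            report.append(f"P1: arc ({u}, {v}) has equal labels but {v} has indegree "
                          f"{g.in_degree(v)}, not 2")
    for u in g:
        children = list(g.successors(u))
        if children and not any(t[u] < t[c] for c in children):
            report.append(f"P2: node {u} has no strictly later child")
    for r in g:
        parents = list(g.predecessors(r))
        if len(parents) == 2:
            equal = [u for u in parents if t[u] == t[r]]
            if len(equal) != 1:
                report.append(
                    f"P3: reticulation {r} is contemporaneous with {len(equal)} parents, "
                    "expected exactly 1"
                )
    return report


def labelling_from_sequence(network: Network, seq: CherrySequence) -> HGTLabelling:
    """The constructive labelling read off a cherry-picking sequence.

    For a binary orchard network with reduction sequence of length m:
    the root gets 0, the j-th leaf in lexicographic taxon order gets
    m + j, and the internal node(s) removed when reducing the i-th pair
    get m + 1 - i.  Each label is used at most twice, and equal labels
    occur only on a tree-node parent with a reticulation child.
    """
    m = len(seq.pairs)
    t: HGTLabelling = {network.root: Fraction(0)}
    for j, taxon in enumerate(sorted(network.taxon_set()), start=1):
        t[network.leaf_of(taxon)] = Fraction(m + j)
    current = network
    for i, pair in enumerate(seq.pairs, start=1):
        if _classify(current, pair.x, pair.y) is None:
            raise ValueError(
                f"sequence does not reduce the network: pair #{i - 1} "
                f"({pair.x}, {pair.y}) is not reducible"
            )
        leaf_x = current.leaf_of(pair.x)
        reduced = reduce_pair(current, pair)
        removed = set(current.graph.nodes) - set(reduced.graph.nodes) - {leaf_x}
        for v in removed:
            t[v] = Fraction(m + 1 - i)
        current = reduced
    if len(current.leaves) != 1:
        raise ValueError("sequence does not reduce the network to a single leaf")
    unlabelled = [v for v in network.graph if v not in t]
    if unlabelled:
        raise ValueError(
            f"internal nodes {sorted(unlabelled)} were never removed by the sequence "
            "(is the network binary?)"
        )
    return t


def _assignment_feasible(
    network: Network,
    equal_arcs: Set[Arc],
) -> Optional[HGTLabelling]:
    """Feasibility core shared by the labelling-existence searches.

    ``equal_arcs`` are the arcs forced to carry equal endpoint labels;
    every other arc is strict (weak inequality plus the exactly-one rule
    leaves no other option).  Labels exist iff (a) no node has all of
    its out-arcs forced equal (P2) and (b) the digraph of strict arcs
    between equality classes is acyclic.  On success, returns integer
    topological ranks of the contracted classes as a witness.
    """
    g = network.graph
    # union-find over forced-equal endpoints
    parent: Dict[Node, Node] = {v: v for v in g}

    def find(v: Node) -> Node:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in equal_arcs:
        parent[find(u)] = find(v)

    for u in g:
        children = list(g.successors(u))
        if children and all((u, c) in equal_arcs for c in children):
            return None  # P2: no strictly later child possible
    quotient = nx.DiGraph()
    quotient.add_nodes_from({find(v) for v in g})
    for u, v in g.edges():
        if (u, v) in equal_arcs:
            continue
        cu, cv = find(u), find(v)
        if cu == cv:
            return None  # a strict arc inside an equality class
        quotient.add_edge(cu, cv)
    if not nx.is_directed_acyclic_graph(quotient):
        return None
    rank = {c: i for i, c in enumerate(nx.topological_sort(quotient))}
    return {v: Fraction(rank[find(v)]) for v in g}


def labelling_exists(
    network: Network,
) -> Tuple[bool, Optional[HGTLabelling], Optional[HorizontalAssignment]]:
    """Decide by exhaustive search whether a binary network admits an
    HGT-consistent labelling.

    Enumerates all 2**k choices of the contemporaneous parent of each
    reticulation and tests each for order-consistency.  This is a
    deliberately direct decision procedure, independent of cherry
    picking, so the two can cross-validate each other.
    """
    retics = sorted(network.reticulations())
    for r in retics:
        if network.graph.in_degree(r) != 2:
            raise ValueError(
                f"reticulation {r} has indegree {network.graph.in_degree(r)}; "
                "labelling existence is decided for binary networks"
            )
    parent_lists = [sorted(network.parents(r)) for r in retics]
    for choice in itertools.product(*parent_lists):
        equal_arcs = {(p, r) for p, r in zip(choice, retics)}
        witness = _assignment_feasible(network, equal_arcs)
        if witness is not None:
            assignment = dict(zip(retics, choice))
            return True, witness, assignment
    return False, None, None


def allbutone_labelling_exists(network: Network) -> bool:
    """Candidate non-binary rule: every reticulation contemporaneous
    with all but one parent.

    For each reticulation the single *non*-contemporaneous parent is
    chosen; all its other in-arcs are forced horizontal.  Agrees with
    :func:`labelling_exists` on binary networks, but does not
    characterize non-binary orchard networks.
    """
    retics = sorted(network.reticulations())
    parent_lists = [sorted(network.parents(r)) for r in retics]
    for choice in itertools.product(*parent_lists):
        equal_arcs: Set[Arc] = set()
        for r, strict_parent in zip(retics, choice):
            for p in network.parents(r):
                if p != strict_parent:
                    equal_arcs.add((p, r))
        if _assignment_feasible(network, equal_arcs) is not None:
            return True
    return False


def horizontal_arcs(network: Network, t: HGTLabelling) -> Set[Arc]:
    """The arcs whose endpoints carry equal labels under a verified
    labelling; exactly one per reticulation in the binary case."""
    report = verify_labelling(network, t)
    if report:
        raise ValueError("labelling is not HGT-consistent: " + "; ".join(report))
    return {(u, v) for u, v in network.graph.edges() if t[u] == t[v]}


def base_tree(network: Network, t: HGTLabelling) -> Network:
    """Delete all horizontal arcs and suppress degree-two nodes.

    The result is a phylogenetic tree on the same taxa, witnessing that
    a network with an HGT-consistent labelling is tree-based.
    """
    arcs = horizontal_arcs(network, t)
    out = network.copy()
    g = out.graph
    for u, v in arcs:
        g.remove_edge(u, v)
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if g.in_degree(v) == 1 and g.out_degree(v) == 1:
                (p,), (c,) = g.predecessors(v), g.successors(v)
                g.remove_node(v)
                if g.has_edge(p, c):
                    raise ValueError(
                        f"suppressing {v} would create a parallel arc {p}->{c}"
                    )
                g.add_edge(p, c)
                changed = True
    report = validate(out)
    if report:
        raise ValueError("base tree extraction failed: " + "; ".join(report))
    return out


def contains_crown(network: Network) -> Tuple[bool, Optional[Set[Node]]]:
    """Search for a crown: nodes u_1..u_k, v_1..v_k (k >= 2, all 2k
    distinct) with arcs (u_i, v_i) and (u_i, v_{i+1}), indices mod k.

    Returns the smallest witness node set if one exists.  The search is
    iterative deepening in k, capped at the number of reticulations
    (each v_i has indegree >= 2).
    """
    g = network.graph
    retics = [v for v in g if g.in_degree(v) >= 2]
    for k in range(2, len(retics) + 1):
        witness = _find_crown(g, k)
        if witness is not None:
            return True, witness
    return False, None


def _find_crown(g: nx.DiGraph, k: int) -> Optional[Set[Node]]:
    # path state: u_1..u_i and v_1..v_{i+1}; arcs (u_j,v_j),(u_j,v_{j+1})
    def extend(us: List[Node], vs: List[Node]) -> Optional[Set[Node]]:
        i = len(us)
        if i == k:
            # close the cycle: need (u_k, v_1) — equivalently vs[k] == vs[0]
            return set(us) | set(vs[:-1]) if vs[-1] == vs[0] else None
        for u in g.predecessors(vs[-1]):
            if u in us:
                continue
            for v_next in g.successors(u):
                if v_next == vs[-1]:
                    continue
                closing = i + 1 == k
                if closing:
                    if v_next != vs[0]:
                        continue
                elif v_next in vs:
                    continue
                found = extend(us + [u], vs + [v_next])
                if found is not None:
                    return found
        return None

    for u1 in g.nodes:
        succ = list(g.successors(u1))
        for v1 in succ:
            for v2 in succ:
                if v2 == v1:
                    continue
                if k == 2:
                    # need u_2 with arcs (u_2, v_2), (u_2, v_1)
                    for u2 in g.predecessors(v2):
                        if u2 != u1 and g.has_edge(u2, v1):
                            return {u1, u2, v1, v2}
                else:
                    found = extend([u1], [v1, v2])
                    if found is not None:
                        return found
    return None
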