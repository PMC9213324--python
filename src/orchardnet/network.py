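"""Data model, validation and isomorphism for rooted phylogenetic networks.

A rooted phylogenetic network is a directed acyclic graph with four node
kinds determined by degrees: a unique root (indegree 0, outdegree 1),
tree nodes (indegree 1, outdegree >= 2), reticulations (indegree >= 2,
outdegree 1), and leaves (indegree 1, outdegree 0) labelled bijectively
by taxa.  Parallel arcs are never allowed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx

Node = int
Arc = Tuple[Node, Node]


class NodeKind(str, Enum):
    ROOT = "root"
    TREE = "tree"
    RETICULATION = "reticulation"
    LEAF = "leaf"


@dataclass
class Network:
    """A rooted phylogenetic network.

    Node identifiers are opaque integers; only taxon labels are stable
    across serialization.  ``graph`` is a :class:`networkx.DiGraph`;
    ``taxa`` maps leaf nodes to taxon names.

    The constructor does not validate; use :func:`validate` to obtain a
    diagnosis, or :meth:`check` to raise on the first violation.
    """

    graph: nx.DiGraph
    taxa: Dict[Node, str] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arcs(cls, arcs: Iterable[Arc], taxa: Dict[Node, str]) -> "Network":
        g = nx.DiGraph()
        g.add_edges_from(arcs)
        for v in taxa:
            g.add_node(v)
        return cls(g, dict(taxa))

    def copy(self) -> "Network":
        return Network(self.graph.copy(), dict(self.taxa))

    def fresh_node(self) -> Node:
        return (max(self.graph.nodes, default=-1)) + 1

    # -- basic accessors ------------------------------------------------------

    @property
    def root(self) -> Node:
        roots = [v for v in self.graph if self.graph.in_degree(v) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one indegree-0 node, found {len(roots)}")
        return roots[0]

    @property
    def leaves(self) -> List[Node]:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def taxon_of(self, v: Node) -> str:
        return self.taxa[v]

    def leaf_of(self, taxon: str) -> Node:
        for v, name in self.taxa.items():
            if name == taxon:
                return v
        raise KeyError(taxon)

    def taxon_set(self) -> Set[str]:
        return set(self.taxa.values())

    def kind(self, v: Node) -> NodeKind:
        indeg = self.graph.in_degree(v)
        outdeg = self.graph.out_degree(v)
        if indeg == 0:
            return NodeKind.ROOT
        if outdeg == 0:
            return NodeKind.LEAF
        if indeg == 1 and outdeg >= 2:
            return NodeKind.TREE
        if indeg >= 2 and outdeg == 1:
            return NodeKind.RETICULATION
        raise ValueError(f"node {v} has invalid degrees ({indeg}, {outdeg})")

    def is_reticulation(self, v: Node) -> bool:
        return self.graph.in_degree(v) >= 2

    def parents(self, v: Node) -> List[Node]:
        return list(self.graph.predecessors(v))

    def children(self, v: Node) -> List[Node]:
        return list(self.graph.successors(v))

    def parent(self, v: Node) -> Node:
        ps = self.parents(v)
        if len(ps) != 1:
            raise ValueError(f"node {v} has {len(ps)} parents, expected 1")
        return ps[0]

    def child(self, v: Node) -> Node:
        cs = self.children(v)
        if len(cs) != 1:
            raise ValueError(f"node {v} has {len(cs)} children, expected 1")
        return cs[0]

    def reticulations(self) -> List[Node]:
        return [v for v in self.graph if self.graph.in_degree(v) >= 2]

    def check(self) -> "Network":
        report = validate(self)
        if report:
            raise ValueError("not a valid network: " + "; ".join(report))
        return self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Network({self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} arcs, taxa={sorted(self.taxa.values())})"
        )


def validate(network: Network) -> List[str]:
    """Diagnose a candidate network against the degree-type conditions.

    Returns a list of human-readable violations; the empty list means the
    candidate is a valid rooted phylogenetic network.  Never raises:
    this is a diagnosis, not an assertion.
    """
    g = network.graph
    report: List[str] = []
    if g.number_of_nodes() == 0:
        return ["graph is empty"]
    if not nx.is_directed_acyclic_graph(g):
        report.append("graph contains a directed cycle")
    # nx.DiGraph cannot represent parallel arcs; reject MultiDiGraph input.
    if g.is_multigraph():
        seen: Set[Arc] = set()
        for u, v in g.edges():
            if (u, v) in seen:
                report.append(f"parallel arcs from {u} to {v}")
            seen.add((u, v))
    roots = [v for v in g if g.in_degree(v) == 0]
    if len(roots) != 1:
        report.append(f"expected exactly one indegree-0 node, found {len(roots)}")
    else:
        if g.out_degree(roots[0]) != 1:
            report.append(f"root {roots[0]} has outdegree {g.out_degree(roots[0])}, expected 1")
    for v in g:
        indeg, outdeg = g.in_degree(v), g.out_degree(v)
        if indeg == 0:
            continue  # handled as root above
        if outdeg == 0:
            if indeg != 1:
                report.append(f"leaf {v} has indegree {indeg}, expected 1")
            if v not in network.taxa:
                report.append(f"leaf {v} carries no taxon label")
        elif indeg == 1 and outdeg >= 2:
            pass  # tree node
        elif indeg >= 2 and outdeg == 1:
            pass  # reticulation
        else:
            report.append(f"node {v} has invalid degrees ({indeg}, {outdeg})")
    labelled_non_leaves = [v for v in network.taxa if v in g and g.out_degree(v) != 0]
    for v in labelled_non_leaves:
        report.append(f"internal node {v} carries a taxon label")
    names = list(network.taxa.values())
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        report.append(f"duplicate taxon labels: {dupes}")
    for v in network.taxa:
        if v not in g:
            report.append(f"taxon map names absent node {v}")
    return report


def is_binary(network: Network) -> bool:
    """True iff every tree node and reticulation has total degree 3."""
    g = network.graph
    for v in g:
        indeg, outdeg = g.in_degree(v), g.out_degree(v)
        if indeg == 0 or outdeg == 0:
            continue
        if indeg + outdeg != 3:
            return False
    return True


def reticulation_number(network: Network) -> int:
    """Reticulation arcs minus reticulation nodes: sum of (indeg(r) - 1)."""
    g = network.graph
    return sum(g.in_degree(v) - 1 for v in g if g.in_degree(v) >= 2)


def contract_arc(network: Network, arc: Arc) -> Network:
    """Delete ``arc`` and identify its endpoints (head into tail).

    The result is a directed labelled graph that need not be a valid
    network; no suppression is performed.
    """
    u, v = arc
    if not network.graph.has_edge(u, v):
        raise ValueError(f"arc {arc} not in network")
    out = network.copy()
    g = out.graph
    g.remove_edge(u, v)
    for p in list(g.predecessors(v)):
        if p != u:
            g.add_edge(p, u)
    for c in list(g.successors(v)):
        if c != u:
            g.add_edge(u, c)
    g.remove_node(v)
    if v in out.taxa:
        out.taxa[u] = out.taxa.pop(v)
    return out


def _binary_groupings(items: List[Node]) -> Iterator[List[Tuple]]:
    """All rooted binary tree shapes over ``items``, as nested pair tuples.

    Yields, for each shape, the nested structure whose leaves are the
    items.  There are (2d-3)!! shapes for d items.
    """
    if len(items) == 1:
        yield items[0]
        return
    first, rest = items[0], items[1:]
    for sub in _binary_groupings(rest):
        # insert `first` on every edge of the shape `sub`
        for placed in _insertions(sub, first):
            yield placed


def _insertions(shape, item) -> Iterator[Tuple]:
    yield (item, shape)
    if isinstance(shape, tuple):
        left, right = shape
        for sub in _insertions(left, item):
            yield (sub, right)
        for sub in _insertions(right, item):
            yield (left, sub)


def binary_resolutions(network: Network) -> Iterator[Network]:
    """Yield every binary resolution of ``network`` up to isomorphism.

    A binary resolution is a binary network from which the input can be
    recovered by contracting arcs.  Tree polytomies are expanded into
    every rooted binary tree over their children; reticulations of
    indegree d into every binary in-tree over their parents.  For a
    binary input the stream is exactly the input itself.

    Raises if the input is not a valid network, or if the number of
    candidate resolutions exceeds 10**4 (desk-scale guarantee).
    """
    report = validate(network)
    if report:
        raise ValueError("cannot resolve an invalid network: " + "; ".join(report))

    g = network.graph
    polytomies = [
        v
        for v in g
        if (g.in_degree(v) == 1 and g.out_degree(v) > 2)
        or (g.in_degree(v) > 2 and g.out_degree(v) == 1)
    ]
    if not polytomies:
        yield network.copy()
        return

    count = 1
    for v in polytomies:
        d = max(g.in_degree(v), g.out_degree(v))
        shapes = 1
        for i in range(3, 2 * d - 2, 2):
            shapes *= i
        count *= shapes
    if count > 10_000:
        raise ValueError(f"resolution space too large ({count} > 10000 candidates)")

    # Arcs are keyed so that expanding adjacent polytomies composes: each
    # expansion rewires only its own endpoint of a keyed arc.
    arc_key = {arc: i for i, arc in enumerate(sorted(g.edges()))}
    per_node_choices: List[List] = []
    for v in polytomies:
        if g.out_degree(v) > 2:
            keys = sorted(arc_key[(v, c)] for c in g.successors(v))
        else:
            keys = sorted(arc_key[(p, v)] for p in g.predecessors(v))
        per_node_choices.append(list(_binary_groupings(keys)))

    seen: List[Network] = []
    for combo in itertools.product(*per_node_choices):
        resolved = network.copy()
        for arc, k in arc_key.items():
            resolved.graph.edges[arc]["k"] = k
        for v, shape in zip(polytomies, combo):
            _expand_polytomy(resolved, v, shape, out=g.out_degree(v) > 2)
        if any(is_isomorphic(resolved, other) for other in seen):
            continue
        seen.append(resolved)
        yield resolved


def _find_keyed_arc(g: nx.DiGraph, key: int) -> Arc:
    for u, v, k in g.edges(data="k"):
        if k == key:
            return (u, v)
    raise KeyError(key)


def _expand_polytomy(net: Network, v: Node, shape, out: bool) -> None:
    """Replace the polytomy at ``v`` in place by the binary shape.

    ``shape`` is a nested pair structure whose leaves are arc keys; each
    keyed arc keeps its far endpoint and is re-attached to the new
    binary structure at the position the shape dictates.
    """
    g = net.graph

    def attach(s, anchor: Node) -> None:
        if not isinstance(s, tuple):
            u, w = _find_keyed_arc(g, s)
            g.remove_edge(u, w)
            if out:
                g.add_edge(anchor, w, k=s)
            else:
                g.add_edge(u, anchor, k=s)
            return
        m = net.fresh_node()
        if out:
            g.add_edge(anchor, m)
        else:
            g.add_edge(m, anchor)
        attach(s[0], m)
        attach(s[1], m)

    attach(shape[0], v)
    attach(shape[1], v)


def is_isomorphic(n1: Network, n2: Network) -> bool:
    """Arc-preserving bijection test that fixes taxon labels."""
    if n1.graph.number_of_nodes() != n2.graph.number_of_nodes():
        return False
    if n1.graph.number_of_edges() != n2.graph.number_of_edges():
        return False
    if n1.taxon_set() != n2.taxon_set():
        return False
    g1 = n1.graph.copy()
    g2 = n2.graph.copy()
    for v in g1:
        g1.nodes[v]["taxon"] = n1.taxa.get(v)
    for v in g2:
        g2.nodes[v]["taxon"] = n2.taxa.get(v)
    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        g1, g2, node_match=lambda a, b: a.get("taxon") == b.get("taxon")
    )
    return matcher.is_isomorphic()
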