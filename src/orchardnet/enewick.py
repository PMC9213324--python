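"""Extended Newick (eNewick) I/O for rooted phylogenetic networks.

Reticulations are encoded with hybrid tags: the first occurrence of a
hybrid node is written ``label#H<i>`` (optionally with its subtree), and
every further occurrence as ``#H<i>``.  Only topology is represented;
branch lengths, if present in the input, are parsed and discarded with
a logged warning.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import networkx as nx

from orchardnet.network import Network, Node

logger = logging.getLogger(__name__)


class EnewickError(ValueError):
    """Malformed eNewick input; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.graph = nx.DiGraph()
        self.taxa: Dict[Node, str] = {}
        self.hybrids: Dict[str, Node] = {}
        self.hybrid_named: Dict[str, Optional[str]] = {}
        self.next_id = 0
        self.saw_length = False

    def fresh(self) -> Node:
        v = self.next_id
        self.next_id += 1
        self.graph.add_node(v)
        return v

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.peek().isspace():
            self.pos += 1

    def parse(self) -> Network:
        self.skip_ws()
        top = self.subtree()
        self.skip_ws()
        if self.peek() != ";":
            raise EnewickError("expected ';'", self.pos)
        self.pos += 1
        if self.saw_length:
            logger.warning("branch lengths in eNewick input were discarded")
        # Root convention: indegree-0 node has outdegree exactly 1.
        if self.graph.out_degree(top) != 1 or top in self.taxa:
            rho = self.fresh()
            self.graph.add_edge(rho, top)
        for tag, v in self.hybrids.items():
            if self.graph.in_degree(v) < 2:
                raise EnewickError(
                    f"hybrid tag #{tag} occurs once (implies indegree "
                    f"{self.graph.in_degree(v)}, need >= 2)",
                    self.pos,
                )
        return Network(self.graph, self.taxa)

    def subtree(self) -> Node:
        self.skip_ws()
        children: List[Node] = []
        if self.peek() == "(":
            self.pos += 1
            children.append(self.subtree())
            self.skip_ws()
            while self.peek() == ",":
                self.pos += 1
                children.append(self.subtree())
                self.skip_ws()
            if self.peek() != ")":
                raise EnewickError("expected ')' or ','", self.pos)
            self.pos += 1
        name, tag = self.label()
        if tag is not None:
            v = self.node_for_hybrid(tag, name)
        else:
            v = self.fresh()
            if name and not children:
                self.taxa[v] = name
            # internal (non-hybrid) labels are ignored: taxa live on leaves
        if not children and tag is None and not name:
            raise EnewickError("empty node: expected a label or '('", self.pos)
        for c in children:
            if self.graph.has_edge(v, c):
                raise EnewickError("parallel arc in eNewick input", self.pos)
            self.graph.add_edge(v, c)
        return v

    def node_for_hybrid(self, tag: str, name: Optional[str]) -> Node:
        if tag in self.hybrids:
            v = self.hybrids[tag]
            prior = self.hybrid_named[tag]
            if name and prior and name != prior:
                raise EnewickError(
                    f"hybrid tag #{tag} carries conflicting names "
                    f"{prior!r} and {name!r}",
                    self.pos,
                )
            if name and not prior:
                self.hybrid_named[tag] = name
        else:
            v = self.fresh()
            self.hybrids[tag] = v
            self.hybrid_named[tag] = name
        return v

    def label(self) -> Tuple[Optional[str], Optional[str]]:
        name = self.bare_name()
        tag = None
        if self.peek() == "#":
            self.pos += 1
            tag = self.bare_name()
            if not tag:
                raise EnewickError("expected a hybrid tag after '#'", self.pos)
        if self.peek() == ":":
            self.pos += 1
            start = self.pos
            while self.peek() and (self.peek().isdigit() or self.peek() in ".eE+-"):
                self.pos += 1
            if self.pos == start:
                raise EnewickError("expected a branch length after ':'", self.pos)
            self.saw_length = True
        return name or None, tag

    def bare_name(self) -> str:
        start = self.pos
        while self.peek() and self.peek() not in "(),;:#":
            self.pos += 1
        return self.text[start : self.pos].strip()


def parse_enewick(text: str) -> Network:
    """Parse one eNewick string into a :class:`Network` (not validated)."""
    return _Parser(text).parse()


def write_enewick(network: Network) -> str:
    """Serialize a network to eNewick.

    Hybrid tags are assigned in a deterministic DFS order; the first
    occurrence of a reticulation carries its subtree.  The unary root is
    written explicitly, so ``parse_enewick(write_enewick(N))`` is
    isomorphic to ``N``.
    """
    g = network.graph
    root = network.root
    tags: Dict[Node, int] = {}
    written: set = set()
    counter = [0]

    def render(v: Node) -> str:
        if g.in_degree(v) >= 2:
            if v in written:
                return f"#H{tags[v]}"
            counter[0] += 1
            tags[v] = counter[0]
            written.add(v)
            suffix = f"#H{tags[v]}"
        else:
            suffix = ""
        children = sorted(g.successors(v), key=_sort_key(network))
        if not children:
            return network.taxa.get(v, "") + suffix
        inner = ",".join(render(c) for c in children)
        return f"({inner}){suffix}"

    return render(root) + ";"


def _sort_key(network: Network):
    """Deterministic child ordering: by smallest taxon reachable."""
    g = network.graph
    memo: Dict[Node, str] = {}

    def smallest(v: Node) -> str:
        if v in memo:
            return memo[v]
        if g.out_degree(v) == 0:
            memo[v] = network.taxa.get(v, "")
        else:
            memo[v] = min(smallest(c) for c in g.successors(v))
        return memo[v]

    return smallest
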