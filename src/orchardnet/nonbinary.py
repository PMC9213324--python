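"""Orchard testing for non-binary networks.

A non-binary network is orchard exactly when some binary resolution of
it is orchard, equivalently when some binary resolution admits an
HGT-consistent labelling.  The direct greedy reduction (with the
non-binary suppression rules) and the resolution-based labelling
search are implemented independently so that the equivalence can be
cross-checked exhaustively on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from orchardnet.network import Network, Node, binary_resolutions
from orchardnet.cherries import CherrySequence, is_orchard
from orchardnet.labelling import HGTLabelling, labelling_exists


@dataclass
class ResolutionWitness:
    """A binary resolution certifying that a non-binary network is
    orchard, together with the contraction map back to the original
    nodes and an HGT-consistent labelling of the resolution."""

    resolved: Network
    contraction_map: Dict[Node, Node]
    labelling: HGTLabelling


def is_orchard_nonbinary(network: Network) -> Tuple[bool, Optional[CherrySequence]]:
    """Greedy orchard test with non-binary reduction semantics (the
    suppression of a reduced pair's parents is conditional on their
    resulting degrees); identical to the binary test on binary input."""
    return is_orchard(network)


def _contraction_map(original: Network, resolved: Network) -> Dict[Node, Node]:
    """Map each node of a resolution to the original node it contracts
    into.  New reticulations follow their child chain down to the
    original polytomy; new tree nodes follow their parent chain up."""
    mapping: Dict[Node, Node] = {}
    original_nodes = set(original.graph.nodes)
    for v in resolved.graph.nodes:
        if v in original_nodes:
            mapping[v] = v
            continue
        cur = v
        if resolved.graph.in_degree(v) >= 2:
            while cur not in original_nodes:
                cur = resolved.child(cur)
        else:
            while cur not in original_nodes:
                cur = resolved.parent(cur)
        mapping[v] = cur
    return mapping


def orchard_resolution(network: Network) -> Optional[ResolutionWitness]:
    """The first binary resolution admitting an HGT-consistent
    labelling, or None if no resolution is orchard.

    Exhausts the (isomorphism-deduplicated) resolution space, so the
    input must be desk-scale; the enumeration refuses more than 10**4
    candidate resolutions.
    """
    for resolved in binary_resolutions(network):
        ok, labelling, _ = labelling_exists(resolved)
        if ok:
            return ResolutionWitness(
                resolved=resolved,
                contraction_map=_contraction_map(network, resolved),
                labelling=labelling,
            )
    return None
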