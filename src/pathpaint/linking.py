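"""Bind diagram nodes to measurement channels and perturbations.

A channel link marks a node as *observed*: during painting it takes its color
from the linked channel. A perturbation link records that an experimental
condition acts on a node with an enhansive or repressive effect; perturbation
links drive Boolean-simulation clamping and a badge in rendering, but do not
alter painted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data import DimensionIndex
from .diagram import Diagram
from .errors import ConflictError, RefError

ENHANSIVE = "enhansive"
REPRESSIVE = "repressive"
EFFECTS = (ENHANSIVE, REPRESSIVE)


@dataclass
class ChannelLink:
    node_id: str
    channel: str


@dataclass
class PerturbationLink:
    node_id: str
    condition: str
    effect: str


@dataclass
class LinkMap:
    channel_links: list[ChannelLink] = field(default_factory=list)
    perturbation_links: list[PerturbationLink] = field(default_factory=list)

    def channel_for(self, node_id: str) -> str | None:
        for link in self.channel_links:
            if link.node_id == node_id:
                return link.channel
        return None

    def perturbations_for(self, node_id: str) -> list[PerturbationLink]:
        return [p for p in self.perturbation_links if p.node_id == node_id]


def link_channel(linkmap: LinkMap, diagram: Diagram, index: DimensionIndex,
                 node_id: str, channel: str) -> LinkMap:
    """Link a node to a channel; at most one channel link per node."""
    node = diagram.node(node_id)  # raises RefError
    if channel not in index.channels:
        raise RefError(f"unknown channel {channel!r}")
    if linkmap.channel_for(node_id) is not None:
        raise ConflictError(f"node {node_id!r} already has a channel link")
    linkmap.channel_links.append(ChannelLink(node_id, channel))
    node.observed = True
    return linkmap


def link_perturbation(linkmap: LinkMap, diagram: Diagram, index: DimensionIndex,
                      node_id: str, condition: str, effect: str) -> LinkMap:
    """Record a perturbation link; a node may carry several, one per condition."""
    diagram.node(node_id)
    if condition not in index.conditions:
        raise RefError(f"unknown condition {condition!r}")
    if effect not in EFFECTS:
        raise RefError(f"effect must be one of {EFFECTS}, got {effect!r}")
    linkmap.perturbation_links.append(PerturbationLink(node_id, condition, effect))
    return linkmap


def observed_partition(diagram: Diagram, linkmap: LinkMap
                       ) -> tuple[list[str], list[str]]:
    """Partition all node ids into (observed, unobserved) by channel link."""
    linked = {link.node_id for link in linkmap.channel_links}
    observed = [n.id for n in diagram.nodes if n.id in linked]
    unobserved = [n.id for n in diagram.nodes if n.id not in linked]
    return observed, unobserved
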