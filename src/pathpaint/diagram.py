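"""Data model for classical textbook-style pathway diagrams.

A :class:`Diagram` is a canvas holding subcellular :class:`Compartment`
rectangles, shaped :class:`Node` biomolecules and signed :class:`Edge` arrows
(activating or inhibiting). Coordinates are pixels with the origin at the
top-left and y increasing downward (SVG convention); a node's ``position`` is
the center of its shape.

Constructive operations (:func:`add_compartment`, :func:`add_node`,
:func:`add_edge`) check their preconditions and keep the diagram valid;
:func:`validate` re-checks every invariant and reports violations as data
rather than raising, so that imported or hand-edited documents can be
diagnosed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import DuplicateError, RefError, ValidationError
from .shapes import SHAPE_REGISTRY

ACTIVATE = "activate"
INHIBIT = "inhibit"
SENSES = (ACTIVATE, INHIBIT)

COMPARTMENT_KINDS = ("extracellular", "membrane", "cytoplasm", "nucleus", "custom")

#: Top-to-bottom stacking order of the standard compartment kinds.
BIOLOGICAL_ORDER = ("extracellular", "membrane", "cytoplasm", "nucleus")


@dataclass
class Style:
    fill: str = "#ffffff"
    stroke: str = "#000000"


@dataclass
class Compartment:
    """A rectangular subcellular region (extracellular space, membrane, ...)."""

    id: str
    name: str
    kind: str = "custom"
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)  # x, y, w, h
    style: Style = field(default_factory=Style)


@dataclass
class Node:
    """A biomolecule on the diagram, centered at ``position``."""

    id: str
    label: str
    compartment_id: str
    shape_id: str = "ellipse"
    position: tuple[float, float] = (0.0, 0.0)
    size: tuple[float, float] = (60.0, 30.0)
    style: Style = field(default_factory=Style)
    observed: bool = False


@dataclass
class Edge:
    """A signed arrow between two distinct nodes."""

    id: str
    source: str
    target: str
    sense: str = ACTIVATE
    waypoints: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class Violation:
    """One invariant violation found by :func:`validate`."""

    entity_id: str
    rule: str
    message: str


@dataclass
class Diagram:
    name: str
    canvas: tuple[float, float]
    compartments: list[Compartment] = field(default_factory=list)
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def compartment(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise RefError(f"unknown compartment {cid!r}")

    def node(self, nid: str) -> Node:
        for n in self.nodes:
            if n.id == nid:
                return n
        raise RefError(f"unknown node {nid!r}")

    def node_by_label(self, label: str) -> Node:
        for n in self.nodes:
            if n.label == label:
                return n
        raise RefError(f"no node labelled {label!r}")

    def all_ids(self) -> set[str]:
        return (
            {c.id for c in self.compartments}
            | {n.id for n in self.nodes}
            | {e.id for e in self.edges}
        )

    def _fresh_id(self, prefix: str) -> str:
        taken = self.all_ids()
        i = len(self.nodes) + len(self.edges) + len(self.compartments)
        while f"{prefix}{i}" in taken:
            i += 1
        return f"{prefix}{i}"


def create_diagram(name: str, canvas: tuple[float, float]) -> Diagram:
    """Create an empty diagram with a positive canvas."""
    w, h = canvas
    if w <= 0 or h <= 0:
        raise ValidationError(f"canvas dimensions must be positive, got {canvas}")
    return Diagram(name=name, canvas=(float(w), float(h)))


def add_compartment(
    diagram: Diagram,
    name: str,
    kind: str = "custom",
    bounds: tuple[float, float, float, float] | None = None,
    style: Style | None = None,
    id: str | None = None,
) -> Compartment:
    if kind not in COMPARTMENT_KINDS:
        raise ValidationError(f"unknown compartment kind {kind!r}")
    if bounds is None:
        bounds = (0.0, 0.0, diagram.canvas[0], diagram.canvas[1])
    if bounds[2] <= 0 or bounds[3] <= 0:
        raise ValidationError(f"compartment bounds degenerate: {bounds}")
    cid = id or diagram._fresh_id("c")
    if cid in diagram.all_ids():
        raise DuplicateError(f"id {cid!r} already used")
    comp = Compartment(id=cid, name=name, kind=kind, bounds=tuple(map(float, bounds)),
                       style=style or Style())
    diagram.compartments.append(comp)
    return comp


def add_node(
    diagram: Diagram,
    label: str,
    compartment_id: str,
    shape_id: str = "ellipse",
    position: tuple[float, float] | None = None,
    size: tuple[float, float] = (60.0, 30.0),
    style: Style | None = None,
    id: str | None = None,
) -> Node:
    """Append a node; the compartment and shape must exist.

    If ``position`` is omitted the node is placed at the compartment center
    (automatic layout can rearrange it later).
    """
    comp = diagram.compartment(compartment_id)  # raises RefError
    if shape_id not in SHAPE_REGISTRY:
        raise RefError(f"unknown shape {shape_id!r}")
    if position is None:
        x, y, w, h = comp.bounds
        position = (x + w / 2.0, y + h / 2.0)
    nid = id or diagram._fresh_id("n")
    if nid in diagram.all_ids():
        raise DuplicateError(f"id {nid!r} already used")
    node = Node(
        id=nid, label=label, compartment_id=compartment_id, shape_id=shape_id,
        position=(float(position[0]), float(position[1])),
        size=(float(size[0]), float(size[1])), style=style or Style(),
    )
    diagram.nodes.append(node)
    return node


def add_edge(diagram: Diagram, source_id: str, target_id: str, sense: str = ACTIVATE,
             id: str | None = None) -> Edge:
    """Append a signed edge.

    Self-loops are rejected (autoregulation must go through an intermediate
    node) and parallel edges with identical (source, target, sense) are
    duplicates.
    """
    diagram.node(source_id)
    diagram.node(target_id)
    if source_id == target_id:
        raise ValidationError(f"self-loop on {source_id!r} rejected")
    if sense not in SENSES:
        raise ValidationError(f"sense must be one of {SENSES}, got {sense!r}")
    for e in diagram.edges:
        if (e.source, e.target, e.sense) == (source_id, target_id, sense):
            raise DuplicateError(
                f"edge ({source_id}, {target_id}, {sense}) already present")
    eid = id or diagram._fresh_id("e")
    if eid in diagram.all_ids():
        raise DuplicateError(f"id {eid!r} already used")
    edge = Edge(id=eid, source=source_id, target=target_id, sense=sense)
    diagram.edges.append(edge)
    return edge


def _contains(bounds: tuple[float, float, float, float], point: tuple[float, float]) -> bool:
    x, y, w, h = bounds
    px, py = point
    return x <= px <= x + w and y <= py <= y + h


def validate(diagram: Diagram) -> list[Violation]:
    """Check every structural invariant; return violations (empty = valid)."""
    out: list[Violation] = []
    seen: set[str] = set()
    for entity in (*diagram.compartments, *diagram.nodes, *diagram.edges):
        if entity.id in seen:
            out.append(Violation(entity.id, "unique-ids", f"duplicate id {entity.id!r}"))
        seen.add(entity.id)
    if diagram.canvas[0] <= 0 or diagram.canvas[1] <= 0:
        out.append(Violation(diagram.name, "canvas", "canvas dimensions must be positive"))
    comp_ids = {c.id for c in diagram.compartments}
    for c in diagram.compartments:
        if c.bounds[2] <= 0 or c.bounds[3] <= 0:
            out.append(Violation(c.id, "bounds", f"degenerate bounds {c.bounds}"))
        if c.kind not in COMPARTMENT_KINDS:
            out.append(Violation(c.id, "kind", f"unknown kind {c.kind!r}"))
    node_ids = set()
    for n in diagram.nodes:
        node_ids.add(n.id)
        if n.compartment_id not in comp_ids:
            out.append(Violation(
                n.id, "compartment-ref",
                f"node {n.id!r} references missing compartment {n.compartment_id!r}"))
        elif not _contains(diagram.compartment(n.compartment_id).bounds, n.position):
            out.append(Violation(
                n.id, "containment",
                f"node {n.id!r} center {n.position} outside compartment "
                f"{n.compartment_id!r}"))
        if n.shape_id not in SHAPE_REGISTRY:
            out.append(Violation(n.id, "shape-ref", f"unknown shape {n.shape_id!r}"))
    for e in diagram.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in node_ids:
                out.append(Violation(
                    e.id, "edge-ref", f"edge {e.id!r} endpoint {endpoint!r} missing"))
        if e.source == e.target:
            out.append(Violation(e.id, "self-loop", f"edge {e.id!r} is a self-loop"))
        if e.sense not in SENSES:
            out.append(Violation(e.id, "sense", f"bad sense {e.sense!r}"))
    return out


def copy_diagram(diagram: Diagram) -> Diagram:
    """Deep-ish copy (new entity objects, shared immutable members)."""
    return Diagram(
        name=diagram.name,
        canvas=diagram.canvas,
        compartments=[replace(c, style=replace(c.style)) for c in diagram.compartments],
        nodes=[replace(n, style=replace(n.style)) for n in diagram.nodes],
        edges=[replace(e, waypoints=list(e.waypoints)) for e in diagram.edges],
        metadata=dict(diagram.metadata),
    )
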