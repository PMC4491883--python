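"""The node shape registry.

Twenty-six shapes are available for biomolecule nodes: the regular polygons
with 3..10 sides, a set of generic container shapes (rectangles, ellipses,
pills, chevrons, receptors, a membrane channel, a star), and stylized glyphs
for DNA, RNA and protein plus common annotation variants (phospho-protein,
complex, degradation sink).

The registry is immutable at runtime: :func:`list_shapes` returns copies and
the module exposes no mutation API.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType


@dataclass(frozen=True)
class ShapeSpec:
    """A registered node shape.

    Attributes
    ----------
    shape_id:
        Stable identifier used in diagram documents.
    kind:
        Geometry family: ``polygon`` (with ``sides``), ``ellipse``, ``rect``
        or ``glyph`` (freeform path).
    sides:
        Number of sides for the ``polygon`` family, else 0.
    """

    shape_id: str
    kind: str
    sides: int = 0


def _build_registry() -> "MappingProxyType[str, ShapeSpec]":
    specs: list[ShapeSpec] = []
    polygon_names = {
        3: "triangle",
        4: "square",
        5: "pentagon",
        6: "hexagon",
        7: "heptagon",
        8: "octagon",
        9: "nonagon",
        10: "decagon",
    }
    for sides, name in polygon_names.items():
        specs.append(ShapeSpec(name, "polygon", sides))
    specs += [
        ShapeSpec("rectangle", "rect"),
        ShapeSpec("rounded-rectangle", "rect"),
        ShapeSpec("ellipse", "ellipse"),
        ShapeSpec("circle", "ellipse"),
        ShapeSpec("diamond", "polygon", 4),
        ShapeSpec("elongated-hexagon", "polygon", 6),
        ShapeSpec("pill", "rect"),
        ShapeSpec("chevron", "polygon", 5),
        ShapeSpec("double-circle", "ellipse"),   # receptor
        ShapeSpec("cup", "glyph"),               # receptor
        ShapeSpec("membrane-channel", "glyph"),
        ShapeSpec("star", "polygon", 10),
        ShapeSpec("dna", "glyph"),
        ShapeSpec("rna", "glyph"),
        ShapeSpec("protein", "glyph"),
        ShapeSpec("phospho-protein", "glyph"),
        ShapeSpec("complex", "glyph"),
        ShapeSpec("degradation-sink", "glyph"),
    ]
    registry = {s.shape_id: s for s in specs}
    if len(registry) != 26:  # pragma: no cover - guards the module itself
        raise AssertionError(f"shape registry must hold 26 shapes, got {len(registry)}")
    return MappingProxyType(registry)


SHAPE_REGISTRY = _build_registry()


def list_shapes() -> list[ShapeSpec]:
    """Return the 26 registered shapes in a stable order."""
    return list(SHAPE_REGISTRY.values())


def get_shape(shape_id: str) -> ShapeSpec:
    """Look up a shape by id; raises ``KeyError`` if unregistered."""
    return SHAPE_REGISTRY[shape_id]
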