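"""Automatic arrangement of diagram nodes within their compartments.

The algorithm is deliberately simple and fully deterministic:

1. Compartments with the standard kinds are restacked full-width in
   biological order (extracellular above membrane above cytoplasm above
   nucleus), preserving their relative heights; custom compartments keep
   their bounds.
2. Within each compartment, nodes are placed on a padded grid. Their order
   along the grid is refined by a few barycenter sweeps (each node moves
   toward the mean x of its neighbors in the edge graph), which tends to
   reduce edge crossings.
3. The grid guarantees the post-conditions directly: every node center is
   inside its compartment and no two node boxes overlap. A compartment whose
   grid cannot host its nodes raises :class:`LayoutError`.

The seed only feeds a tie-break jitter; for a fixed seed the result is a
pure function of the input diagram.
"""

from __future__ import annotations

import numpy as np

from .diagram import BIOLOGICAL_ORDER, Diagram, copy_diagram
from .errors import LayoutError

PAD = 12.0  # minimum gap between node boxes and to compartment borders
SWEEPS = 3


def auto_layout(diagram: Diagram, seed: int = 0) -> Diagram:
    """Return a copy of the diagram with non-overlapping, contained positions."""
    out = copy_diagram(diagram)
    if not out.nodes:
        return out
    rng = np.random.default_rng(seed)
    _restack_compartments(out)
    positions = {n.id: n.position for n in out.nodes}
    neighbors = _neighbor_map(out)

    for comp in out.compartments:
        members = [n for n in out.nodes if n.compartment_id == comp.id]
        if not members:
            continue
        members.sort(key=lambda n: (n.position[0], n.label, n.id))
        order = list(range(len(members)))
        # barycenter sweeps: sort members by mean neighbor x
        for _ in range(SWEEPS):
            def barycenter(n):
                xs = [positions[m][0] for m in neighbors.get(n.id, ())]
                return float(np.mean(xs)) if xs else positions[n.id][0]
            jitter = {n.id: rng.uniform(0, 1e-6) for n in members}
            members.sort(key=lambda n: (barycenter(n) + jitter[n.id], n.label, n.id))
            _place_on_grid(comp, members)
            for n in members:
                positions[n.id] = n.position
        _place_on_grid(comp, members)
        for n in members:
            positions[n.id] = n.position
    return out


def _restack_compartments(diagram: Diagram) -> None:
    standard = [c for c in diagram.compartments if c.kind in BIOLOGICAL_ORDER]
    if not standard:
        return
    standard.sort(key=lambda c: BIOLOGICAL_ORDER.index(c.kind))
    total_h = sum(c.bounds[3] for c in standard)
    scale = min(1.0, diagram.canvas[1] / total_h)
    y = 0.0
    for c in standard:
        h = c.bounds[3] * scale
        c.bounds = (0.0, y, diagram.canvas[0], h)
        y += h


def _neighbor_map(diagram: Diagram) -> dict[str, list[str]]:
    nb: dict[str, list[str]] = {}
    for e in diagram.edges:
        nb.setdefault(e.source, []).append(e.target)
        nb.setdefault(e.target, []).append(e.source)
    return nb


def _place_on_grid(comp, members) -> None:
    # Containment is center-only, so node boxes may overhang thin
    # compartments (membranes); the grid only has to keep centers inside and
    # boxes apart.
    x0, y0, w, h = comp.bounds
    cell_w = max(n.size[0] for n in members) + PAD
    cell_h = max(n.size[1] for n in members) + PAD
    cols = max(1, int(w // cell_w))
    rows_needed = -(-len(members) // cols)
    span_h = (rows_needed - 1) * cell_h
    if span_h > h:
        raise LayoutError(
            f"compartment {comp.id!r} ({w:.0f}x{h:.0f}) too small for "
            f"{len(members)} nodes")
    y_start = y0 + (h - span_h) / 2.0
    for i, n in enumerate(members):
        r, c = divmod(i, cols)
        row_len = min(cols, len(members) - r * cols)
        row_span = (row_len - 1) * cell_w
        cx = x0 + (w - row_span) / 2.0 + c * cell_w
        cy = y_start + r * cell_h
        n.position = (float(cx), float(cy))


def count_crossings(diagram: Diagram) -> int:
    """Number of intersecting straight-line edge pairs (shared endpoints
    excluded) — a cheap layout-quality metric."""
    pos = {n.id: n.position for n in diagram.nodes}
    segs = [(pos[e.source], pos[e.target], e.source, e.target) for e in diagram.edges]
    crossings = 0
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            a, b, sa, ta = segs[i]
            c, d, sb, tb = segs[j]
            if {sa, ta} & {sb, tb}:
                continue
            if _segments_cross(a, b, c, d):
                crossings += 1
    return crossings


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return (v > 0) - (v < 0)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def boxes_overlap(diagram: Diagram) -> list[tuple[str, str]]:
    """Pairs of nodes whose bounding boxes overlap (empty after layout)."""
    out = []
    nodes = diagram.nodes
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            ax, ay = a.position
            bx, by = b.position
            if (abs(ax - bx) < (a.size[0] + b.size[0]) / 2.0
                    and abs(ay - by) < (a.size[1] + b.size[1]) / 2.0):
                out.append((a.id, b.id))
    return out
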