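"""Render painted frames to SVG and raster images, and assemble animations.

Every frame renders as four SVG groups — compartments, edges, nodes, chrome
(legend + timestamp) — so the element inventory of a frame is a predictable
function of the diagram structure. Each node is exactly one SVG shape element
(polygon/ellipse/rect/path, chosen by its shape spec) filled with the frame
color; unobserved or no-data nodes are grey. Observed nodes can carry a small
heatmap glyph below them whose cells use the same colormap as the node fill.

Rasterization draws the same scene with Pillow at a configurable scale;
animated GIFs are Pillow image sequences with the loop flag set.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image, ImageDraw

from .diagram import Diagram
from .errors import ContractError
from .heatmap import HeatmapGrid
from .paint import NO_DATA_COLOR, ColorMap, FrameSeries, map_color
from .shapes import get_shape

SVG_NS = "http://www.w3.org/2000/svg"

GLYPH_CELL = 6.0   # px per heatmap glyph cell
GLYPH_GAP = 4.0    # gap between node box and its glyph
LEGEND_W, LEGEND_H = 120.0, 10.0


@dataclass
class RenderOptions:
    grey_compartments: bool = False
    show_heatmaps: bool = True
    show_legend: bool = True
    scale: float = 1.0  # raster scale factor (pixels per diagram unit)


def _hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _polygon_points(cx: float, cy: float, w: float, h: float, sides: int,
                    shape_id: str) -> list[tuple[float, float]]:
    if shape_id == "diamond":
        return [(cx, cy - h / 2), (cx + w / 2, cy), (cx, cy + h / 2), (cx - w / 2, cy)]
    if shape_id == "chevron":
        return [(cx - w / 2, cy - h / 2), (cx + w / 4, cy - h / 2), (cx + w / 2, cy),
                (cx + w / 4, cy + h / 2), (cx - w / 2, cy + h / 2)]
    if shape_id == "elongated-hexagon":
        return [(cx - w / 2, cy), (cx - w / 4, cy - h / 2), (cx + w / 4, cy - h / 2),
                (cx + w / 2, cy), (cx + w / 4, cy + h / 2), (cx - w / 4, cy + h / 2)]
    if shape_id == "star":
        pts = []
        for k in range(10):
            r = 0.5 if k % 2 == 0 else 0.22
            ang = -math.pi / 2 + k * math.pi / 5
            pts.append((cx + r * w * math.cos(ang), cy + r * h * math.sin(ang)))
        return pts
    # regular polygon, apex up
    pts = []
    for k in range(sides):
        ang = -math.pi / 2 + 2 * math.pi * k / sides
        pts.append((cx + 0.5 * w * math.cos(ang), cy + 0.5 * h * math.sin(ang)))
    return pts


def _glyph_path(shape_id: str, cx: float, cy: float, w: float, h: float) -> str:
    x0, y0, x1, y1 = cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2
    if shape_id == "dna":  # two crossing strands
        return (f"M {x0:.1f} {y0:.1f} C {cx:.1f} {cy:.1f} {cx:.1f} {cy:.1f} "
                f"{x1:.1f} {y1:.1f} M {x0:.1f} {y1:.1f} C {cx:.1f} {cy:.1f} "
                f"{cx:.1f} {cy:.1f} {x1:.1f} {y0:.1f} Z")
    if shape_id == "rna":  # single wavy strand
        return (f"M {x0:.1f} {cy:.1f} Q {cx - w / 4:.1f} {y0:.1f} {cx:.1f} {cy:.1f} "
                f"Q {cx + w / 4:.1f} {y1:.1f} {x1:.1f} {cy:.1f} Z")
    if shape_id == "cup":
        return (f"M {x0:.1f} {y0:.1f} L {x0:.1f} {y1:.1f} L {x1:.1f} {y1:.1f} "
                f"L {x1:.1f} {y0:.1f} L {cx + w / 4:.1f} {y0:.1f} "
                f"L {cx:.1f} {cy:.1f} L {cx - w / 4:.1f} {y0:.1f} Z")
    if shape_id == "membrane-channel":
        return (f"M {x0:.1f} {y0:.1f} L {cx - w / 6:.1f} {y0:.1f} "
                f"L {cx - w / 6:.1f} {y1:.1f} L {x0:.1f} {y1:.1f} Z "
                f"M {cx + w / 6:.1f} {y0:.1f} L {x1:.1f} {y0:.1f} "
                f"L {x1:.1f} {y1:.1f} L {cx + w / 6:.1f} {y1:.1f} Z")
    if shape_id == "degradation-sink":
        return (f"M {cx:.1f} {y0:.1f} A {w / 2:.1f} {h / 2:.1f} 0 1 1 "
                f"{cx - 0.01:.1f} {y0:.1f} Z M {x0:.1f} {y1:.1f} L {x1:.1f} {y0:.1f}")
    if shape_id == "complex":  # two stacked boxes
        return (f"M {x0:.1f} {y0:.1f} H {x1:.1f} V {cy:.1f} H {x0:.1f} Z "
                f"M {x0:.1f} {cy:.1f} H {x1:.1f} V {y1:.1f} H {x0:.1f} Z")
    # protein / phospho-protein blobs
    return (f"M {x0:.1f} {cy:.1f} C {x0:.1f} {y0:.1f} {x1:.1f} {y0:.1f} "
            f"{x1:.1f} {cy:.1f} C {x1:.1f} {y1:.1f} {x0:.1f} {y1:.1f} "
            f"{x0:.1f} {cy:.1f} Z")


# ---------------------------------------------------------------------------
# SVG


def render_frame(diagram: Diagram, frames: FrameSeries, frame_index: int,
                 heatmaps: dict[str, HeatmapGrid] | None = None,
                 options: RenderOptions | None = None) -> str:
    """One frame as a well-formed standalone SVG document."""
    options = options or RenderOptions()
    if frame_index < 0 or frame_index >= frames.n_frames():
        raise ContractError(f"frame index {frame_index} out of range")
    missing = [n.id for n in diagram.nodes if n.id not in frames.values]
    if missing:
        raise ContractError(f"frame does not cover nodes {missing}")

    w, h = diagram.canvas
    svg = etree.Element(f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS},
                        width=str(w), height=str(h),
                        viewBox=f"0 0 {w} {h}")

    g_comp = etree.SubElement(svg, f"{{{SVG_NS}}}g", id="compartments")
    for c in diagram.compartments:
        x, y, cw, ch = c.bounds
        fill = "#d9d9d9" if options.grey_compartments else c.style.fill
        etree.SubElement(g_comp, f"{{{SVG_NS}}}rect", x=str(x), y=str(y),
                         width=str(cw), height=str(ch), fill=fill,
                         stroke=c.style.stroke)

    g_edges = etree.SubElement(svg, f"{{{SVG_NS}}}g", id="edges")
    pos = {n.id: n.position for n in diagram.nodes}
    for e in diagram.edges:
        (x1, y1), (x2, y2) = pos[e.source], pos[e.target]
        line = etree.SubElement(g_edges, f"{{{SVG_NS}}}line",
                                x1=str(x1), y1=str(y1), x2=str(x2), y2=str(y2),
                                stroke="#333333")
        line.set("stroke-dasharray", "4 3" if e.sense == "inhibit" else "none")

    g_nodes = etree.SubElement(svg, f"{{{SVG_NS}}}g", id="nodes")
    for n in diagram.nodes:
        color = frames.colors.get(n.id, [NO_DATA_COLOR] * frames.n_frames())[frame_index]
        fill = _hex(color)
        spec = get_shape(n.shape_id)
        cx, cy = n.position
        nw, nh = n.size
        if spec.kind == "ellipse":
            etree.SubElement(g_nodes, f"{{{SVG_NS}}}ellipse", cx=str(cx), cy=str(cy),
                             rx=str(nw / 2), ry=str(nh / 2), fill=fill,
                             stroke=n.style.stroke)
        elif spec.kind == "rect":
            rx = "0" if n.shape_id == "rectangle" else str(min(nw, nh) / 4)
            etree.SubElement(g_nodes, f"{{{SVG_NS}}}rect", x=str(cx - nw / 2),
                             y=str(cy - nh / 2), width=str(nw), height=str(nh),
                             rx=rx, fill=fill, stroke=n.style.stroke)
        elif spec.kind == "polygon":
            pts = _polygon_points(cx, cy, nw, nh, spec.sides, n.shape_id)
            etree.SubElement(
                g_nodes, f"{{{SVG_NS}}}polygon",
                points=" ".join(f"{px:.1f},{py:.1f}" for px, py in pts),
                fill=fill, stroke=n.style.stroke)
        else:  # glyph
            etree.SubElement(g_nodes, f"{{{SVG_NS}}}path",
                             d=_glyph_path(n.shape_id, cx, cy, nw, nh),
                             fill=fill, stroke=n.style.stroke)
        label = etree.SubElement(g_nodes, f"{{{SVG_NS}}}text", x=str(cx), y=str(cy))
        label.set("text-anchor", "middle")
        label.set("font-size", "10")
        label.set("font-family", "sans-serif")
        label.text = n.label

    if options.show_heatmaps and heatmaps:
        g_hm = etree.SubElement(svg, f"{{{SVG_NS}}}g", id="heatmaps")
        t = frames.times[frame_index]
        for n in diagram.nodes:
            grid = heatmaps.get(n.id)
            if grid is None:
                continue
            _svg_heatmap_glyph(g_hm, n, grid, t, frames.cmap)

    g_chrome = etree.SubElement(svg, f"{{{SVG_NS}}}g", id="chrome")
    if options.show_legend and frames.cmap is not None:
        _svg_legend(g_chrome, frames.cmap, w, h)
    ts = etree.SubElement(g_chrome, f"{{{SVG_NS}}}text", x="8", y=str(h - 8))
    ts.set("font-size", "12")
    ts.set("font-family", "sans-serif")
    ts.text = f"t = {frames.times[frame_index]:g} min"

    return etree.tostring(svg, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


def _glyph_time(grid: HeatmapGrid, t: float) -> float:
    """Nearest keyframe time with a grid (interpolated frames reuse it)."""
    times = sorted(grid.values)
    return min(times, key=lambda kt: (abs(kt - t), kt))


def _svg_heatmap_glyph(parent, node, grid: HeatmapGrid, t: float,
                       cmap: ColorMap | None) -> None:
    vals = grid.ordered(_glyph_time(grid, t))
    rows, cols = vals.shape
    x0 = node.position[0] - cols * GLYPH_CELL / 2
    y0 = node.position[1] + node.size[1] / 2 + GLYPH_GAP
    for r in range(rows):
        for c in range(cols):
            v = vals[r, c]
            color = map_color(None if np.isnan(v) else float(v),
                              cmap) if cmap else NO_DATA_COLOR
            etree.SubElement(parent, f"{{{SVG_NS}}}rect",
                             x=str(x0 + c * GLYPH_CELL), y=str(y0 + r * GLYPH_CELL),
                             width=str(GLYPH_CELL), height=str(GLYPH_CELL),
                             fill=_hex(color), stroke="none")


def _svg_legend(parent, cmap: ColorMap, w: float, h: float) -> None:
    x0, y0 = w - LEGEND_W - 10, h - LEGEND_H - 22
    steps = 24
    for i in range(steps):
        frac = i / (steps - 1)
        lo, hi = cmap.domain
        color = map_color(lo + frac * (hi - lo), cmap)
        etree.SubElement(parent, f"{{{SVG_NS}}}rect",
                         x=str(x0 + i * LEGEND_W / steps), y=str(y0),
                         width=str(LEGEND_W / steps + 0.5), height=str(LEGEND_H),
                         fill=_hex(color), stroke="none")
    for frac, anchor in ((0.0, "start"), (1.0, "end")):
        lo, hi = cmap.domain
        txt = etree.SubElement(parent, f"{{{SVG_NS}}}text",
                               x=str(x0 + frac * LEGEND_W), y=str(y0 + LEGEND_H + 10))
        txt.set("font-size", "9")
        txt.set("font-family", "sans-serif")
        txt.set("text-anchor", anchor)
        txt.text = f"{lo + frac * (hi - lo):.2g}"


# ---------------------------------------------------------------------------
# raster


def rasterize_frame(diagram: Diagram, frames: FrameSeries, frame_index: int,
                    heatmaps: dict[str, HeatmapGrid] | None = None,
                    options: RenderOptions | None = None) -> Image.Image:
    """Draw one frame with Pillow (same scene as the SVG)."""
    options = options or RenderOptions()
    s = options.scale
    w, h = int(diagram.canvas[0] * s), int(diagram.canvas[1] * s)
    img = Image.new("RGB", (max(w, 1), max(h, 1)), "#ffffff")
    draw = ImageDraw.Draw(img)

    for c in diagram.compartments:
        x, y, cw, ch = (v * s for v in c.bounds)
        fill = "#d9d9d9" if options.grey_compartments else c.style.fill
        draw.rectangle([x, y, x + cw, y + ch], fill=fill, outline=c.style.stroke)

    pos = {n.id: (n.position[0] * s, n.position[1] * s) for n in diagram.nodes}
    for e in diagram.edges:
        draw.line([pos[e.source], pos[e.target]], fill="#333333", width=1)

    for n in diagram.nodes:
        color = frames.colors.get(n.id, [NO_DATA_COLOR] * frames.n_frames())[frame_index]
        cx, cy = pos[n.id]
        nw, nh = n.size[0] * s, n.size[1] * s
        spec = get_shape(n.shape_id)
        box = [cx - nw / 2, cy - nh / 2, cx + nw / 2, cy + nh / 2]
        if spec.kind == "polygon":
            pts = _polygon_points(cx, cy, nw, nh, spec.sides, n.shape_id)
            draw.polygon(pts, fill=color, outline=(0, 0, 0))
        elif spec.kind == "rect":
            draw.rectangle(box, fill=color, outline=(0, 0, 0))
        else:  # ellipse and glyphs rasterize as ellipses
            draw.ellipse(box, fill=color, outline=(0, 0, 0))

    if options.show_heatmaps and heatmaps:
        t = frames.times[frame_index]
        for n in diagram.nodes:
            grid = heatmaps.get(n.id)
            if grid is None:
                continue
            vals = grid.ordered(_glyph_time(grid, t))
            rows, cols = vals.shape
            gx0 = pos[n.id][0] - cols * GLYPH_CELL * s / 2
            gy0 = pos[n.id][1] + n.size[1] * s / 2 + GLYPH_GAP * s
            for r in range(rows):
                for c in range(cols):
                    v = vals[r, c]
                    color = map_color(None if np.isnan(v) else float(v), frames.cmap)
                    cell = GLYPH_CELL * s
                    draw.rectangle(
                        [gx0 + c * cell, gy0 + r * cell,
                         gx0 + (c + 1) * cell, gy0 + (r + 1) * cell], fill=color)
    return img


def render_animation(diagram: Diagram, frames: FrameSeries, format: str = "gif",
                     out: str | Path | None = None,
                     heatmaps: dict[str, HeatmapGrid] | None = None,
                     options: RenderOptions | None = None,
                     frame_ms: int = 80):
    """Render every frame of the series.

    ``gif``: returns GIF bytes (looping, ``frame_ms`` per frame) and writes
    ``out`` if given. ``png_sequence`` / ``svg_sequence``: returns the list
    of per-frame payloads; with ``out`` (a directory) files are written as
    ``frame_0000.png`` / ``.svg``.
    """
    if frames.n_frames() == 0:
        raise ContractError("animation needs at least one frame")
    if format == "gif":
        imgs = [rasterize_frame(diagram, frames, i, heatmaps, options)
                for i in range(frames.n_frames())]
        buf = io.BytesIO()
        imgs[0].save(buf, format="GIF", save_all=True, append_images=imgs[1:],
                     duration=frame_ms, loop=0)
        data = buf.getvalue()
        if out is not None:
            Path(out).write_bytes(data)
        return data
    if format == "png_sequence":
        payloads = []
        for i in range(frames.n_frames()):
            img = rasterize_frame(diagram, frames, i, heatmaps, options)
            buf = io.BytesIO()
            img.save(buf, format="PNG")
            payloads.append(buf.getvalue())
        _write_seq(payloads, out, "png")
        return payloads
    if format == "svg_sequence":
        payloads = [render_frame(diagram, frames, i, heatmaps, options)
                    for i in range(frames.n_frames())]
        _write_seq([p.encode() for p in payloads], out, "svg")
        return payloads
    raise ContractError(f"unknown animation format {format!r}")


def _write_seq(payloads: list[bytes], out, ext: str) -> None:
    if out is None:
        return
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, data in enumerate(payloads):
        (outdir / f"frame_{i:04d}.{ext}").write_bytes(data)
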