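"""Serialization: the diagram JSON document, SBML export, KGML import and
the plain-text Boolean rule listing.

The diagram document is a versioned JSON object embedding the diagram, the
link map and the paint config. Serialization is canonical (sorted keys,
2-space indent) and unknown extra fields survive a read/write cycle, so
documents written by newer versions re-emit byte-identically.

SBML export targets Level 3 with the qualitative-models (``qual``) package:
the diagram carries no kinetics, so nodes become qualitative species and
signed edges become transitions with positive/negative inputs.

KGML (KEGG Markup Language) import is offline-file only: ``entry`` elements
become nodes with their graphics coordinates mapped 1:1 to canvas pixels and
``relation`` elements of subtype activation/inhibition become signed edges;
other subtypes are skipped and counted.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .boolean import BooleanRule
from .diagram import (Compartment, Diagram, Edge, Node, Style, add_compartment,
                      create_diagram, validate)
from .errors import ParseError, SchemaError
from .linking import ChannelLink, LinkMap, PerturbationLink
from .paint import PaintConfig

logger = logging.getLogger(__name__)

DOCUMENT_VERSION = 1

_KNOWN_TOP = {"version", "diagram", "links", "config"}


@dataclass
class DiagramDocument:
    diagram: Diagram
    linkmap: LinkMap = field(default_factory=LinkMap)
    config: PaintConfig = field(default_factory=PaintConfig)
    version: int = DOCUMENT_VERSION
    extras: dict = field(default_factory=dict)  # unknown fields, preserved


# ---------------------------------------------------------------------------
# diagram JSON


def _style_dict(s: Style) -> dict:
    return {"fill": s.fill, "stroke": s.stroke}


def _diagram_dict(d: Diagram) -> dict:
    return {
        "name": d.name,
        "canvas": list(d.canvas),
        "compartments": [
            {"id": c.id, "name": c.name, "kind": c.kind, "bounds": list(c.bounds),
             "style": _style_dict(c.style)}
            for c in d.compartments
        ],
        "nodes": [
            {"id": n.id, "label": n.label, "compartment": n.compartment_id,
             "shape": n.shape_id, "position": list(n.position),
             "size": list(n.size), "style": _style_dict(n.style),
             "observed": n.observed}
            for n in d.nodes
        ],
        "edges": [
            {"id": e.id, "source": e.source, "target": e.target, "sense": e.sense,
             "waypoints": [list(p) for p in e.waypoints]}
            for e in d.edges
        ],
        "metadata": dict(d.metadata),
    }


def write_json(diagram: Diagram, linkmap: LinkMap | None = None,
               config: PaintConfig | None = None, path: str | Path | None = None,
               extras: dict | None = None) -> str:
    """Serialize to the canonical document text; optionally write ``path``."""
    doc = dict(extras or {})
    doc["version"] = DOCUMENT_VERSION
    doc["diagram"] = _diagram_dict(diagram)
    doc["links"] = {
        "channel_links": [{"node": l.node_id, "channel": l.channel}
                          for l in (linkmap or LinkMap()).channel_links],
        "perturbation_links": [
            {"node": l.node_id, "condition": l.condition, "effect": l.effect}
            for l in (linkmap or LinkMap()).perturbation_links],
    }
    doc["config"] = (config or PaintConfig()).to_dict()
    text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _need(d: dict, key: str, path: str):
    if key not in d:
        raise SchemaError(f"missing {path}/{key}")
    return d[key]


def read_json(source: str | Path) -> DiagramDocument:
    """Parse a diagram document (text, or a path to one)."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and source.endswith(".json")):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("document root must be an object")
    _need(doc, "version", "$")
    ddict = _need(doc, "diagram", "$")
    canvas = _need(ddict, "canvas", "$/diagram")
    diagram = create_diagram(_need(ddict, "name", "$/diagram"), tuple(canvas))
    for c in ddict.get("compartments", []):
        diagram.compartments.append(Compartment(
            id=c["id"], name=c["name"], kind=c.get("kind", "custom"),
            bounds=tuple(c["bounds"]), style=Style(**c.get("style", {}))))
    for n in ddict.get("nodes", []):
        diagram.nodes.append(Node(
            id=n["id"], label=n["label"], compartment_id=n["compartment"],
            shape_id=n["shape"], position=tuple(n["position"]),
            size=tuple(n["size"]), style=Style(**n.get("style", {})),
            observed=bool(n.get("observed", False))))
    for e in ddict.get("edges", []):
        diagram.edges.append(Edge(
            id=e["id"], source=e["source"], target=e["target"], sense=e["sense"],
            waypoints=[tuple(p) for p in e.get("waypoints", [])]))
    diagram.metadata = dict(ddict.get("metadata", {}))

    links = doc.get("links", {})
    linkmap = LinkMap(
        channel_links=[ChannelLink(l["node"], l["channel"])
                       for l in links.get("channel_links", [])],
        perturbation_links=[
            PerturbationLink(l["node"], l["condition"], l["effect"])
            for l in links.get("perturbation_links", [])],
    )
    config = PaintConfig.from_dict(doc.get("config", {}))
    extras = {k: v for k, v in doc.items() if k not in _KNOWN_TOP}
    return DiagramDocument(diagram=diagram, linkmap=linkmap, config=config,
                           version=int(doc["version"]), extras=extras)


# ---------------------------------------------------------------------------
# SBML export


SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"


def _sbml_id(raw: str) -> str:
    """SBML SIds must match [A-Za-z_][A-Za-z0-9_]*."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def export_sbml(diagram: Diagram) -> str:
    """Serialize the diagram as an SBML L3 qualitative model.

    One qualitative species per node (its compartment preserved), one
    transition per edge with the edge sense recorded as the input sign.
    """
    nsmap = {None: SBML_NS, "qual": QUAL_NS}
    sbml = etree.Element("sbml", nsmap=nsmap, level="3", version="1")
    sbml.set(f"{{{QUAL_NS}}}required", "true")
    model = etree.SubElement(sbml, "model", id=_sbml_id(diagram.name) or "model")

    if diagram.compartments:
        locs = etree.SubElement(model, "listOfCompartments")
        for c in diagram.compartments:
            etree.SubElement(locs, "compartment", id=_sbml_id(c.id),
                             name=c.name, constant="true")

    los = etree.SubElement(model, f"{{{QUAL_NS}}}listOfQualitativeSpecies")
    for n in diagram.nodes:
        sp = etree.SubElement(los, f"{{{QUAL_NS}}}qualitativeSpecies")
        sp.set(f"{{{QUAL_NS}}}id", _sbml_id(n.id))
        sp.set(f"{{{QUAL_NS}}}name", n.label)
        sp.set(f"{{{QUAL_NS}}}compartment", _sbml_id(n.compartment_id))
        sp.set(f"{{{QUAL_NS}}}constant", "false")
        sp.set(f"{{{QUAL_NS}}}maxLevel", "1")

    lot = etree.SubElement(model, f"{{{QUAL_NS}}}listOfTransitions")
    for e in diagram.edges:
        tr = etree.SubElement(lot, f"{{{QUAL_NS}}}transition")
        tr.set(f"{{{QUAL_NS}}}id", _sbml_id(e.id))
        loi = etree.SubElement(tr, f"{{{QUAL_NS}}}listOfInputs")
        inp = etree.SubElement(loi, f"{{{QUAL_NS}}}input")
        inp.set(f"{{{QUAL_NS}}}qualitativeSpecies", _sbml_id(e.source))
        inp.set(f"{{{QUAL_NS}}}sign",
                "positive" if e.sense == "activate" else "negative")
        inp.set(f"{{{QUAL_NS}}}transitionEffect", "none")
        loo = etree.SubElement(tr, f"{{{QUAL_NS}}}listOfOutputs")
        out = etree.SubElement(loo, f"{{{QUAL_NS}}}output")
        out.set(f"{{{QUAL_NS}}}qualitativeSpecies", _sbml_id(e.target))
        out.set(f"{{{QUAL_NS}}}transitionEffect", "assignmentLevel")

    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


# ---------------------------------------------------------------------------
# KGML import


_KGML_SENSE = {"activation": "activate", "expression": "activate",
               "inhibition": "inhibit", "repression": "inhibit"}

_MARGIN = 60.0


def import_kgml(path: str | Path) -> Diagram:
    """Build a diagram from a KGML pathway file on disk.

    Entries become nodes in a single cytoplasm compartment with KEGG graphics
    coordinates preserved; activation/inhibition relations become edges.
    Unsupported relation subtypes are skipped; their count is logged and
    stored in ``diagram.metadata['kgml_skipped_relations']``.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed KGML: {exc}") from exc
    root = tree.getroot()
    name = root.get("title") or root.get("name") or "kgml"

    entries = []
    for entry in root.findall("entry"):
        g = entry.find("graphics")
        if g is None:
            continue
        label = (g.get("name") or entry.get("name") or entry.get("id")).split(",")[0]
        entries.append({
            "id": entry.get("id"),
            "label": label,
            "x": float(g.get("x", 0)), "y": float(g.get("y", 0)),
            "w": float(g.get("width", 46)), "h": float(g.get("height", 17)),
        })
    if entries:
        width = max(e["x"] for e in entries) + _MARGIN
        height = max(e["y"] for e in entries) + _MARGIN
    else:
        width = height = 400.0
    diagram = create_diagram(name, (width, height))
    comp = add_compartment(diagram, "cytoplasm", kind="cytoplasm",
                           bounds=(0, 0, width, height), id="cytoplasm")
    for e in entries:
        diagram.nodes.append(Node(
            id=f"k{e['id']}", label=e["label"], compartment_id=comp.id,
            shape_id="rounded-rectangle", position=(e["x"], e["y"]),
            size=(e["w"], e["h"])))

    node_ids = {n.id for n in diagram.nodes}
    skipped = 0
    for i, rel in enumerate(root.findall("relation")):
        subtypes = [s.get("name") for s in rel.findall("subtype")]
        sense = next((_KGML_SENSE[s] for s in subtypes if s in _KGML_SENSE), None)
        src, dst = f"k{rel.get('entry1')}", f"k{rel.get('entry2')}"
        if sense is None or src not in node_ids or dst not in node_ids or src == dst:
            skipped += 1
            continue
        if any((e.source, e.target, e.sense) == (src, dst, sense)
               for e in diagram.edges):
            skipped += 1
            continue
        diagram.edges.append(Edge(id=f"r{i}", source=src, target=dst, sense=sense))
    if skipped:
        logger.info("KGML import: skipped %d unsupported relations", skipped)
    diagram.metadata["kgml_skipped_relations"] = skipped

    problems = validate(diagram)
    if problems:  # pragma: no cover - importer is built to keep diagrams valid
        raise ParseError(f"KGML import produced invalid diagram: {problems[0]}")
    return diagram


# ---------------------------------------------------------------------------
# Boolean rule text


def emit_boolean_script(rules: dict[str, BooleanRule]) -> str:
    """Readable, re-parseable rule listing: one ``node' = expr`` line per node.

    ``B' = (A OR D) AND NOT (C)``; a node with no regulators holds state
    (``B' = B``), a node with only inhibitors is their negation.
    """
    lines = []
    for nid in sorted(rules):
        r = rules[nid]
        acts = " OR ".join(sorted(r.activators))
        inhs = " OR ".join(sorted(r.inhibitors))
        if not acts and not inhs:
            expr = nid
        elif acts and inhs:
            expr = f"({acts}) AND NOT ({inhs})"
        elif acts:
            expr = f"({acts})"
        else:
            expr = f"NOT ({inhs})"
        lines.append(f"{nid}' = {expr}")
    return "\n".join(lines) + "\n"


_RULE_RE = re.compile(
    r"^(?P<node>\S+)'\s*=\s*(?:\((?P<acts>[^)]*)\)|(?P<hold>\S+))?"
    r"(?:\s*AND\s*)?(?:NOT\s*\((?P<inhs>[^)]*)\))?\s*$")


def parse_boolean_script(text: str) -> dict[str, BooleanRule]:
    """Inverse of :func:`emit_boolean_script`."""
    rules: dict[str, BooleanRule] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ParseError(f"cannot parse rule on line {lineno}: {line!r}")
        node = m.group("node")
        acts = m.group("acts")
        inhs = m.group("inhs")
        hold = m.group("hold")
        rule = BooleanRule(node)
        if acts:
            rule.activators = {s.strip() for s in acts.split("OR") if s.strip()}
        if inhs:
            rule.inhibitors = {s.strip() for s in inhs.split("OR") if s.strip()}
        if hold is not None and hold != node and not acts and not inhs:
            raise ParseError(f"line {lineno}: hold rule must reference the node itself")
        rules[node] = rule
    return rules
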