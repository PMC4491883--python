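"""Deterministic synthetic data and diagrams.

The central fixture emulates a mass-cytometry time course of LPS-stimulated
human PBMCs: fourteen phospho-channels measured in fourteen PBMC cell types
at eight timepoints (0, 1, 5, 15, 30, 60, 120 and 240 min), one stimulated
condition against an unstimulated control. The synthetic dynamics encode the
qualitative biology of that system:

* monocytes respond fast — p38, ERK and NF-kB peak within 15-30 min of LPS,
  followed by a slower S6 rise at 2 h;
* T cells and NK cells respond late — STAT3, STAT5 and ITK rise after 2 h
  (secondary to monocyte IL-6 secretion);
* B cells show a late STAT1 response at 4 h.

Values are generated from piecewise-linear target curves in arcsinh space,
mapped back to raw intensity through sinh and multiplied by seeded log-normal
noise (sigma configurable; sigma=0 gives the noiseless targets exactly, which
the curve construction guarantees to satisfy the orderings above). The
fixture emulates aggregate per-cell-type medians, not per-event single-cell
distributions; a small per-event variant exists for exercising event
aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DIMS, DimensionIndex, MeasurementTable
from .diagram import ACTIVATE, INHIBIT, Diagram, add_compartment, add_edge, add_node, create_diagram
from .linking import LinkMap, link_channel, link_perturbation
from .paint import ControlSpec, EquationSpec, PaintConfig

TIMEPOINTS = [0.0, 1.0, 5.0, 15.0, 30.0, 60.0, 120.0, 240.0]

#: The fourteen observed signaling molecules (phospho-channels).
OBSERVED_NODES = [
    "p38", "ERK", "NFkB", "S6", "STAT1", "STAT3", "STAT5", "ITK",
    "CREB", "SHP2", "ZAP70", "SLP76", "PLCg2", "LAT",
]

#: The fourteen PBMC cell types.
CELL_TYPES = [
    "CD14- monocytes", "CD14+ monocytes", "dendritic cells",
    "IgM+ B cells", "IgM- B cells", "NK cells",
    "CD8+ T cells", "CD4+ T cells",
    "CD14- HLADR- cells", "CD14- HLADRhigh cells",
    "CD14+ HLADR- cells", "CD14+ HLADRhigh cells",
    "CD14- surface- cells", "CD14+ surface- cells",
]

MONOCYTES = ("CD14- monocytes", "CD14+ monocytes")
T_NK = ("CD8+ T cells", "CD4+ T cells", "NK cells")
B_CELLS = ("IgM+ B cells", "IgM- B cells")

CONDITIONS = ["unstimulated", "LPS"]

ARCSINH_COFACTOR = 5.0
_BASE = 0.2  # resting activity in arcsinh units

# piecewise-linear targets in arcsinh space: (time, level) knots
_EARLY_PEAK = [(0, _BASE), (1, 0.4), (5, 1.2), (15, 2.2), (30, 2.4),
               (60, 1.4), (120, 0.8), (240, 0.5)]
_S6_LATE = [(0, _BASE), (60, 0.3), (120, 1.6), (240, 2.2)]
_TNK_LATE = [(0, _BASE), (60, 0.3), (120, 0.9), (240, 2.0)]
_B_VERY_LATE = [(0, _BASE), (120, 0.4), (240, 1.8)]


def _interp(knots: list[tuple[float, float]], t: float) -> float:
    ts = [k[0] for k in knots]
    vs = [k[1] for k in knots]
    return float(np.interp(t, ts, vs))


def target_level(cell_type: str, channel_node: str, condition: str, t: float) -> float:
    """Noiseless target activity in arcsinh units for one fixture cell."""
    if condition != "LPS":
        return _BASE
    if cell_type in MONOCYTES and channel_node in ("p38", "ERK", "NFkB"):
        return _interp(_EARLY_PEAK, t)
    if cell_type in MONOCYTES and channel_node == "S6":
        return _interp(_S6_LATE, t)
    if cell_type in T_NK and channel_node in ("STAT3", "STAT5", "ITK"):
        return _interp(_TNK_LATE, t)
    if cell_type in B_CELLS and channel_node == "STAT1":
        return _interp(_B_VERY_LATE, t)
    return _BASE


def channel_name(node_label: str) -> str:
    return f"p-{node_label}"


@dataclass
class CaseStudy:
    diagram: Diagram
    index: DimensionIndex
    table: MeasurementTable
    linkmap: LinkMap
    config: PaintConfig


def _case_study_diagram() -> Diagram:
    d = create_diagram("pbmc-lps", (1200.0, 800.0))
    add_compartment(d, "extracellular", kind="extracellular",
                    bounds=(0, 0, 1200, 120), id="extracellular")
    add_compartment(d, "membrane", kind="membrane",
                    bounds=(0, 120, 1200, 50), id="membrane")
    add_compartment(d, "cytoplasm", kind="cytoplasm",
                    bounds=(0, 170, 1200, 450), id="cytoplasm")
    add_compartment(d, "nucleus", kind="nucleus",
                    bounds=(0, 620, 1200, 180), id="nucleus")

    add_node(d, "LPS", "extracellular", "circle", position=(200, 60), id="LPS")
    add_node(d, "IL6", "extracellular", "circle", position=(700, 60), id="IL6")
    add_node(d, "TLR4", "membrane", "double-circle", position=(200, 145), id="TLR4")
    add_node(d, "IL6R", "membrane", "double-circle", position=(700, 145), id="IL6R")
    add_node(d, "BCR", "membrane", "double-circle", position=(1000, 145), id="BCR")
    add_node(d, "MYD88", "cytoplasm", "protein", position=(200, 220), id="MYD88")

    xs = np.linspace(120, 1080, len(OBSERVED_NODES))
    for label, x in zip(OBSERVED_NODES, xs):
        y = 320.0 if label not in ("NFkB", "CREB", "STAT1") else 440.0
        add_node(d, label, "cytoplasm", "ellipse", position=(float(x), y), id=label)

    for a, b, s in [
        ("LPS", "TLR4", ACTIVATE), ("TLR4", "MYD88", ACTIVATE),
        ("MYD88", "p38", ACTIVATE), ("MYD88", "ERK", ACTIVATE),
        ("MYD88", "NFkB", ACTIVATE), ("ERK", "S6", ACTIVATE),
        ("p38", "CREB", ACTIVATE), ("IL6", "IL6R", ACTIVATE),
        ("IL6R", "STAT3", ACTIVATE), ("IL6R", "STAT5", ACTIVATE),
        ("IL6R", "STAT1", ACTIVATE), ("IL6R", "ITK", ACTIVATE),
        ("BCR", "ZAP70", ACTIVATE), ("ZAP70", "SLP76", ACTIVATE),
        ("SLP76", "PLCg2", ACTIVATE), ("ZAP70", "LAT", ACTIVATE),
        ("SHP2", "STAT1", INHIBIT), ("IL6R", "SHP2", ACTIVATE),
    ]:
        add_edge(d, a, b, s)
    return d


def generate_case_study(seed: int = 0, sigma: float = 0.15) -> CaseStudy:
    """The packaged PBMC/LPS fixture; ``sigma=0`` disables the noise."""
    diagram = _case_study_diagram()
    channels = [channel_name(lbl) for lbl in OBSERVED_NODES]
    index = DimensionIndex(
        individuals=["donor1"], cell_types=list(CELL_TYPES),
        conditions=list(CONDITIONS), dosages=["standard"],
        channels=channels, timepoints=list(TIMEPOINTS))
    index.check()

    rng = np.random.default_rng(seed)
    rows = []
    for ct in CELL_TYPES:
        for cond in CONDITIONS:
            for node_label in OBSERVED_NODES:
                for t in TIMEPOINTS:
                    level = target_level(ct, node_label, cond, t)
                    raw = ARCSINH_COFACTOR * math.sinh(level)
                    if sigma > 0:
                        raw *= math.exp(sigma * rng.standard_normal())
                    rows.append(("donor1", ct, cond, "standard",
                                 channel_name(node_label), t, raw))
    table = MeasurementTable(pd.DataFrame(rows, columns=[*DIMS, "value"]))

    linkmap = LinkMap()
    for label in OBSERVED_NODES:
        link_channel(linkmap, diagram, index, label, channel_name(label))
    link_perturbation(linkmap, diagram, index, "TLR4", "LPS", "enhansive")

    config = PaintConfig(
        statistic="mean",
        equation=EquationSpec(kind="arcsinh", cofactor=ARCSINH_COFACTOR),
        control=ControlSpec(kind="first_column"),
        colormap="blue-yellow",
        steps_per_interval=4,
        heatmap={"dim1": "cell_type", "dim2": "condition", "cluster": False},
    )
    return CaseStudy(diagram=diagram, index=index, table=table,
                     linkmap=linkmap, config=config)


def generate_case_study_events(seed: int = 0, events_per_group: int = 20,
                               sigma: float = 0.25,
                               cell_types: list[str] | None = None,
                               channels: list[str] | None = None) -> pd.DataFrame:
    """Small per-event variant (rows of individual events) for exercising
    event aggregation; restricted to a subset by default to stay desk-sized."""
    cell_types = cell_types or list(MONOCYTES)
    channels = channels or [channel_name("p38")]
    rng = np.random.default_rng(seed)
    rows = []
    for ct in cell_types:
        for cond in CONDITIONS:
            for ch in channels:
                node = ch.removeprefix("p-")
                for t in TIMEPOINTS:
                    level = target_level(ct, node, cond, t)
                    center = ARCSINH_COFACTOR * math.sinh(level)
                    vals = center * np.exp(sigma * rng.standard_normal(events_per_group))
                    for v in vals:
                        rows.append(("donor1", ct, cond, "standard", ch, t, float(v)))
    return pd.DataFrame(rows, columns=[*DIMS, "event_value"])


def generate_random(seed: int, sizes: tuple[int, int, int, int, int, int]
                    ) -> tuple[DimensionIndex, MeasurementTable]:
    """Fully crossed table of i.i.d. log-normal values.

    ``sizes`` orders as (individuals, cell_types, conditions, dosages,
    channels, timepoints); all must be >= 1.
    """
    if any(s < 1 for s in sizes):
        raise ValueError("all dimension sizes must be >= 1")
    ni, nct, nc, nd, nch, nt = sizes
    index = DimensionIndex(
        individuals=[f"ind{i}" for i in range(ni)],
        cell_types=[f"ct{i}" for i in range(nct)],
        conditions=[f"cond{i}" for i in range(nc)],
        dosages=[f"dose{i}" for i in range(nd)],
        channels=[f"ch{i}" for i in range(nch)],
        timepoints=[float(10 * i) for i in range(nt)])
    rng = np.random.default_rng(seed)
    rows = []
    for ind in index.individuals:
        for ct in index.cell_types:
            for cond in index.conditions:
                for dose in index.dosages:
                    for ch in index.channels:
                        for t in index.timepoints:
                            rows.append((ind, ct, cond, dose, ch, t,
                                         float(rng.lognormal(1.0, 0.5))))
    return index, MeasurementTable(pd.DataFrame(rows, columns=[*DIMS, "value"]))
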