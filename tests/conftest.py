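import pandas as pd
import pytest

import pathpaint as pp
from pathpaint.data import DIMS, MeasurementTable


@pytest.fixture()
def toy_diagram():
    """Two compartments, three nodes, two signed edges."""
    d = pp.create_diagram("toy", (400, 300))
    pp.add_compartment(d, "membrane", kind="membrane", bounds=(0, 0, 400, 60),
                       id="mem")
    pp.add_compartment(d, "cytoplasm", kind="cytoplasm", bounds=(0, 60, 400, 240),
                       id="cyt")
    pp.add_node(d, "TLR4", "mem", "double-circle", position=(200, 30), id="TLR4")
    pp.add_node(d, "p38", "cyt", "ellipse", position=(120, 150), id="p38")
    pp.add_node(d, "S6", "cyt", "ellipse", position=(280, 150), id="S6")
    pp.add_edge(d, "TLR4", "p38", "activate")
    pp.add_edge(d, "p38", "S6", "activate")
    return d


def make_table(rows):
    """rows: list of (individual, cell_type, condition, dosage, channel, t, value)."""
    return MeasurementTable(pd.DataFrame(rows, columns=[*DIMS, "value"]))


@pytest.fixture()
def toy_table():
    """2 conditions x 2 timepoints of one channel: the printed 2x2 table
    [[1, 2], [3, 4]] with rows condA, condB and columns t=0, t=5."""
    rows = [
        ("i1", "ct1", "condA", "d1", "ch1", 0.0, 1.0),
        ("i1", "ct1", "condA", "d1", "ch1", 5.0, 2.0),
        ("i1", "ct1", "condB", "d1", "ch1", 0.0, 3.0),
        ("i1", "ct1", "condB", "d1", "ch1", 5.0, 4.0),
    ]
    return make_table(rows)


@pytest.fixture()
def toy_index():
    return pp.DimensionIndex(
        individuals=["i1"], cell_types=["ct1"], conditions=["condA", "condB"],
        dosages=["d1"], channels=["ch1"], timepoints=[0.0, 5.0])


@pytest.fixture(scope="session")
def case_study():
    """Noiseless packaged PBMC/LPS fixture (shared, treat as read-only)."""
    return pp.generate_case_study(seed=1, sigma=0.0)


@pytest.fixture(scope="session")
def case_study_frames(case_study):
    cs = case_study
    return pp.node_values(cs.table, cs.index, cs.linkmap, cs.diagram,
                          equation=cs.config.equation, control=cs.config.control,
                          colormap=cs.config.colormap)


@pytest.fixture()
def ring_diagram():
    """Three-node negative feedback ring A -> B -> C -| A."""
    d = pp.create_diagram("ring", (300, 300))
    pp.add_compartment(d, "cyt", kind="cytoplasm", id="cyt")
    for n in "ABC":
        pp.add_node(d, n, "cyt", id=n)
    pp.add_edge(d, "A", "B", "activate")
    pp.add_edge(d, "B", "C", "activate")
    pp.add_edge(d, "C", "A", "inhibit")
    return d
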