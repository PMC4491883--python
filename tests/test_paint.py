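"""Controls, equations, color mapping and interpolation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathpaint as pp
from pathpaint.errors import ContractError
from pathpaint.paint import ColorMap


class TestControlValue:
    """On the printed 2x2 table [[1, 2], [3, 4]] (condA/condB x t=0/5)."""

    def control(self, table, index, kind, cond, t):
        return pp.control_value(table, index, "ch1", cond, t,
                                pp.ControlSpec(kind))

    def test_first_column_is_t0_of_the_condition(self, toy_table, toy_index):
        assert self.control(toy_table, toy_index, "first_column", "condB", 5.0) == 3.0

    def test_first_row_is_first_condition_at_t(self, toy_table, toy_index):
        assert self.control(toy_table, toy_index, "first_row", "condB", 0.0) == 1.0

    def test_table_extrema_constant_over_cells(self, toy_table, toy_index):
        for cond in ("condA", "condB"):
            for t in (0.0, 5.0):
                assert self.control(toy_table, toy_index, "table_max", cond, t) == 4.0
                assert self.control(toy_table, toy_index, "table_min", cond, t) == 1.0

    def test_missing_control_cell_signals_no_data(self, toy_table, toy_index):
        trimmed = pp.MeasurementTable(
            toy_table.df[~((toy_table.df.condition == "condA")
                           & (toy_table.df.timepoint == 0.0))].copy())
        assert self.control(trimmed, toy_index, "first_row", "condB", 0.0) is None


class TestApplyEquation:
    def test_fold(self):
        assert pp.apply_equation(10, 2, pp.EquationSpec("fold")) == 5.0

    def test_arcsinh_closed_form(self):
        # asinh(1) - asinh(0) = ln(1 + sqrt(2))
        got = pp.apply_equation(5, 0, pp.EquationSpec("arcsinh", cofactor=5))
        assert got == pytest.approx(math.log(1 + math.sqrt(2)), abs=1e-12)

    def test_identity_cases(self):
        assert pp.apply_equation(1, 1, pp.EquationSpec("log")) == 0.0
        assert pp.apply_equation(7, 7, pp.EquationSpec("difference")) == 0.0

    def test_raw_ignores_control(self):
        assert pp.apply_equation(3.5, None, pp.EquationSpec("raw")) == 3.5

    @pytest.mark.parametrize("kind,x,c", [
        ("fold", 1.0, 0.0), ("log", -1.0, 1.0), ("log", 1.0, 0.0)])
    def test_domain_violations_become_no_data(self, kind, x, c):
        assert pp.apply_equation(x, c, pp.EquationSpec(kind)) is None

    @settings(deadline=None, max_examples=50)
    @given(x=st.floats(0.1, 1e6), c=st.floats(0.1, 1e6))
    def test_algebraic_identities(self, x, c):
        fold = pp.apply_equation(x, c, pp.EquationSpec("fold"))
        diff = pp.apply_equation(x, c, pp.EquationSpec("difference"))
        assert fold * c == pytest.approx(x, rel=1e-9)
        assert diff + c == pytest.approx(x, rel=1e-9)
        assert pp.apply_equation(x, x, pp.EquationSpec("arcsinh")) == 0.0


class TestMapColor:
    BY = ColorMap(domain=(0.0, 10.0))

    def test_endpoints_hit_first_and_last_stops(self):
        assert pp.map_color(0.0, self.BY) == (0, 0, 255)
        assert pp.map_color(10.0, self.BY) == (255, 255, 0)

    def test_midpoint_is_channelwise_blend(self):
        # independent oracle: per-channel linear interpolation at 50%
        expected = tuple(round((a + b) / 2) for a, b in zip((0, 0, 255),
                                                            (255, 255, 0)))
        assert pp.map_color(5.0, self.BY) == expected

    def test_out_of_domain_clamps(self):
        assert pp.map_color(-99.0, self.BY) == (0, 0, 255)
        assert pp.map_color(99.0, self.BY) == (255, 255, 0)

    def test_no_data_is_grey(self):
        assert pp.map_color(None, self.BY) == (128, 128, 128)
        assert pp.map_color(float("nan"), self.BY) == (128, 128, 128)

    def test_monotone_yellow_fraction(self):
        reds = [pp.map_color(v, self.BY)[0] for v in np.linspace(0, 10, 21)]
        assert reds == sorted(reds)

    def test_three_stop_map_passes_through_middle_stop(self):
        cmap = pp.make_colormap("blue-white-red", (-1.0, 1.0))
        assert pp.map_color(0.0, cmap) == (255, 255, 255)


def _series(times, values, domain=(0.0, 10.0)):
    fs = pp.FrameSeries(times=list(times), values={"n": list(values)},
                        cmap=ColorMap(domain=domain))
    fs.resolve_colors()
    return fs


class TestInterpolate:
    def test_linear_midpoint(self):
        fs = pp.interpolate(_series([0, 10], [0.0, 10.0]), steps_per_interval=2)
        assert fs.times == [0, 5.0, 10]
        assert fs.values["n"] == [0.0, 5.0, 10.0]

    def test_keyframes_preserved_exactly(self):
        base = _series([0, 1, 5], [0.25, 0.5, 0.125])
        fs = pp.interpolate(base, steps_per_interval=3)
        for t, v in zip(base.times, base.values["n"]):
            assert fs.values["n"][fs.times.index(t)] == v

    def test_frame_count_formula(self):
        fs = pp.interpolate(_series([0, 1, 2], [0, 1, 2]), steps_per_interval=4)
        assert fs.n_frames() == 2 * 4 + 1

    def test_frames_per_minute_weights_long_intervals(self):
        fs = pp.interpolate(_series([0, 1, 5], [0, 1, 2]), frames_per_minute=1)
        # 1 frame in the 1-min interval, 4 in the 4-min interval, + final
        assert fs.n_frames() == 1 + 4 + 1

    def test_single_keyframe_unchanged(self):
        base = _series([0], [1.0])
        assert pp.interpolate(base, steps_per_interval=4) is base

    def test_no_data_interval_stays_no_data(self):
        fs = pp.interpolate(_series([0, 10, 20], [1.0, None, 2.0]),
                            steps_per_interval=2)
        assert fs.values["n"] == [1.0, None, None, None, 2.0]
        grey = (128, 128, 128)
        assert fs.colors["n"][1] == grey

    def test_both_sampling_modes_together_rejected(self):
        with pytest.raises(ContractError):
            pp.interpolate(_series([0, 1], [0, 1]), steps_per_interval=2,
                           frames_per_minute=1)

    @settings(deadline=None, max_examples=30)
    @given(v0=st.floats(-100, 100), v1=st.floats(-100, 100),
           steps=st.integers(2, 8))
    def test_bounded_and_monotone_on_segments(self, v0, v1, steps):
        fs = pp.interpolate(_series([0, 10], [v0, v1], domain=(-100, 100)),
                            steps_per_interval=steps)
        vals = fs.values["n"]
        lo, hi = min(v0, v1), max(v0, v1)
        assert all(lo - 1e-9 <= v <= hi + 1e-9 for v in vals)
        diffs = np.diff(vals)
        assert (diffs >= -1e-9).all() or (diffs <= 1e-9).all()


class TestNodeValues:
    def test_raw_single_channel_series(self, toy_diagram):
        from conftest import make_table
        index = pp.DimensionIndex(individuals=["i1"], cell_types=["ct1"],
                                  conditions=["c"], dosages=["d"],
                                  channels=["ch1"], timepoints=[0.0, 240.0])
        table = make_table([("i1", "ct1", "c", "d", "ch1", 0.0, 0.0),
                            ("i1", "ct1", "c", "d", "ch1", 240.0, 10.0)])
        lm = pp.LinkMap()
        pp.link_channel(lm, toy_diagram, index, "p38", "ch1")
        fs = pp.node_values(table, index, lm, toy_diagram,
                            equation=pp.EquationSpec("raw"))
        assert fs.values["p38"] == [0.0, 10.0]
        assert fs.values["S6"] == [None, None]  # unobserved -> no data

    def test_two_cell_types_average(self, toy_diagram):
        from conftest import make_table
        index = pp.DimensionIndex(individuals=["i1"], cell_types=["a", "b"],
                                  conditions=["c"], dosages=["d"],
                                  channels=["ch1"], timepoints=[0.0])
        table = make_table([("i1", "a", "c", "d", "ch1", 0.0, 0.0),
                            ("i1", "b", "c", "d", "ch1", 0.0, 10.0)])
        lm = pp.LinkMap()
        pp.link_channel(lm, toy_diagram, index, "p38", "ch1")
        fs = pp.node_values(table, index, lm, toy_diagram,
                            equation=pp.EquationSpec("raw"))
        assert fs.values["p38"] == [5.0]

    def test_case_study_has_8_keyframes(self, case_study_frames):
        assert case_study_frames.n_frames() == 8
        assert case_study_frames.times == [0, 1, 5, 15, 30, 60, 120, 240]

    def test_determinism_bit_identical(self, case_study):
        cs = case_study
        kw = dict(equation=cs.config.equation, control=cs.config.control)
        a = pp.node_values(cs.table, cs.index, cs.linkmap, cs.diagram, **kw)
        b = pp.node_values(cs.table, cs.index, cs.linkmap, cs.diagram, **kw)
        assert a.times == b.times and a.values == b.values and a.colors == b.colors

    def test_symmetric_domain_for_signed_equations(self, case_study_frames):
        lo, hi = case_study_frames.cmap.domain
        assert lo == -hi
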