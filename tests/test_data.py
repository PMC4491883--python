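"""Measurement ingestion, event aggregation and dimension collapsing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathpaint as pp
from pathpaint.data import DIMS, MeasurementTable
from pathpaint.errors import ContractError, DataError, ParseError, SchemaError

from conftest import make_table


def _toy_csv(tmp_path, text, name="toy.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


HEADER = "individual,cell_type,condition,dosage,channel,timepoint,value\n"


class TestReadMeasurements:
    def test_counts_and_index(self, tmp_path):
        text = HEADER + "".join(
            f"i1,ct1,c1,d1,{ch},{t},1.5\n"
            for ch, t in itertools.product(["chA", "chB"], [0, 60]))
        index, table = pp.read_measurements(_toy_csv(tmp_path, text))
        assert len(table) == 4
        assert index.channels == ["chA", "chB"]
        assert index.timepoints == [0.0, 60.0]

    def test_duplicate_key_rejected(self, tmp_path):
        text = HEADER + "i1,ct1,c1,d1,chA,0,1\ni1,ct1,c1,d1,chA,0,2\n"
        with pytest.raises(DataError, match="chA"):
            pp.read_measurements(_toy_csv(tmp_path, text))

    def test_missing_column_named(self, tmp_path):
        text = "individual,cell_type,condition,dosage,channel,timepoint\ni,c,c,d,ch,0\n"
        with pytest.raises(SchemaError, match="value"):
            pp.read_measurements(_toy_csv(tmp_path, text))

    def test_non_numeric_value_locates_row(self, tmp_path):
        text = HEADER + "i1,ct1,c1,d1,chA,0,1\ni1,ct1,c1,d1,chA,5,oops\n"
        with pytest.raises(ParseError, match="row 1"):
            pp.read_measurements(_toy_csv(tmp_path, text))

    def test_csv_and_json_encodings_agree(self, tmp_path):
        text = HEADER + "i1,ct1,c1,d1,chA,0,1.25\ni1,ct1,c1,d1,chA,5,2.5\n"
        _, from_csv = pp.read_measurements(_toy_csv(tmp_path, text))
        jpath = tmp_path / "toy.json"
        pp.write_measurements(from_csv, jpath)
        _, from_json = pp.read_measurements(jpath)
        pd.testing.assert_frame_equal(from_csv.df, from_json.df)


class TestAggregateEvents:
    @pytest.fixture()
    def one_group(self):
        return pd.DataFrame(
            [("i1", "ct", "c", "d", "ch", 0.0, v) for v in (1, 2, 3, 100)],
            columns=[*DIMS, "event_value"])

    @pytest.mark.parametrize("stat,expected", [
        ("median", 2.5), ("max", 100.0), ("mean", 26.5), ("min", 1.0)])
    def test_statistics_on_one_group(self, one_group, stat, expected):
        table = pp.aggregate_events(one_group, stat)
        assert len(table) == 1
        assert table.df["value"].iloc[0] == expected

    def test_empty_table_gives_empty_result(self):
        empty = pd.DataFrame(columns=[*DIMS, "event_value"])
        assert len(pp.aggregate_events(empty, "mean")) == 0

    def test_unknown_statistic_rejected(self, one_group):
        with pytest.raises(ContractError):
            pp.aggregate_events(one_group, "mode")


class TestCollapse:
    def test_mean_over_conditions(self):
        table = make_table([
            ("i1", "ct", "condA", "d", "ch", 0.0, 10.0),
            ("i1", "ct", "condB", "d", "ch", 0.0, 20.0)])
        out = pp.collapse(table, ("channel", "timepoint"))
        assert out.df["value"].tolist() == [15.0]

    def test_keep_all_dims_is_identity(self, toy_table):
        out = pp.collapse(toy_table, DIMS)
        pd.testing.assert_frame_equal(out.df, toy_table.df)

    def test_empty_keep_dims_rejected(self, toy_table):
        with pytest.raises(ContractError):
            pp.collapse(toy_table, ())

    def test_collapse_order_independent_on_complete_data(self):
        rng = np.random.default_rng(7)
        rows = [("i1", ct, cond, "d", "ch", t, float(rng.normal()))
                for ct in ("x", "y") for cond in ("a", "b", "c")
                for t in (0.0, 5.0)]
        table = make_table(rows)
        via1 = pp.collapse(pp.collapse(table, ("cell_type", "channel", "timepoint")),
                           ("channel", "timepoint"))
        via2 = pp.collapse(pp.collapse(table, ("condition", "channel", "timepoint")),
                           ("channel", "timepoint"))
        direct = pp.collapse(table, ("channel", "timepoint"))
        np.testing.assert_allclose(via1.df["value"], direct.df["value"])
        np.testing.assert_allclose(via2.df["value"], direct.df["value"])

    def test_missing_cells_single_mean_over_present_leaves(self):
        # brute-force oracle: the documented semantics is one unweighted mean
        rows = [("i1", "x", "a", "d", "ch", 0.0, 1.0),
                ("i1", "x", "b", "d", "ch", 0.0, 2.0),
                ("i1", "y", "a", "d", "ch", 0.0, 6.0)]  # (y, b) missing
        table = make_table(rows)
        out = pp.collapse(table, ("channel", "timepoint"))
        assert out.df["value"].iloc[0] == pytest.approx((1 + 2 + 6) / 3)

    @settings(deadline=None, max_examples=25)
    @given(vals=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=12))
    def test_collapse_matches_numpy_mean_oracle(self, vals):
        rows = [("i1", f"ct{k}", "c", "d", "ch", 0.0, v)
                for k, v in enumerate(vals)]
        out = pp.collapse(make_table(rows), ("channel", "timepoint"))
        assert out.df["value"].iloc[0] == pytest.approx(np.mean(vals))


class TestEventToCollapseConsistency:
    def test_pooled_mean_on_balanced_design(self):
        # mean aggregation then collapse equals the pooled mean of all events
        rng = np.random.default_rng(3)
        rows = []
        for ct in ("x", "y"):
            for t in (0.0, 5.0):
                for _ in range(5):
                    rows.append(("i1", ct, "c", "d", "ch", t, float(rng.normal())))
        events = pd.DataFrame(rows, columns=[*DIMS, "event_value"])
        table = pp.aggregate_events(events, "mean")
        collapsed = pp.collapse(table, ("channel", "timepoint"))
        for t in (0.0, 5.0):
            pooled = events[events["timepoint"] == t]["event_value"].mean()
            got = collapsed.df.loc[collapsed.df["timepoint"] == t, "value"].iloc[0]
            assert got == pytest.approx(pooled)


class TestMeasurementTableInvariants:
    def test_duplicate_six_tuple_rejected(self):
        rows = [("i", "c", "c", "d", "ch", 0.0, 1.0)] * 2
        with pytest.raises(DataError):
            make_table(rows)

    def test_non_finite_value_rejected(self):
        with pytest.raises(DataError):
            make_table([("i", "c", "c", "d", "ch", 0.0, float("nan"))])

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(DataError):
            pp.DimensionIndex(individuals=["i"], cell_types=["c"],
                              conditions=["c"], dosages=["d"], channels=["ch"],
                              timepoints=[5.0, 5.0]).check()
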