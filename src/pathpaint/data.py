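"""Measurement tables annotated on the six experimental dimensions.

Cytometry time courses are long-format tables in which every scalar is
annotated with the individual, cell type, condition, dosage, channel and
timepoint it belongs to. Two granularities exist:

* an *event table* holds one row per cell event per channel and is reduced to
  one value per annotation 6-tuple with :func:`aggregate_events`
  (mean/median/min/max);
* a *measurement table* holds at most one scalar per 6-tuple and is the input
  to painting and heatmaps.

:func:`collapse` averages a measurement table down to a subset of dimensions
with a single unweighted mean over all present leaf cells (not a
mean-of-means); missing cells are simply absent and skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, DataError, ParseError, SchemaError

#: The six annotation dimensions, in canonical column order.
DIMS = ("individual", "cell_type", "condition", "dosage", "channel", "timepoint")

STATISTICS = ("mean", "median", "min", "max")


@dataclass
class DimensionIndex:
    """Ordered category labels per dimension; timepoints in minutes, sorted."""

    individuals: list[str] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    dosages: list[str] = field(default_factory=list)
    channels: list[str] = field(default_factory=list)
    timepoints: list[float] = field(default_factory=list)

    _FIELD_BY_DIM = {
        "individual": "individuals",
        "cell_type": "cell_types",
        "condition": "conditions",
        "dosage": "dosages",
        "channel": "channels",
        "timepoint": "timepoints",
    }

    def labels(self, dim: str) -> list:
        return getattr(self, self._FIELD_BY_DIM[dim])

    def check(self) -> None:
        for dim, attr in self._FIELD_BY_DIM.items():
            vals = getattr(self, attr)
            if len(set(vals)) != len(vals):
                raise DataError(f"duplicate labels in dimension {dim!r}")
        tps = self.timepoints
        if any(t < 0 for t in tps):
            raise DataError("timepoints must be non-negative minutes")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise DataError("timepoints must be strictly increasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DimensionIndex":
        """Build an index from observed labels (first-appearance order for
        categories, sorted for timepoints)."""
        idx = cls(
            individuals=list(dict.fromkeys(df["individual"].astype(str))),
            cell_types=list(dict.fromkeys(df["cell_type"].astype(str))),
            conditions=list(dict.fromkeys(df["condition"].astype(str))),
            dosages=list(dict.fromkeys(df["dosage"].astype(str))),
            channels=list(dict.fromkeys(df["channel"].astype(str))),
            timepoints=sorted(set(float(t) for t in df["timepoint"])),
        )
        idx.check()
        return idx


@dataclass
class MeasurementTable:
    """At most one finite scalar per key tuple over ``dims``.

    ``df`` holds one column per dimension in ``dims`` plus a ``value`` column;
    ``dims`` is the full six-dimension set for freshly read tables and a
    subset after :func:`collapse`.
    """

    df: pd.DataFrame
    dims: tuple[str, ...] = DIMS

    def __post_init__(self) -> None:
        missing = [c for c in (*self.dims, "value") if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.df = self.df[[*self.dims, "value"]].reset_index(drop=True)
        if not np.isfinite(self.df["value"].to_numpy(dtype=float)).all():
            raise DataError("non-finite measurement values")
        dup = self.df.duplicated(subset=list(self.dims))
        if dup.any():
            offender = tuple(self.df.loc[dup.idxmax(), list(self.dims)])
            raise DataError(f"duplicate key {offender}")

    def __len__(self) -> int:
        return len(self.df)

    def get(self, **key) -> float | None:
        """Value at one key tuple, or None when the cell is missing."""
        mask = pd.Series(True, index=self.df.index)
        for k, v in key.items():
            mask &= self.df[k] == v
        sub = self.df.loc[mask, "value"]
        if len(sub) == 0:
            return None
        return float(sub.iloc[0])


def _require_columns(df: pd.DataFrame) -> None:
    for col in (*DIMS, "value"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")


def _coerce_values(df: pd.DataFrame) -> pd.DataFrame:
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna() | df["value"].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"non-numeric value in row {row}: {df['value'].iloc[row]!r}")
    df = df.copy()
    df["value"] = vals.astype(float)
    df["timepoint"] = pd.to_numeric(df["timepoint"], errors="raise").astype(float)
    for col in ("individual", "cell_type", "condition", "dosage", "channel"):
        df[col] = df[col].astype(str)
    return df


def read_measurements(path: str | Path, format: str | None = None
                      ) -> tuple[DimensionIndex, MeasurementTable]:
    """Read a long-format measurement file (CSV or JSON).

    CSV: UTF-8, comma separated, header row with the exact column names
    ``individual,cell_type,condition,dosage,channel,timepoint,value``.
    JSON: ``{"measurements": [{<same keys>}, ...]}``. Timepoints are minutes.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype={"value": object})
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        rows = doc["measurements"] if isinstance(doc, dict) else doc
        df = pd.DataFrame(rows)
    else:
        raise ContractError(f"format must be csv or json, got {format!r}")
    _require_columns(df)
    df = _coerce_values(df)
    index = DimensionIndex.from_frame(df)
    return index, MeasurementTable(df)


def write_measurements(table: MeasurementTable, path: str | Path,
                       format: str | None = None) -> None:
    """Symmetric writer for :func:`read_measurements`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        table.df.to_csv(path, index=False)
    elif format == "json":
        rows = table.df.to_dict(orient="records")
        path.write_text(json.dumps({"measurements": rows}, indent=1), encoding="utf-8")
    else:
        raise ContractError(f"format must be csv or json, got {format!r}")


def aggregate_events(events: pd.DataFrame, statistic: str = "mean") -> MeasurementTable:
    """Reduce per-event rows to one scalar per annotation 6-tuple.

    ``events`` needs the six dimension columns plus ``event_value``. The
    median of an even-sized group is the midpoint of the central pair.
    """
    if statistic not in STATISTICS:
        raise ContractError(f"statistic must be one of {STATISTICS}, got {statistic!r}")
    for col in (*DIMS, "event_value"):
        if col not in events.columns:
            raise SchemaError(f"missing required column {col!r}")
    if len(events) == 0:
        empty = pd.DataFrame(columns=[*DIMS, "value"])
        return MeasurementTable(empty)
    grouped = (
        events.groupby(list(DIMS), sort=False, observed=True)["event_value"]
        .agg(statistic)
        .reset_index()
        .rename(columns={"event_value": "value"})
    )
    return MeasurementTable(grouped)


def collapse(table: MeasurementTable, keep_dims: tuple[str, ...] | list[str]
             ) -> MeasurementTable:
    """Average over all dimensions not in ``keep_dims``.

    Semantics: a single unweighted arithmetic mean over all present leaf
    cells in each kept-dimension group; missing cells do not contribute.
    Keeping every current dimension is the identity.
    """
    keep = tuple(keep_dims)
    if len(keep) == 0:
        raise ContractError("keep_dims must be non-empty")
    unknown = [d for d in keep if d not in table.dims]
    if unknown:
        raise ContractError(f"not dimensions of this table: {unknown}")
    if set(keep) == set(table.dims):
        return MeasurementTable(table.df.copy(), dims=table.dims)
    keep_ordered = tuple(d for d in table.dims if d in keep)
    out = (
        table.df.groupby(list(keep_ordered), sort=False, observed=True)["value"]
        .mean()
        .reset_index()
    )
    return MeasurementTable(out, dims=keep_ordered)
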