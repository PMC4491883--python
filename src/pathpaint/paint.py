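"""The painting pipeline: control selection, equation transform, per-node
values per timepoint, colormap resolution and timepoint interpolation.

For each observed node the pipeline (1) collapses the node's channel over
individual, cell type, condition and dosage by unweighted mean, (2) picks a
control value for each timepoint from the channel's condition x timepoint
table, (3) applies the selected equation, and (4) resolves a color through the
colormap. Domain violations (log of a non-positive ratio, fold over a zero
control, a missing control cell) become a *no-data* signal painted grey —
never an exception mid-animation.

Equations (x = measured value, c = control, b = arcsinh cofactor, default 5):

====================  =============================
raw                   x
fold                  x / c
difference            x - c
log                   log10(x / c)
arcsinh               asinh(x / b) - asinh(c / b)
====================  =============================

The arcsinh form is the cytometry-standard scaling: approximately linear near
zero and logarithmic for large intensities, with the cofactor setting the
crossover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DimensionIndex, MeasurementTable, collapse
from .diagram import Diagram
from .errors import ContractError, ValidationError
from .linking import LinkMap, observed_partition

CONTROL_KINDS = ("first_row", "first_column", "table_min", "table_max")
EQUATION_KINDS = ("raw", "log", "fold", "arcsinh", "difference")

#: Fill used for nodes with no data at a frame.
NO_DATA_COLOR = (128, 128, 128)


@dataclass
class ControlSpec:
    """Which cell of the per-channel condition x timepoint table is the
    reference: rows are conditions (index order), columns timepoints
    (ascending), so ``first_column`` is the classic fold-over-t0 control."""

    kind: str = "first_column"

    def __post_init__(self) -> None:
        if self.kind not in CONTROL_KINDS:
            raise ContractError(f"control kind must be one of {CONTROL_KINDS}")


@dataclass
class EquationSpec:
    kind: str = "raw"
    cofactor: float = 5.0  # arcsinh only

    def __post_init__(self) -> None:
        if self.kind not in EQUATION_KINDS:
            raise ContractError(f"equation kind must be one of {EQUATION_KINDS}")
        if self.cofactor <= 0:
            raise ContractError("cofactor must be positive")


@dataclass
class ColorMap:
    """Linear-interpolated color stops over a finite domain."""

    name: str = "blue-yellow"
    stops: tuple[tuple[int, int, int], ...] = ((0, 0, 255), (255, 255, 0))
    domain: tuple[float, float] = (0.0, 1.0)
    no_data: tuple[int, int, int] = NO_DATA_COLOR

    def __post_init__(self) -> None:
        if len(self.stops) < 2:
            raise ValidationError("colormap needs at least 2 stops")
        lo, hi = self.domain
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValidationError(f"bad colormap domain {self.domain}")


#: Named colormaps selectable from paint configs.
COLORMAPS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "blue-yellow": ((0, 0, 255), (255, 255, 0)),
    "blue-white-red": ((0, 0, 255), (255, 255, 255), (255, 0, 0)),
    "green-red": ((0, 160, 0), (255, 0, 0)),
    "greyscale": ((0, 0, 0), (255, 255, 255)),
}


def make_colormap(name: str, domain: tuple[float, float]) -> ColorMap:
    if name not in COLORMAPS:
        raise ContractError(f"unknown colormap {name!r}; have {sorted(COLORMAPS)}")
    return ColorMap(name=name, stops=COLORMAPS[name], domain=domain)


@dataclass
class FrameSeries:
    """Per-node scalar values and resolved colors at each (key)frame time.

    ``values[node_id][k]`` is the transformed value at ``times[k]`` or None
    (no data); unobserved nodes carry all-None series. ``cmap`` is kept so
    interpolation can recompute colors on the same domain.
    """

    times: list[float]
    values: dict[str, list[float | None]]
    colors: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    cmap: ColorMap | None = None

    def n_frames(self) -> int:
        return len(self.times)

    def resolve_colors(self) -> None:
        cmap = self.cmap
        if cmap is None:
            raise ContractError("FrameSeries has no colormap attached")
        self.colors = {
            nid: [map_color(v, cmap) for v in series]
            for nid, series in self.values.items()
        }


# ---------------------------------------------------------------------------
# controls and equations


def channel_pivot(table: MeasurementTable, index: DimensionIndex, channel: str
                  ) -> pd.DataFrame:
    """The channel's condition x timepoint table, individual/cell_type/dosage
    collapsed by mean. Rows follow index.conditions, columns ascending time;
    missing cells are NaN."""
    sub = table.df[table.df["channel"] == channel]
    pivot = sub.pivot_table(index="condition", columns="timepoint", values="value",
                            aggfunc="mean")
    pivot = pivot.reindex(index=[c for c in index.conditions],
                          columns=sorted(index.timepoints))
    return pivot


def control_value(table: MeasurementTable, index: DimensionIndex, channel: str,
                  condition: str | None, timepoint: float, spec: ControlSpec
                  ) -> float | None:
    """Reference value for one cell of the channel's condition x timepoint
    table; None signals a missing control cell (painted as no-data).

    ``condition=None`` addresses the condition-collapsed series (the painting
    path, where conditions were averaged out): ``first_row`` still reads the
    first listed condition at this timepoint, ``first_column`` the collapsed
    mean at the earliest timepoint.
    """
    pivot = channel_pivot(table, index, channel)
    if pivot.size == 0 or pivot.isna().all().all():
        return None
    kind = spec.kind
    if kind == "table_min":
        return float(np.nanmin(pivot.to_numpy()))
    if kind == "table_max":
        return float(np.nanmax(pivot.to_numpy()))
    if kind == "first_row":
        first_cond = pivot.index[0]
        val = pivot.loc[first_cond, timepoint] if timepoint in pivot.columns else np.nan
        return None if pd.isna(val) else float(val)
    # first_column
    t0 = pivot.columns[0]
    if condition is None:
        val = pivot[t0].mean()  # collapsed over conditions
    else:
        if condition not in pivot.index:
            return None
        val = pivot.loc[condition, t0]
    return None if pd.isna(val) else float(val)


def apply_equation(x: float | None, c: float | None, spec: EquationSpec
                   ) -> float | None:
    """Transform one measured value against its control; None propagates."""
    if x is None:
        return None
    kind = spec.kind
    if kind == "raw":
        return float(x)
    if c is None:
        return None
    if kind == "difference":
        return float(x - c)
    if kind == "arcsinh":
        b = spec.cofactor
        return float(math.asinh(x / b) - math.asinh(c / b))
    if kind == "fold":
        if c == 0:
            return None
        return float(x / c)
    # log
    if c == 0 or (x / c) <= 0:
        return None
    return float(math.log10(x / c))


# ---------------------------------------------------------------------------
# node series and colors


def node_values(table: MeasurementTable, index: DimensionIndex, linkmap: LinkMap,
                diagram: Diagram, equation: EquationSpec | None = None,
                control: ControlSpec | None = None,
                colormap: str = "blue-yellow",
                domain: tuple[float, float] | None = None) -> FrameSeries:
    """Keyframe series: one transformed value per observed node per timepoint.

    The colormap domain defaults to the (min, max) of all painted values in
    this run, symmetrized about 0 for the signed equations (log, difference,
    arcsinh).
    """
    equation = equation or EquationSpec()
    control = control or ControlSpec()
    times = sorted(index.timepoints)
    observed, unobserved = observed_partition(diagram, linkmap)

    values: dict[str, list[float | None]] = {}
    for nid in observed:
        channel = linkmap.channel_for(nid)
        sub = MeasurementTable(
            table.df[table.df["channel"] == channel].copy(), dims=table.dims)
        if len(sub) == 0:
            values[nid] = [None] * len(times)
            continue
        series = collapse(sub, ("channel", "timepoint"))
        by_time = dict(zip(series.df["timepoint"], series.df["value"]))
        row: list[float | None] = []
        for t in times:
            x = by_time.get(t)
            c = control_value(table, index, channel, None, t, control)
            row.append(apply_equation(x, c, equation))
        values[nid] = row
    for nid in unobserved:
        values[nid] = [None] * len(times)

    if domain is None:
        painted = [v for series in values.values() for v in series if v is not None]
        if painted:
            lo, hi = min(painted), max(painted)
        else:
            lo, hi = 0.0, 1.0
        if equation.kind in ("log", "difference", "arcsinh"):
            m = max(abs(lo), abs(hi), 1e-12)
            lo, hi = -m, m
        if hi <= lo:  # constant data: widen to a unit band around the value
            lo, hi = lo - 0.5, hi + 0.5
        domain = (float(lo), float(hi))

    fs = FrameSeries(times=list(times), values=values,
                     cmap=make_colormap(colormap, domain))
    fs.resolve_colors()
    return fs


def map_color(value: float | None, cmap: ColorMap) -> tuple[int, int, int]:
    """Linear interpolation across the stops; out-of-domain values clamp to
    the endpoints and None maps to the no-data grey."""
    if value is None or not math.isfinite(value):
        return cmap.no_data
    lo, hi = cmap.domain
    t = (value - lo) / (hi - lo)
    t = min(1.0, max(0.0, t))
    n = len(cmap.stops)
    pos = t * (n - 1)
    i = min(int(pos), n - 2)
    frac = pos - i
    a, b = cmap.stops[i], cmap.stops[i + 1]
    return tuple(int(round(a[k] + frac * (b[k] - a[k]))) for k in range(3))


# ---------------------------------------------------------------------------
# interpolation


def interpolate(frames: FrameSeries, steps_per_interval: int | None = None,
                frames_per_minute: float | None = None) -> FrameSeries:
    """Insert piecewise-linear frames between adjacent keyframes.

    Exactly one of ``steps_per_interval`` (k frames per keyframe interval,
    equal count regardless of interval length) or ``frames_per_minute``
    (sampling uniform in minutes, so longer intervals get more frames) must
    be given. Keyframe times and values are preserved exactly; an interval
    with a no-data endpoint renders no-data at its interior frames. With
    fewer than two keyframes the input is returned unchanged.
    """
    if (steps_per_interval is None) == (frames_per_minute is None):
        raise ContractError("give exactly one of steps_per_interval / frames_per_minute")
    if frames.n_frames() < 2:
        return frames

    times = frames.times
    new_times: list[float] = []
    # (segment index, fraction) for every output frame
    samples: list[tuple[int, float]] = []
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        if steps_per_interval is not None:
            k = max(1, int(steps_per_interval))
        else:
            k = max(1, int(round((t1 - t0) * frames_per_minute)))
        for j in range(k):
            frac = j / k
            samples.append((i, frac))
            new_times.append(t0 + frac * (t1 - t0))
    samples.append((len(times) - 2, 1.0))
    new_times.append(times[-1])

    new_values: dict[str, list[float | None]] = {}
    for nid, series in frames.values.items():
        out: list[float | None] = []
        for seg, frac in samples:
            v0, v1 = series[seg], series[seg + 1]
            if frac == 0.0:
                out.append(v0)
            elif frac == 1.0:
                out.append(v1)
            elif v0 is None or v1 is None:
                out.append(None)
            else:
                out.append(v0 + frac * (v1 - v0))
        new_values[nid] = out

    fs = FrameSeries(times=new_times, values=new_values, cmap=frames.cmap)
    if frames.cmap is not None:
        fs.resolve_colors()
    return fs


# ---------------------------------------------------------------------------
# paint config


@dataclass
class PaintConfig:
    """The serializable paint-config block of a diagram document."""

    statistic: str = "mean"
    equation: EquationSpec = field(default_factory=EquationSpec)
    control: ControlSpec = field(default_factory=ControlSpec)
    colormap: str = "blue-yellow"
    domain: tuple[float, float] | None = None
    steps_per_interval: int | None = 4
    frames_per_minute: float | None = None
    heatmap: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "equation": {"kind": self.equation.kind, "cofactor": self.equation.cofactor},
            "control": self.control.kind,
            "colormap": self.colormap,
            "domain": list(self.domain) if self.domain else None,
            "steps_per_interval": self.steps_per_interval,
            "frames_per_minute": self.frames_per_minute,
            "heatmap": dict(self.heatmap),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PaintConfig":
        eq = d.get("equation", {})
        return cls(
            statistic=d.get("statistic", "mean"),
            equation=EquationSpec(kind=eq.get("kind", "raw"),
                                  cofactor=eq.get("cofactor", 5.0)),
            control=ControlSpec(kind=d.get("control", "first_column")),
            colormap=d.get("colormap", "blue-yellow"),
            domain=tuple(d["domain"]) if d.get("domain") else None,
            steps_per_interval=d.get("steps_per_interval"),
            frames_per_minute=d.get("frames_per_minute"),
            heatmap=dict(d.get("heatmap", {})),
        )
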