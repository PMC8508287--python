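"""Exactly-specified assay arithmetic.

Dual-luciferase reporter ratios (firefly / Renilla), fold changes
against a control, trapezoidal area under growth curves, and percent
inhibition of control-normalized readouts such as spheroid areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TimeSeries:
    """A monitored readout over time: confluence %, area, or object counts."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if len(times) != len(values):
            raise ValueError("times and values must have equal length")
        if len(times) < 2:
            raise ValueError("a time series needs at least 2 points")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly ascending")
        if any(v < 0 for v in values):
            raise ValueError("values must be non-negative")


def relative_luciferase(firefly: float, renilla: float) -> float:
    """Firefly activity normalized to the Renilla transfection control."""
    if renilla <= 0:
        raise ValueError("Renilla activity must be > 0")
    return firefly / renilla


def fold_change_vs_control(value: float, control: float) -> float:
    if control <= 0:
        raise ValueError("control must be > 0")
    return value / control


def auc(series: TimeSeries) -> float:
    """Trapezoidal area under the curve over the full time span."""
    return float(np.trapezoid(series.values, series.times))


def percent_inhibition(treated: float, control: float) -> float:
    """100 * (1 - treated/control); positive when treatment reduces the readout."""
    if control <= 0:
        raise ValueError("control must be > 0")
    if treated < 0:
        raise ValueError("treated must be >= 0")
    return 100.0 * (1.0 - treated / control)


def auc_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-series AUC from a long-format table (series_id, time, value)."""
    required = {"series_id", "time", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"long-format table missing column(s): {sorted(missing)}")
    rows = []
    for sid, grp in frame.groupby("series_id", sort=False):
        grp = grp.sort_values("time")
        series = TimeSeries(tuple(grp["time"]), tuple(grp["value"]))
        rows.append({"series_id": sid, "n_points": len(grp), "auc": auc(series)})
    return pd.DataFrame(rows).set_index("series_id")
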