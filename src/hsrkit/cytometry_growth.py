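"""Flow-cytometry summaries and growth-curve quantification.

Per-cell fluorescence is normalized by side scatter before taking the
sample median: side scatter tracks cell size (which multiplies fluorescence)
and collapses for dead or dying cells, so the ratio both removes size
variation and pushes dead-cell events out of the middle of the distribution.

Growth is quantified as the log-phase maximal growth rate: the maximum of
the smoothed OD600 derivative over the window after the temperature shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowSample",
    "GrowthSeries",
    "GrowthRate",
    "normalized_median",
    "fold_change_series",
    "max_growth_rate",
    "read_flow_csv",
    "read_growth_csv",
]

MIN_EVENTS = 100


@dataclass(frozen=True)
class FlowSample:
    """Per-event fluorescence and side scatter for one sample."""

    label: str
    fluorescence: np.ndarray
    side_scatter: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        s = np.asarray(self.side_scatter, dtype=float)
        if f.shape != s.shape or f.ndim != 1:
            raise ValueError("channels must be 1-d arrays of equal length")
        object.__setattr__(self, "fluorescence", f)
        object.__setattr__(self, "side_scatter", s)

    @property
    def n_events(self) -> int:
        return len(self.fluorescence)


def normalized_median(sample: FlowSample, min_events: int = MIN_EVENTS) -> float:
    """Median over events of fluorescence / side scatter.

    Events with non-positive side scatter are dropped first; fewer than
    ``min_events`` remaining is rejected as underpowered.
    """
    keep = sample.side_scatter > 0
    n = int(keep.sum())
    if n < min_events:
        raise ValueError(
            f"sample {sample.label!r}: only {n} events with positive side "
            f"scatter (< {min_events})"
        )
    return float(np.median(sample.fluorescence[keep] / sample.side_scatter[keep]))


def fold_change_series(
    samples: Mapping[float, FlowSample], reference_time: float = 0.0
) -> pd.Series:
    """Per-time normalized median divided by its value at the reference time."""
    if reference_time not in samples:
        raise ValueError(f"no sample at reference time {reference_time}")
    medians = {t: normalized_median(s) for t, s in samples.items()}
    ref = medians[reference_time]
    if ref <= 0:
        raise ValueError("reference-time median must be positive")
    times = sorted(medians)
    return pd.Series([medians[t] / ref for t in times], index=times, name="fold_change")


@dataclass(frozen=True)
class GrowthSeries:
    """One replicate's OD600 series (20-min sampling over 24 h by default)."""

    times: np.ndarray
    od600: np.ndarray
    replicate: str = "r1"
    strain: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("times/od600 must be 1-d arrays of equal length")
        if len(t) < 20:
            raise ValueError("growth series too short (< 20 points)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("OD600 must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class GrowthRate:
    rate: float      # OD/min
    time_min: float  # where the maximum derivative occurred


def max_growth_rate(
    series: GrowthSeries, shift_time_min: float = 240.0, window: int = 3
) -> GrowthRate:
    """Log-phase maximal growth rate: maximum OD600 derivative after the
    temperature shift.

    The OD series is smoothed with a centered 3-point moving average
    (interior points only, so a linear ramp keeps its exact slope), the
    derivative taken by central finite differences, and the maximum searched
    over times at or after ``shift_time_min``.
    """
    t, od = series.times, series.od600
    half = window // 2
    kernel = np.ones(window) / window
    smoothed = np.convolve(od, kernel, mode="valid")
    t_in = t[half : len(t) - half]
    deriv = np.gradient(smoothed, t_in)
    mask = t_in >= shift_time_min
    if not mask.any():
        raise ValueError("no samples at or after the shift time")
    i = int(np.argmax(deriv[mask]))
    idx = np.nonzero(mask)[0][i]
    return GrowthRate(rate=float(deriv[idx]), time_min=float(t_in[idx]))


def read_flow_csv(path) -> dict[str, FlowSample]:
    """Read tidy per-event CSV with columns sample,event,fluor,ssc."""
    df = pd.read_csv(path)
    out = {}
    for label, grp in df.groupby("sample"):
        out[str(label)] = FlowSample(
            label=str(label),
            fluorescence=grp["fluor"].to_numpy(),
            side_scatter=grp["ssc"].to_numpy(),
        )
    return out


def read_growth_csv(path) -> list[GrowthSeries]:
    """Read tidy growth CSV with columns strain,replicate,time_min,od600."""
    df = pd.read_csv(path)
    out = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"]):
        grp = grp.sort_values("time_min")
        out.append(
            GrowthSeries(
                times=grp["time_min"].to_numpy(),
                od600=grp["od600"].to_numpy(),
                replicate=str(rep),
                strain=str(strain),
            )
        )
    return out
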