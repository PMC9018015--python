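"""Turn raw per-window counts into analysis-ready traces.

The standard reduction for reporter assays on this class of device:

1. optionally rebin consecutive windows (trading temporal resolution for
   sensitivity -- counts are Poisson, so summing windows is lossless);
2. estimate the constant baseline from pre-treatment windows;
3. subtract the baseline (fold-change division available as an option);
4. aggregate replicate wells to mean +/- sd.

Background-subtracted values may be negative from shot noise; they are
preserved, since clipping at zero would bias replicate means upward.
Window midpoints serve as time coordinates for downstream fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .device import CountSeries

__all__ = [
    "ProcessedSeries",
    "AggregateSeries",
    "rebin",
    "pre_treatment_windows",
    "estimate_baseline",
    "subtract_background",
    "fold_change",
    "aggregate_replicates",
    "process_counts",
]


@dataclass(frozen=True)
class ProcessedSeries:
    """A background-corrected trace for one well."""

    well_id: str
    window_length: float
    times: np.ndarray  # window midpoints, s
    values: np.ndarray  # counts relative to baseline (may be negative)
    baseline_counts: float
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if self.baseline_counts < 0:
            raise ValueError("baseline_counts must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AggregateSeries:
    """Pointwise mean +/- sample sd across replicate wells."""

    group: str
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be non-negative")


def rebin(series: CountSeries, factor: int) -> CountSeries:
    """Sum counts in blocks of ``factor`` consecutive windows.

    Total counts over the covered span are conserved; a trailing remainder
    that does not fill a block is dropped with a warning.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return series
    n_blocks = len(series) // factor
    remainder = len(series) - n_blocks * factor
    if remainder:
        warnings.warn(
            f"rebin: dropping {remainder} trailing window(s) not filling a block",
            stacklevel=2,
        )
    summed = series.counts[: n_blocks * factor].reshape(n_blocks, factor).sum(axis=1)
    return CountSeries(
        well_id=series.well_id,
        window_length=series.window_length * factor,
        counts=summed,
    )


def pre_treatment_windows(series: CountSeries, treatment_time: float) -> np.ndarray:
    """Indices of windows wholly before ``treatment_time``."""
    ends = series.window_starts + series.window_length
    return np.flatnonzero(ends <= treatment_time)


def estimate_baseline(series: CountSeries, windows: Sequence[int]) -> float:
    """Arithmetic mean of counts over the designated pre-treatment windows.

    The mean (rather than the median) is the unbiased level estimate for
    Poisson counts.
    """
    idx = np.asarray(windows, dtype=int)
    if idx.size == 0:
        raise ValueError("at least one pre-treatment window is required")
    if np.any(idx < 0) or np.any(idx >= len(series)):
        raise ValueError("window indices out of range")
    return float(series.counts[idx].mean())


def subtract_background(
    series: CountSeries, baseline: float, *, windows_used: Sequence[int] | None = None
) -> ProcessedSeries:
    """Counts minus the constant baseline, per window."""
    values = series.counts.astype(float) - baseline
    return ProcessedSeries(
        well_id=series.well_id,
        window_length=series.window_length,
        times=series.times,
        values=values,
        baseline_counts=max(baseline, 0.0),
        normalization={
            "method": "subtract",
            "baseline_counts": baseline,
            "windows": list(map(int, windows_used)) if windows_used is not None else None,
        },
    )


def fold_change(
    series: CountSeries, baseline: float, *, windows_used: Sequence[int] | None = None
) -> ProcessedSeries:
    """Counts divided by the baseline (requires a positive baseline)."""
    if baseline <= 0:
        raise ValueError("fold-change normalization requires baseline > 0")
    values = series.counts.astype(float) / baseline
    return ProcessedSeries(
        well_id=series.well_id,
        window_length=series.window_length,
        times=series.times,
        values=values,
        baseline_counts=baseline,
        normalization={
            "method": "fold",
            "baseline_counts": baseline,
            "windows": list(map(int, windows_used)) if windows_used is not None else None,
        },
    )


def process_counts(
    series: CountSeries,
    treatment_time: float,
    *,
    rebin_factor: int = 1,
    method: str = "subtract",
) -> ProcessedSeries:
    """The standard pipeline: rebin, estimate baseline pre-treatment, normalise."""
    binned = rebin(series, rebin_factor)
    idx = pre_treatment_windows(binned, treatment_time)
    if idx.size == 0:
        raise ValueError("no complete window precedes the treatment time")
    baseline = estimate_baseline(binned, idx)
    if method == "subtract":
        return subtract_background(binned, baseline, windows_used=idx)
    if method == "fold":
        return fold_change(binned, baseline, windows_used=idx)
    raise ValueError(f"unknown normalization method {method!r}")


def aggregate_replicates(
    processed: Sequence[ProcessedSeries], group: str | None = None
) -> AggregateSeries:
    """Pointwise mean and sample sd (n-1 denominator) across replicates.

    All series must share an identical time grid.  With a single replicate
    the sd is reported as zero.
    """
    if not processed:
        raise ValueError("at least one series is required")
    times = processed[0].times
    for p in processed[1:]:
        if p.times.shape != times.shape or not np.allclose(p.times, times):
            raise ValueError("replicates must share an identical time grid")
    stack = np.stack([p.values for p in processed])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return AggregateSeries(
        group=group if group is not None else processed[0].well_id,
        times=times,
        mean=mean,
        sd=sd,
        n=n,
    )
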