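"""Breathing-cycle detection from whole-body plethysmography signals.

The pipeline identifies inspiration/expiration phases of unrestrained-mouse
breathing by double-thresholding the plethysmography signal s(t) into a
trinary series b(t), smoothing b(t) with a moving average and re-trinarizing,
then taking the first frame of each maximal run of +1 (resp. -1) as the onset
of a positive (resp. negative) cycle.  The inter-breathing-cycle interval
(ICI) is the time between consecutive positive-cycle onsets that bracket at
least one negative-cycle onset.

Thresholds default to +0.15 / -0.4 signal units and the smoothing window to
25 frames; both are instrument-dependent and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .trace import DataError, ParameterError, Trace

__all__ = ["TrinarySeries", "CycleSet", "ICISample", "trinarize",
           "smooth_retrinarize", "detect_cycles", "compute_ici", "ici_cdf",
           "breath_pipeline"]

#: smoothed means with magnitude below this are treated as exact zeros
ZERO_TOL = 1e-12


@dataclass
class TrinarySeries:
    """Per-frame codes in {-1, 0, +1} at a fixed sampling interval."""

    values: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise DataError("trinary series may only contain -1, 0, +1")
        self.values = self.values.astype(np.int8)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CycleSet:
    """Onset frame indices of positive and negative breathing cycles."""

    positive_onsets: np.ndarray
    negative_onsets: np.ndarray

    def __post_init__(self) -> None:
        self.positive_onsets = np.asarray(self.positive_onsets, dtype=np.int64)
        self.negative_onsets = np.asarray(self.negative_onsets, dtype=np.int64)
        for name, arr in (("positive", self.positive_onsets),
                          ("negative", self.negative_onsets)):
            if arr.size > 1 and not (np.diff(arr) > 0).all():
                raise DataError(f"{name} onsets must be strictly increasing")


@dataclass
class ICISample:
    """Inter-breathing-cycle intervals (seconds) for one animal."""

    intervals: np.ndarray
    animal_id: str = ""
    group: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size and not (self.intervals > 0).all():
            raise DataError("ICI values must be positive")

    def __len__(self) -> int:
        return self.intervals.size


def trinarize(trace: Trace, upper: float = 0.15, lower: float = -0.4) -> TrinarySeries:
    """Double-threshold a signal into a trinary series.

    Codes are +1 where ``s > upper``, -1 where ``s < lower`` and 0 in the
    closed band ``lower <= s <= upper`` (strict inequalities: samples exactly
    at a threshold map to 0).
    """
    if not lower < upper:
        raise ParameterError(f"lower ({lower}) must be below upper ({upper})")
    trace.require_finite()
    s = trace.values
    b = np.zeros(s.size, dtype=np.int8)
    b[s > upper] = 1
    b[s < lower] = -1
    return TrinarySeries(b, trace.sampling_interval)


def smooth_retrinarize(b: TrinarySeries, window: int = 25) -> TrinarySeries:
    """Moving-average smoothing followed by re-trinarization.

    A centered moving average of ``window`` frames is applied to the trinary
    codes (windows are truncated at the series edges), then positive means map
    to +1, negative means to -1 and exact zeros stay 0.  ``window`` must be
    odd so the window centers on a frame.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd positive integer, got {window}")
    n = len(b)
    if n <= window:
        raise DataError(f"series of length {n} is not longer than window {window}")
    kernel = np.ones(window)
    sums = np.convolve(b.values.astype(float), kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    mean = sums / counts
    out = np.zeros(n, dtype=np.int8)
    out[mean > ZERO_TOL] = 1
    out[mean < -ZERO_TOL] = -1
    return TrinarySeries(out, b.sampling_interval)


def detect_cycles(b: TrinarySeries) -> CycleSet:
    """Find cycle onsets: the first frame of every maximal run of +1 / -1.

    A run touching index 0 counts, with its onset at 0.  An all-zero series
    yields empty onset sets.
    """
    v = b.values
    prev = np.concatenate(([0], v[:-1]))
    pos = np.flatnonzero((v == 1) & (prev != 1))
    neg = np.flatnonzero((v == -1) & (prev != -1))
    return CycleSet(pos, neg)


def compute_ici(cycles: CycleSet, sampling_interval: float,
                animal_id: str = "", group: str = "",
                use_negative: bool = False) -> ICISample:
    """Inter-breathing-cycle intervals from detected cycle onsets.

    For each consecutive pair of positive onsets with at least one negative
    onset strictly between them, the interval is their frame difference times
    ``sampling_interval``.  Pairs without an intervening negative cycle are
    skipped.  With ``use_negative=True`` the roles of positive and negative
    cycles are swapped (the study reports no statistical difference between
    the two conventions).
    """
    a = cycles.negative_onsets if use_negative else cycles.positive_onsets
    other = cycles.positive_onsets if use_negative else cycles.negative_onsets
    if a.size < 2:
        return ICISample(np.empty(0), animal_id, group)
    # number of `other` onsets strictly before each boundary
    lo = np.searchsorted(other, a[:-1], side="right")
    hi = np.searchsorted(other, a[1:], side="left")
    keep = hi > lo
    intervals = (a[1:] - a[:-1])[keep] * sampling_interval
    return ICISample(intervals, animal_id, group)


def ici_cdf(sample: ICISample) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative distribution of the ICI.

    Returns the sorted unique interval values and the right-continuous
    cumulative probability at each; the final probability is exactly 1.
    """
    if len(sample) == 0:
        raise DataError(f"empty ICI sample for animal {sample.animal_id!r}")
    x = np.sort(sample.intervals)
    uniq, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / x.size
    cum[-1] = 1.0
    return uniq, cum


def breath_pipeline(trace: Trace, upper: float = 0.15, lower: float = -0.4,
                    window: int = 25, start: float | None = None,
                    duration: float | None = None,
                    use_negative: bool = False) -> ICISample:
    """Run the full breathing pipeline on one trace.

    Optionally restricts the analysis to ``[start, start + duration)`` seconds
    (e.g. the 1 h window following animal adaptation) before trinarization.
    """
    if start is not None or duration is not None:
        t0 = trace.start_time if start is None else start
        t1 = trace.start_time + trace.duration if duration is None else t0 + duration
        trace = trace.window(t0, t1)
    b = smooth_retrinarize(trinarize(trace, upper, lower), window)
    cycles = detect_cycles(b)
    return compute_ici(cycles, trace.sampling_interval,
                       animal_id=str(trace.meta.get("animal_id", "")),
                       group=str(trace.meta.get("group", "")),
                       use_negative=use_negative)
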