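"""Uniformly sampled physiological traces and file I/O.

A :class:`Trace` is the common container for every signal the package
analyzes: whole-body plethysmography records, cell-attached spike traces,
whole-cell postsynaptic-current sweeps and field-potential sweeps.  Values
are stored in the instrument's native units ("signal units" for
plethysmography, pA for currents, mV for field potentials) together with the
sampling interval in seconds per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Trace", "DataError", "ParameterError", "read_trace_csv",
           "write_trace_csv", "read_traces_edf"]


class DataError(ValueError):
    """Raised when input data violate a contract (non-finite samples, empty
    samples, windows outside the recording, ...)."""


class ParameterError(ValueError):
    """Raised when an analysis or simulation parameter is invalid."""


@dataclass
class Trace:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    values : ndarray
        Signal amplitude per frame.
    sampling_interval : float
        Seconds per frame; must be positive.
    start_time : float, default 0.0
        Time of the first frame, in seconds.
    meta : dict
        Free-form metadata (animal id, group label, channel name, units).
    """

    values: np.ndarray
    sampling_interval: float
    start_time: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("trace values must be one-dimensional")
        if not self.sampling_interval > 0:
            raise ParameterError(
                f"sampling_interval must be positive, got {self.sampling_interval}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.sampling_interval

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.values.size * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds."""
        return self.start_time + np.arange(self.values.size) * self.sampling_interval

    def require_finite(self) -> None:
        """Raise :class:`DataError` naming the first non-finite frame."""
        bad = ~np.isfinite(self.values)
        if bad.any():
            raise DataError(f"non-finite sample at frame {int(np.argmax(bad))}")

    def window(self, t_start: float, t_stop: float) -> "Trace":
        """Return the sub-trace covering ``[t_start, t_stop)`` seconds."""
        i0 = max(0, int(np.ceil((t_start - self.start_time) / self.sampling_interval)))
        i1 = min(len(self), int(np.ceil((t_stop - self.start_time) / self.sampling_interval)))
        if i1 <= i0:
            raise DataError(f"window [{t_start}, {t_stop}) is outside the trace")
        return Trace(self.values[i0:i1], self.sampling_interval,
                     start_time=self.start_time + i0 * self.sampling_interval,
                     meta=dict(self.meta))


def read_trace_csv(path: str | Path, time_col: str = "time_s",
                   value_col: str | None = None, meta: dict | None = None) -> Trace:
    """Read a two-column (time, value) CSV into a :class:`Trace`.

    The time column must be uniformly sampled; the value column defaults to
    the first non-time column.
    """
    df = pd.read_csv(path)
    if time_col not in df.columns:
        time_col = df.columns[0]
    if value_col is None:
        value_col = next(c for c in df.columns if c != time_col)
    t = df[time_col].to_numpy(float)
    if t.size < 2:
        raise DataError(f"{path}: need at least two samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise DataError(f"{path}: time column is not uniformly sampled")
    return Trace(df[value_col].to_numpy(float), dt, start_time=float(t[0]),
                 meta=meta or {})


def write_trace_csv(trace: Trace, path: str | Path, value_col: str = "value") -> None:
    pd.DataFrame({"time_s": trace.times, value_col: trace.values}).to_csv(
        path, index=False)


def read_traces_edf(path: str | Path) -> list[Trace]:
    """Read every channel of an EDF file as a :class:`Trace`.

    Requires ``mne``.  Channel names are stored under ``meta['channel']``.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    dt = 1.0 / raw.info["sfreq"]
    data = raw.get_data()
    return [Trace(data[i], dt, meta={"channel": name, "source": str(path)})
            for i, name in enumerate(raw.ch_names)]
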