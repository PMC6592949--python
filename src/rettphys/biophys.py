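"""Biophysical estimation: GABA driving force from single-channel I/V data
and mGluR-dependent long-term depression from fEPSP slopes.

DF_GABA — the driving force of GABA_A-receptor currents, E_GABA minus the
resting membrane potential — is estimated as the zero-current abscissa of a
least-squares fit to the single-channel current/voltage relation recorded in
the cell-attached configuration.  With the potential axis expressed as -Vp
(the negated pipette command, the convention in which such curves are
plotted), the current through the patch is proportional to (-Vp - DF_GABA),
so the fitted reversal abscissa IS the driving force; a convention switch
handles raw-Vp input.

LTD: the fEPSP slope is measured on the 30-70 % rising phase of each sweep,
normalized to the pre-drug baseline, and summarized over the early window
(20-25 min after DHPG washout) and the late window (50-55 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace import DataError, ParameterError, Trace

__all__ = ["IVDataset", "DFEstimate", "SlopeSeries", "LTDSummary", "fit_iv",
           "fepsp_slope", "normalize_slopes", "ltd_summary",
           "EARLY_LTD_WINDOW", "LATE_LTD_WINDOW", "MIN_OPENINGS"]

#: minutes after DHPG washout
EARLY_LTD_WINDOW = (20.0, 25.0)
LATE_LTD_WINDOW = (50.0, 55.0)
#: minimum single-channel openings per potential for a reliable mean current
MIN_OPENINGS = 20


@dataclass
class IVDataset:
    """Single-channel current/voltage relation.

    One row per holding potential: the imposed potential (mV, -Vp convention
    by default), the mean open-channel current (pA) and the number of channel
    openings averaged.  ``low_openings`` flags potentials with fewer than
    :data:`MIN_OPENINGS` openings.
    """

    potentials_mV: np.ndarray
    mean_current_pA: np.ndarray
    n_openings: np.ndarray
    convention: str = "minus_vp"  # 'minus_vp' (as plotted) or 'vp' (raw pipette)

    def __post_init__(self) -> None:
        self.potentials_mV = np.asarray(self.potentials_mV, dtype=float)
        self.mean_current_pA = np.asarray(self.mean_current_pA, dtype=float)
        self.n_openings = np.asarray(self.n_openings, dtype=int)
        if np.unique(self.potentials_mV).size < 3:
            raise ParameterError("need at least 3 distinct potentials")
        if self.convention not in ("minus_vp", "vp"):
            raise ParameterError(f"unknown convention {self.convention!r}")

    @property
    def low_openings(self) -> np.ndarray:
        return self.n_openings < MIN_OPENINGS


@dataclass
class DFEstimate:
    reversal_mV: float
    df_gaba_mV: float
    slope_conductance_pS: float
    residual_rms_pA: float
    extrapolated: bool
    low_openings: bool
    model: str = "linear"


@dataclass
class SlopeSeries:
    """fEPSP slopes over an LTD experiment.

    Times are minutes relative to DHPG washout (negative = baseline period);
    ``normalized`` is percent of the pre-drug baseline mean.
    """

    times_min: np.ndarray
    slopes: np.ndarray
    normalized: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.times_min.size > 1 and not (np.diff(self.times_min) > 0).all():
            raise DataError("times must be strictly increasing")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)


@dataclass
class LTDSummary:
    early_pct: float
    early_sem: float
    late_pct: float
    late_sem: float
    early_window: tuple[float, float] = EARLY_LTD_WINDOW
    late_window: tuple[float, float] = LATE_LTD_WINDOW


def fit_iv(data: IVDataset, model: str = "linear",
           extrapolation_margin: float = 20.0) -> DFEstimate:
    """Estimate the reversal potential (and DF_GABA) from an I/V relation.

    ``model='linear'`` fits I = g (V - V_rev) by ordinary least squares;
    ``model='quadratic'`` adds a rectification term and takes the root nearest
    the recorded potential span.  A reversal falling more than
    ``extrapolation_margin`` mV outside the recorded range is flagged as
    extrapolated.  DF_GABA equals V_rev when potentials are in the -Vp
    convention and -V_rev when raw Vp values were supplied.
    """
    v = data.potentials_mV
    i = data.mean_current_pA
    if np.ptp(v) == 0:
        raise DataError("all potentials identical: fit is rank-deficient")
    if model == "linear":
        coef = np.polyfit(v, i, 1)
        g, b = float(coef[0]), float(coef[1])
        if g == 0:
            raise DataError("zero slope conductance: reversal undefined")
        v_rev = -b / g
        resid = i - np.polyval(coef, v)
    elif model == "quadratic":
        coef = np.polyfit(v, i, 2)
        roots = np.roots(coef)
        roots = roots[np.isreal(roots)].real
        if roots.size == 0:
            raise DataError("quadratic I/V fit has no real zero crossing")
        mid = 0.5 * (v.min() + v.max())
        v_rev = float(roots[np.argmin(np.abs(roots - mid))])
        g = float(np.polyval(np.polyder(coef), v_rev))
        resid = i - np.polyval(coef, v)
    else:
        raise ParameterError(f"unknown model {model!r}")
    extrapolated = not (v.min() - extrapolation_margin
                        <= v_rev <= v.max() + extrapolation_margin)
    df = v_rev if data.convention == "minus_vp" else -v_rev
    # g is pA/mV = nS; report pS
    return DFEstimate(reversal_mV=float(v_rev), df_gaba_mV=float(df),
                      slope_conductance_pS=float(g * 1e3),
                      residual_rms_pA=float(np.sqrt(np.mean(resid ** 2))),
                      extrapolated=extrapolated,
                      low_openings=bool(data.low_openings.any()),
                      model=model)


def fepsp_slope(sweep: Trace, onset_window: tuple[float, float],
                lo: float = 0.30, hi: float = 0.70) -> float:
    """fEPSP onset slope: linear regression over the 30-70 % rising phase.

    The peak is the extremum of largest deviation from the pre-window baseline
    inside ``onset_window`` (seconds); the rising phase runs from the window
    start to that peak, and the regression uses the samples whose deviation is
    between ``lo`` and ``hi`` of the peak-to-baseline amplitude.  Returns the
    slope in signal units per ms (mV/ms for a field potential in mV).
    """
    sub = sweep.window(*onset_window)
    pre = sweep.values[:max(0, int(round((onset_window[0] - sweep.start_time)
                                         / sweep.sampling_interval)))]
    baseline = float(pre.mean()) if pre.size else float(sub.values[0])
    dev = sub.values - baseline
    k_peak = int(np.argmax(np.abs(dev)))
    amp = dev[k_peak]
    if amp == 0:
        raise DataError("no fEPSP peak found in the onset window")
    frac = dev[:k_peak + 1] / amp  # rising phase, monotone toward 1
    band = np.flatnonzero((frac >= lo) & (frac <= hi))
    if band.size < 3:
        raise DataError(f"only {band.size} samples in the {lo:.0%}-{hi:.0%} band")
    t_ms = (sub.times[band]) * 1e3
    res = stats.linregress(t_ms, sub.values[band])
    return float(res.slope)


def normalize_slopes(series: SlopeSeries,
                     baseline_window: tuple[float, float] | None = None,
                     baseline_span_min: float = 10.0) -> SlopeSeries:
    """Express slopes as percent of the pre-drug baseline mean.

    The baseline defaults to the final ``baseline_span_min`` minutes before
    time zero (DHPG onset/washout reference).  Normalizing an
    already-normalized series returns identical values (idempotence): the
    baseline mean of a normalized series is 100 %, and dividing by it changes
    nothing.
    """
    if baseline_window is None:
        t0 = max(series.times_min.min(), -baseline_span_min)
        baseline_window = (t0, 0.0)
    m = (series.times_min >= baseline_window[0]) & (series.times_min < baseline_window[1])
    if not m.any():
        raise DataError("baseline window contains no sweeps")
    src = series.normalized if series.normalized is not None else series.slopes
    base = float(src[m].mean())
    if base == 0:
        raise DataError("zero baseline mean: normalization undefined")
    return SlopeSeries(series.times_min, series.slopes,
                       normalized=100.0 * src / base,
                       baseline_window=baseline_window)


def _window_stats(t: np.ndarray, y: np.ndarray,
                  window: tuple[float, float]) -> tuple[float, float]:
    m = (t >= window[0]) & (t <= window[1])
    if not m.any():
        raise DataError(f"series does not cover the window {window} min")
    vals = y[m]
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), sem


def ltd_summary(series: SlopeSeries,
                early_window: tuple[float, float] = EARLY_LTD_WINDOW,
                late_window: tuple[float, float] = LATE_LTD_WINDOW) -> LTDSummary:
    """Mean +/- SEM of the normalized fEPSP slope in the early- and late-LTD
    windows (minutes after DHPG washout).  The series is normalized first if
    it has not been."""
    if series.normalized is None:
        series = normalize_slopes(series)
    early, early_sem = _window_stats(series.times_min, series.normalized, early_window)
    late, late_sem = _window_stats(series.times_min, series.normalized, late_window)
    return LTDSummary(early, early_sem, late, late_sem, early_window, late_window)
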