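"""Spike and postsynaptic-current quantification.

Implements threshold-based event detection (threshold = 3x the SD of the
bath noise), drug-effect normalization with the washout-recovery exclusion
rule, population-burst detection (>= 3 sEPSC riding on a >= 60 pA baseline
elevation), charge density, the sIPSC/sEPSC charge-density ratio, paired-trace
synchrony (Pearson r and cross-correlogram) and the recording quality-control
exclusions (holding-current bounds per age class; > 15 % parameter drift).

Current conventions: inward synaptic currents are negative deflections;
``polarity='negative'`` rectifies the trace so all internal amplitudes are
positive.  Charges are in pC (pA x s), densities in pC/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import median_filter

from .trace import DataError, ParameterError, Trace

__all__ = ["EventTrain", "Burst", "BurstSet", "DrugEffect", "QCRecord",
           "estimate_noise_sd", "detect_events", "frequency_timecourse",
           "drug_effect", "detect_bursts", "charge_density", "ei_ratio",
           "paired_correlation", "qc_filter"]

Polarity = Literal["positive", "negative"]


@dataclass
class EventTrain:
    """Detected events: onset times (s), peak amplitudes (pA, rectified
    positive), per-event charge (pC) and the duration of the source recording."""

    times: np.ndarray
    amplitudes: np.ndarray
    charges: np.ndarray
    polarity: Polarity = "negative"
    source_id: str = ""
    duration: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise DataError("event times must be strictly increasing")
        if (self.charges < 0).any():
            raise DataError("event charges must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    def in_window(self, t0: float, t1: float) -> "EventTrain":
        m = (self.times >= t0) & (self.times < t1)
        return EventTrain(self.times[m], self.amplitudes[m], self.charges[m],
                          self.polarity, self.source_id, duration=t1 - t0)


@dataclass
class Burst:
    start: float
    end: float
    charge: float
    peak_amplitude: float
    n_events: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def charge_density(self) -> float:
        return self.charge / self.duration


@dataclass
class BurstSet:
    bursts: list[Burst] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)


@dataclass
class DrugEffect:
    baseline_hz: float
    drug_hz: float
    normalized_effect: float
    washout_hz: float
    washout_ok: bool


@dataclass
class QCRecord:
    """Per-cell quality-control record for whole-cell recordings."""

    holding_current_pA: float
    age_class: str  # 'P0' or 'P15'
    input_resistance_drift_pct: float = 0.0
    holding_current_drift_pct: float = 0.0
    decision: str = ""
    reason: str = ""


def estimate_noise_sd(trace: Trace, baseline_window: tuple[float, float]) -> float:
    """SD of the (event-free) samples in ``baseline_window`` (seconds).

    The caller asserts the window is free of events — typically noise recorded
    in the bath solution.  Requires at least 100 samples.
    """
    sub = trace.window(*baseline_window)
    if len(sub) < 100:
        raise DataError(f"baseline window has only {len(sub)} samples (<100)")
    return float(np.std(sub.values))


def _rectify(trace: Trace, polarity: Polarity) -> np.ndarray:
    x = trace.values - np.median(trace.values)
    return x if polarity == "positive" else -x


def detect_events(trace: Trace, noise_sd: float, polarity: Polarity = "negative",
                  threshold_mult: float = 3.0, refractory: float = 0.005,
                  baseline_span: float = 0.05, smooth: float = 0.002,
                  detrend: float | None = None) -> EventTrain:
    """Threshold-crossing event detection.

    An event starts where the polarity-rectified, median-centred signal
    crosses ``threshold_mult * noise_sd`` and extends until it falls back
    below half the threshold; a new event cannot start until ``refractory``
    seconds after the previous event's extent ends (re-arm rule).  Per-event
    peak amplitude and charge (integral of the deviation from a local
    baseline, the median of the ``baseline_span`` seconds preceding onset)
    are computed over the extent.

    Thresholding is applied to a boxcar-smoothed copy of the signal
    (``smooth`` seconds, on the order of the event rise time; 0 disables it)
    so that single-sample noise excursions past the threshold do not register
    as events, while amplitudes and charges are measured on the raw signal.
    With ``detrend`` (seconds), a running median of that span is subtracted
    before thresholding so events riding on slow baseline shifts — e.g.
    individual sEPSCs inside a population burst's elevation — are still
    detected one by one.
    """
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive (threshold degenerate)")
    trace.require_finite()
    x = _rectify(trace, polarity)
    dt = trace.sampling_interval
    if detrend is not None:
        size = max(int(round(detrend / dt)) | 1, 3)
        x = x - median_filter(x, size=size, mode="nearest")
    if smooth and smooth > dt:
        w = int(round(smooth / dt))
        d = np.convolve(x, np.ones(w) / w, mode="same")
    else:
        d = x
    thresh = threshold_mult * noise_sd
    above = d > thresh
    if not above.any():
        return EventTrain(np.empty(0), np.empty(0), np.empty(0), polarity,
                          str(trace.meta.get("id", "")), trace.duration)
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    below_half = np.flatnonzero(~(d > 0.5 * thresh))
    n = x.size
    ref_frames = max(int(round(refractory / dt)), 0)
    base_frames = max(int(round(baseline_span / dt)), 1)

    times, amps, charges = [], [], []
    rearm_at = 0  # earliest frame a new event may start
    for k in onsets:
        if k < rearm_at:
            continue
        # extent: from onset until signal drops below half-threshold
        j = np.searchsorted(below_half, k)
        end = int(below_half[j]) if j < below_half.size else n
        base = float(np.median(x[max(0, k - base_frames):k])) if k > 0 else 0.0
        seg = x[k:end]
        times.append(trace.start_time + k * dt)
        amps.append(float(seg.max() - base))
        charges.append(float(np.abs(seg - base).sum() * dt))
        rearm_at = end + ref_frames
    return EventTrain(np.array(times), np.array(amps), np.array(charges),
                      polarity, str(trace.meta.get("id", "")), trace.duration)


def frequency_timecourse(train: EventTrain, bin: float,
                         duration: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Event frequency per time bin (Hz).  Total counts are conserved:
    sum(rates) * bin equals the number of events inside the covered span."""
    if bin <= 0:
        raise ParameterError("bin width must be positive")
    total = duration if duration is not None else train.duration
    if total <= 0:
        total = float(train.times[-1] + bin) if len(train) else bin
    edges = np.arange(0.0, total + bin, bin)
    counts, _ = np.histogram(train.times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / bin


def _window_freq(train: EventTrain, window: tuple[float, float]) -> float:
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError(f"window {window} has non-positive width")
    return float(np.count_nonzero((train.times >= t0) & (train.times < t1)) / (t1 - t0))


def drug_effect(train: EventTrain, baseline_window: tuple[float, float],
                drug_window: tuple[float, float],
                washout_window: tuple[float, float],
                washout_tol: float = 0.20) -> DrugEffect:
    """Drug effect on event frequency, normalized to baseline.

    ``normalized_effect = freq(drug) / freq(baseline)``; values below 1
    indicate inhibition, above 1 excitation.  ``washout_ok`` is True when the
    washout frequency returns to within ``washout_tol`` (default +/-20 %) of
    baseline — recordings failing this are excluded from analysis.
    """
    if not baseline_window[1] <= drug_window[0] or not drug_window[1] <= washout_window[0]:
        raise ParameterError("windows must be disjoint and ordered "
                             "baseline < drug < washout")
    f_base = _window_freq(train, baseline_window)
    if f_base == 0:
        raise DataError("baseline frequency is zero: normalized effect undefined")
    f_drug = _window_freq(train, drug_window)
    f_wash = _window_freq(train, washout_window)
    ok = abs(f_wash - f_base) <= washout_tol * f_base
    return DrugEffect(f_base, f_drug, f_drug / f_base, f_wash, ok)


def detect_bursts(train: EventTrain, trace: Trace, min_events: int = 3,
                  elevation_pA: float = 60.0, baseline_filter: float = 0.2,
                  max_gap: float = 0.05) -> BurstSet:
    """Population-burst detection.

    The running baseline is a median filter (default 200 ms) of the
    polarity-rectified trace; epochs where it is elevated by at least
    ``elevation_pA`` above the quiescent level (the median of the running
    baseline) and containing at least ``min_events`` detected events become
    bursts.  Sub-``max_gap`` interruptions of an elevated epoch (noise wiggle
    around the criterion) are bridged.  Per-burst charge is the integral of
    the rectified signal above the quiescent level over the epoch.
    """
    x = _rectify(trace, train.polarity)
    dt = trace.sampling_interval
    size = max(int(round(baseline_filter / dt)) | 1, 3)  # odd filter length
    runmed = median_filter(x, size=size, mode="nearest")
    quiescent = float(np.median(runmed))
    elevated = (runmed - quiescent) >= elevation_pA
    gap_frames = int(round(max_gap / dt))
    if gap_frames > 0 and elevated.any() and not elevated.all():
        # bridge short dips: close gaps shorter than max_gap
        d = np.diff(elevated.astype(np.int8))
        falls = np.flatnonzero(d == -1) + 1
        rises = np.flatnonzero(d == 1) + 1
        for f in falls:
            nxt = rises[rises > f]
            if nxt.size and nxt[0] - f <= gap_frames:
                elevated[f:nxt[0]] = True
    bursts: list[Burst] = []
    if elevated.any():
        d = np.diff(elevated.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if elevated[0]:
            starts = np.concatenate(([0], starts))
        if elevated[-1]:
            ends = np.concatenate((ends, [x.size]))
        for i0, i1 in zip(starts, ends):
            t0 = trace.start_time + i0 * dt
            t1 = trace.start_time + i1 * dt
            n_ev = int(np.count_nonzero((train.times >= t0) & (train.times < t1)))
            if n_ev < min_events:
                continue
            seg = x[i0:i1] - quiescent
            bursts.append(Burst(start=t0, end=t1,
                                charge=float(seg.sum() * dt),
                                peak_amplitude=float(seg.max()),
                                n_events=n_ev))
    return BurstSet(bursts)


def charge_density(train: EventTrain, duration: float,
                   control_reference: float | None = None):
    """Summed per-event charge per second of recording (pC/s).

    With ``control_reference`` (the control-group mean CD, supplied
    explicitly), also returns the CD normalized to control.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    cd = float(train.charges.sum() / duration)
    if control_reference is None:
        return cd
    if control_reference == 0:
        raise ParameterError("control reference charge density is zero")
    return cd, cd / control_reference


def ei_ratio(ipsc_cd: float, epsc_cd: float) -> float:
    """sIPSC/sEPSC charge-density ratio (inhibition/excitation balance)."""
    if epsc_cd <= 0:
        raise ParameterError("sEPSC charge density must be positive")
    return ipsc_cd / epsc_cd


def _bin_means(v: np.ndarray, w: int) -> np.ndarray:
    n = (v.size // w) * w
    return v[:n].reshape(-1, w).mean(axis=1)


def paired_correlation(a: Trace, b: Trace, max_lag: float = 0.5,
                       bin: float = 0.01):
    """Synchrony between two simultaneously recorded traces.

    Both traces are binned at ``bin`` seconds (mean within bins) and the
    Pearson coefficient at zero lag is returned together with the normalized
    cross-correlogram over lags in ``[-max_lag, +max_lag]``.  Binning makes
    the coefficient reflect event co-occurrence rather than kinetics.
    """
    if len(a) != len(b) or a.sampling_interval != b.sampling_interval:
        raise ParameterError("traces must share duration and sampling")
    w = max(int(round(bin / a.sampling_interval)), 1)
    xa = _bin_means(a.values, w)
    xb = _bin_means(b.values, w)
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    sa, sb = xa.std(), xb.std()
    if sa == 0 or sb == 0:
        raise DataError("zero-variance trace: correlation undefined")
    nb = xa.size
    max_shift = min(int(round(max_lag / bin)), nb - 1)
    lags = np.arange(-max_shift, max_shift + 1)
    denom = nb * sa * sb
    xcorr = np.array([
        np.dot(xa[max(0, -s):nb - max(0, s)], xb[max(0, s):nb - max(0, -s)])
        for s in lags]) / denom
    r = float(np.dot(xa, xb) / denom)
    return r, lags * bin, xcorr


def qc_filter(rec: QCRecord, p0_bound: float = 30.0, p15_bound: float = 40.0,
              drift_bound: float = 15.0, invert_holding_sign: bool = False) -> QCRecord:
    """Apply the whole-cell recording exclusion rules.

    Cells are excluded when the holding current at -70 mV exceeds the
    age-class bound (default magnitude bounds: 30 pA at P0, 40 pA at P15,
    read as "more negative than -bound" since a large negative holding
    current indicates leak; ``invert_holding_sign`` flips the reading), or
    when holding current or input resistance drifted by more than
    ``drift_bound`` percent during the recording.  Exactly one triggering
    rule is recorded.
    """
    if rec.age_class not in ("P0", "P15"):
        raise DataError(f"unknown age class {rec.age_class!r}")
    bound = p0_bound if rec.age_class == "P0" else p15_bound
    h = rec.holding_current_pA
    holding_bad = (h > -bound) if invert_holding_sign else (h < -bound)
    if holding_bad:
        rec.decision, rec.reason = "exclude", (
            f"holding current {h:g} pA exceeds {rec.age_class} bound ({bound:g} pA)")
    elif rec.input_resistance_drift_pct > drift_bound:
        rec.decision, rec.reason = "exclude", (
            f"input resistance drift {rec.input_resistance_drift_pct:g}% > {drift_bound:g}%")
    elif rec.holding_current_drift_pct > drift_bound:
        rec.decision, rec.reason = "exclude", (
            f"holding current drift {rec.holding_current_drift_pct:g}% > {drift_bound:g}%")
    else:
        rec.decision, rec.reason = "keep", ""
    return rec
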