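"""Synthetic physiological signals with known ground truth.

Every generator emulates the statistical structure of one recording modality
analyzed by the package, with the planted ground truth returned alongside the
signal so downstream detectors can be validated without real data:

* breathing cohorts — per-animal plethysmography traces whose
  inter-breathing-cycle intervals (ICIs) are drawn from genotype-dependent
  log-normal distributions (strictly positive and right-skewed, like real
  breathing intervals);
* postsynaptic-current traces and pairs — Poisson event trains rendered with
  a double-exponential kernel, optionally pair-correlated and carrying
  population bursts (event clusters riding on a baseline elevation);
* cell-attached spike traces with a drug-response epoch;
* single-channel I/V tables with a known reversal potential;
* baseline-normalized fEPSP slope series with configurable early/late
  depression.

All randomness flows from one explicit integer seed per call; fixed seeds
give bit-identical outputs.  Zero-noise signals are constructed so every
downstream detector recovers the planted ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biophys import IVDataset, SlopeSeries
from .breath import CycleSet
from .trace import ParameterError, Trace

__all__ = ["BreathSimParams", "EphysSimParams", "BurstSpec", "IVSimParams",
           "BreathRecord", "gen_breath_cohort", "gen_psc_pair",
           "gen_spike_trace", "gen_iv_dataset", "gen_ltd_series"]


# ---------------------------------------------------------------------------
# breathing cohorts
# ---------------------------------------------------------------------------

@dataclass
class BreathSimParams:
    """Conditions of a simulated plethysmography cohort.

    ``group_ici_dists`` maps each group label to a log-normal ICI
    distribution given as (median seconds, sigma of log).  Defaults emulate
    the study design: a wild-type group with short regular intervals and two
    Mecp2-null groups (untreated and maternally pretreated) sharing one
    longer, more irregular distribution — the pretreatment does not change
    breathing.  Cycle amplitudes are chosen so positive deflections exceed
    the +0.15 detection threshold and negative deflections fall below -0.4
    at zero noise.
    """

    n_animals_per_group: int = 10
    group_ici_dists: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "wt": (0.30, 0.20),
        "mecp2": (0.45, 0.35),
        "mecp2_mp": (0.45, 0.35),
    })
    pos_amplitude: float = 1.0
    pos_duration: float = 0.10
    neg_amplitude: float = 1.0
    neg_duration: float = 0.10
    noise_sd: float = 0.02
    sampling_rate: float = 1000.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1:
            raise ParameterError("need at least one animal per group")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ParameterError("sampling rate and duration must be positive")
        for g, (med, sig) in self.group_ici_dists.items():
            if med <= 0 or sig <= 0:
                raise ParameterError(f"group {g!r}: ICI median and sigma must be positive")
        if self.pos_amplitude <= 0.15 or self.neg_amplitude <= 0.4:
            raise ParameterError("deflection amplitudes must clear the "
                                 "+0.15 / -0.4 thresholds at zero noise")


@dataclass
class BreathRecord:
    """One simulated animal: trace plus planted ground truth."""

    trace: Trace
    true_cycles: CycleSet          # onsets in the analysis (smoothed) convention
    true_ici: np.ndarray           # seconds, frame-quantized planted intervals
    animal_id: str
    group: str


def _cycle_template(params: BreathSimParams) -> np.ndarray:
    """Clean single-cycle waveform: positive then negative half-sine.

    Samples are taken at lobe-interior phases so the first sample of each
    lobe is nonzero but below threshold (a realistic gradual onset)."""
    fs = params.sampling_rate
    np_pos = max(int(round(params.pos_duration * fs)), 3)
    np_neg = max(int(round(params.neg_duration * fs)), 3)
    pos = params.pos_amplitude * np.sin(np.pi * (np.arange(np_pos) + 0.5) / np_pos)
    neg = -params.neg_amplitude * np.sin(np.pi * (np.arange(np_neg) + 0.5) / np_neg)
    return np.concatenate((pos, neg))


def _template_onset_offsets(template: np.ndarray, params: BreathSimParams,
                            upper: float = 0.15, lower: float = -0.4,
                            window: int = 25) -> tuple[int, int]:
    """Offsets (frames) from the cycle start to the positive and negative
    cycle onsets in the smoothed-trinary convention, computed on the clean
    template via direct window sums (generator-local arithmetic)."""
    pad = window  # cycles are separated by at least `window` zero frames
    s = np.concatenate((np.zeros(pad), template, np.zeros(pad)))
    b = np.where(s > upper, 1, np.where(s < lower, -1, 0)).astype(float)
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], b)))
    idx = np.arange(s.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, s.size)
    means = (csum[hi] - csum[lo]) / (hi - lo)
    tri = np.where(means > 1e-12, 1, np.where(means < -1e-12, -1, 0))
    pos_on = int(np.flatnonzero(tri == 1)[0]) - pad
    neg_on = int(np.flatnonzero(tri == -1)[0]) - pad
    return pos_on, neg_on


def _gen_breath_animal(rng: np.random.Generator, params: BreathSimParams,
                       dist: tuple[float, float], animal_id: str,
                       group: str, window: int = 25) -> BreathRecord:
    fs = params.sampling_rate
    dt = 1.0 / fs
    n = int(round(params.duration * fs))
    template = _cycle_template(params)
    tlen = template.size
    # minimum interval: the cycle itself plus a zero gap long enough that
    # smoothing windows of adjacent cycles never overlap
    min_frames = tlen + window + 2
    med, sig = dist

    start = window + 2
    onsets = [start]
    while True:
        ici = float(rng.lognormal(mean=np.log(med), sigma=sig))
        frames = max(int(round(ici * fs)), min_frames)
        nxt = onsets[-1] + frames
        if nxt + tlen + window >= n:
            break
        onsets.append(nxt)
    onsets_arr = np.asarray(onsets, dtype=np.int64)
    signal = np.zeros(n)
    for k in onsets_arr:
        signal[k:k + tlen] += template
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=n)

    pos_off, neg_off = _template_onset_offsets(template, params, window=window)
    true_cycles = CycleSet(onsets_arr + pos_off, onsets_arr + neg_off)
    true_ici = np.diff(onsets_arr) * dt
    trace = Trace(signal, dt, meta={"animal_id": animal_id, "group": group,
                                    "units": "signal units"})
    return BreathRecord(trace, true_cycles, true_ici, animal_id, group)


def gen_breath_cohort(params: BreathSimParams, window: int = 25) -> list[BreathRecord]:
    """Simulate a full plethysmography cohort.

    Returns one :class:`BreathRecord` per animal, groups interleaved in the
    order of ``group_ici_dists``.  Planted ICIs are quantized to the frame
    grid; ground-truth onsets are expressed in the smoothed-trinary analysis
    convention so zero-noise detection matches them exactly.
    """
    records: list[BreathRecord] = []
    idx = 0
    for group, dist in params.group_ici_dists.items():
        for j in range(params.n_animals_per_group):
            rng = np.random.default_rng([params.seed, idx])
            records.append(_gen_breath_animal(
                rng, params, dist, animal_id=f"{group}_{j:02d}", group=group,
                window=window))
            idx += 1
    return records


# ---------------------------------------------------------------------------
# postsynaptic-current and spike traces
# ---------------------------------------------------------------------------

@dataclass
class BurstSpec:
    """Population bursts: clusters of events riding on a baseline elevation.

    The elevation rises and falls with raised-cosine ramps (``ramp_s`` each
    side of the flat top), emulating the gradual build-up of summating
    synaptic currents rather than an instrument-like step."""

    rate_hz: float = 0.2
    events_per_burst: int = 5
    elevation_pA: float = 80.0
    duration_s: float = 0.4
    ramp_s: float = 0.1


@dataclass
class EphysSimParams:
    """Conditions of a simulated current/spike recording.

    Events are a dead-time Poisson process (``min_separation_s`` enforces
    detectability of individual events) rendered with a double-exponential
    kernel.  ``drug_multiplier`` scales the rate inside a drug epoch
    (<1 inhibitory, >1 excitatory).  ``pair_correlation`` is the fraction of
    events shared between the two traces of a dual recording.
    """

    baseline_rate: float = 2.0
    drug_multiplier: float = 0.5
    rise_ms: float = 2.0
    decay_ms: float = 10.0
    amp_mean_pA: float = 30.0
    amp_sd_pA: float = 8.0
    burst_spec: BurstSpec | None = None
    pair_correlation: float = 0.0
    noise_sd: float = 2.0
    sampling_rate: float = 2000.0
    min_separation_s: float = 0.05
    polarity: str = "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or (self.burst_spec and self.burst_spec.rate_hz < 0):
            raise ParameterError("rates must be non-negative")
        if not 0.0 <= self.pair_correlation <= 1.0:
            raise ParameterError("pair_correlation must be in [0, 1]")
        if self.rise_ms <= 0 or self.decay_ms <= self.rise_ms:
            raise ParameterError("kernel requires 0 < rise < decay")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling rate must be positive")


def _kernel(params: EphysSimParams) -> np.ndarray:
    """Double-exponential kernel normalized to unit peak."""
    fs = params.sampling_rate
    tau_r = params.rise_ms * 1e-3
    tau_d = params.decay_ms * 1e-3
    t = np.arange(int(round(6 * tau_d * fs))) / fs
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / k.max()


def _dead_time_poisson(rng: np.random.Generator, rate: float, t0: float,
                       t1: float, dead: float) -> list[float]:
    """Poisson process on [t0, t1) with a refractory dead time."""
    if rate <= 0:
        return []
    out: list[float] = []
    t = t0
    while True:
        t += rng.exponential(1.0 / rate) + dead
        if t >= t1:
            return out
        out.append(t)


def _render(times: np.ndarray, amps: np.ndarray, kernel: np.ndarray,
            n: int, fs: float) -> np.ndarray:
    impulses = np.zeros(n)
    idx = np.round(np.asarray(times) * fs).astype(int)
    keep = idx < n
    np.add.at(impulses, idx[keep], np.asarray(amps)[keep])
    out = np.convolve(impulses, kernel)[:n]
    return out


def _draw_amps(rng: np.random.Generator, k: int, params: EphysSimParams) -> np.ndarray:
    a = rng.normal(params.amp_mean_pA, params.amp_sd_pA, size=k)
    return np.clip(a, 0.2 * params.amp_mean_pA, None)


def gen_psc_pair(params: EphysSimParams, duration: float = 60.0
                 ) -> tuple[Trace, Trace, np.ndarray, np.ndarray]:
    """Simulate a dual PSC recording.

    A shared event process at rate ``pair_correlation * baseline_rate`` is
    superimposed on two independent processes at the complementary rate, so
    the expected fraction of shared events equals ``pair_correlation``;
    shared events carry the same amplitude in both traces.  Optional bursts
    (shared across the pair) add clustered events on a baseline-elevation
    plateau.  Returns the two traces and the planted event times of each.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(duration * fs))
    kernel = _kernel(params)
    if kernel.size >= n:
        raise ParameterError("event kernel is longer than the trace")
    c = params.pair_correlation
    shared = _dead_time_poisson(rng, c * params.baseline_rate, 0, duration,
                                params.min_separation_s)
    own_a = _dead_time_poisson(rng, (1 - c) * params.baseline_rate, 0, duration,
                               params.min_separation_s)
    own_b = _dead_time_poisson(rng, (1 - c) * params.baseline_rate, 0, duration,
                               params.min_separation_s)
    shared_amps = _draw_amps(rng, len(shared), params)

    plateau = np.zeros(n)
    burst_times_a: list[float] = []
    burst_amps_a: list[float] = []
    if params.burst_spec is not None:
        bs = params.burst_spec
        n_ramp = int(round(bs.ramp_s * fs))
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / max(n_ramp, 1)))
        for b0 in _dead_time_poisson(rng, bs.rate_hz, 1.0,
                                     duration - bs.duration_s - 2 * bs.ramp_s - 1.0,
                                     bs.duration_s + 2 * bs.ramp_s + 0.5):
            i0 = int(round(b0 * fs))
            i1 = min(int(round((b0 + bs.duration_s) * fs)), n)
            plateau[i0:i1] += bs.elevation_pA
            r0 = max(i0 - n_ramp, 0)
            plateau[r0:i0] += bs.elevation_pA * ramp[n_ramp - (i0 - r0):]
            r1 = min(i1 + n_ramp, n)
            plateau[i1:r1] += bs.elevation_pA * ramp[::-1][:r1 - i1]
            # one event per equal slot of the flat top, jittered within the
            # slot, so in-burst events stay resolvable by the detector
            span = bs.duration_s - 0.04
            slot = span / bs.events_per_burst
            ev = (b0 + 0.02 + slot * (np.arange(bs.events_per_burst)
                                      + rng.uniform(0.1, 0.5, bs.events_per_burst)))
            burst_times_a.extend(ev)
            burst_amps_a.extend(_draw_amps(rng, bs.events_per_burst, params))

    def assemble(own: list[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.concatenate((shared, own, burst_times_a))
        a = np.concatenate((shared_amps, _draw_amps(rng, len(own), params),
                            burst_amps_a))
        order = np.argsort(t)
        return t[order], a[order], _render(t[order], a[order], kernel, n, fs) + plateau

    ta, aa, sig_a = assemble(own_a)
    tb, ab, sig_b = assemble(own_b)
    if params.noise_sd > 0:
        sig_a = sig_a + rng.normal(0, params.noise_sd, n)
        sig_b = sig_b + rng.normal(0, params.noise_sd, n)
    sgn = -1.0 if params.polarity == "negative" else 1.0
    dt = 1.0 / fs
    tr_a = Trace(sgn * sig_a, dt, meta={"id": "cell_a", "units": "pA"})
    tr_b = Trace(sgn * sig_b, dt, meta={"id": "cell_b", "units": "pA"})
    return tr_a, tr_b, ta, tb


def gen_spike_trace(params: EphysSimParams, duration: float = 180.0,
                    drug_window: tuple[float, float] = (60.0, 90.0)
                    ) -> tuple[Trace, np.ndarray]:
    """Cell-attached spike trace with a drug-response epoch.

    The firing rate is ``baseline_rate`` outside ``drug_window`` and
    ``baseline_rate * drug_multiplier`` inside it.  Returns the trace and the
    planted spike times.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(duration * fs))
    r = params.baseline_rate
    segs = [(0.0, drug_window[0], r),
            (drug_window[0], drug_window[1], r * params.drug_multiplier),
            (drug_window[1], duration, r)]
    times: list[float] = []
    for t0, t1, rate in segs:
        times.extend(_dead_time_poisson(rng, rate, t0, t1, params.min_separation_s))
    times_arr = np.asarray(sorted(times))
    amps = _draw_amps(rng, times_arr.size, params)
    # short biphasic spike kernel
    spike = replace(params, rise_ms=0.5, decay_ms=2.0)
    sig = _render(times_arr, amps, _kernel(spike), n, fs)
    if params.noise_sd > 0:
        sig = sig + rng.normal(0, params.noise_sd, n)
    sgn = -1.0 if params.polarity == "negative" else 1.0
    return Trace(sgn * sig, 1.0 / fs, meta={"units": "pA"}), times_arr


# ---------------------------------------------------------------------------
# single-channel I/V
# ---------------------------------------------------------------------------

@dataclass
class IVSimParams:
    """Single-channel I/V conditions.

    ``reversal_potential`` is the ground-truth zero-current abscissa in the
    -Vp convention (i.e. the true DF_GABA).  Default potentials span -100 to
    +60 mV in 10 mV steps with 20 openings per potential, the recording
    protocol the estimator assumes.
    """

    reversal_potential: float = -10.0
    slope_conductance_pS: float = 20.0
    potentials: tuple[float, ...] = tuple(range(-100, 70, 10))
    openings_per_potential: int = 20
    current_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.potentials)) < 3:
            raise ParameterError("need at least 3 distinct potentials")
        if self.openings_per_potential < 1:
            raise ParameterError("openings_per_potential must be >= 1")


def gen_iv_dataset(params: IVSimParams) -> IVDataset:
    """Simulate a single-channel I/V table.

    The mean open-channel current at potential V is
    ``g * (V - V_rev) / 1000`` pA (g in pS, V in mV) plus the mean of
    per-opening Gaussian noise.
    """
    rng = np.random.default_rng(params.seed)
    v = np.asarray(params.potentials, dtype=float)
    g_pa_per_mv = params.slope_conductance_pS * 1e-3
    means = np.empty(v.size)
    for i, vi in enumerate(v):
        true_i = g_pa_per_mv * (vi - params.reversal_potential)
        openings = true_i + rng.normal(0, params.current_noise_sd,
                                       size=params.openings_per_potential) \
            if params.current_noise_sd > 0 else np.full(params.openings_per_potential, true_i)
        means[i] = openings.mean()
    return IVDataset(v, means, np.full(v.size, params.openings_per_potential))


# ---------------------------------------------------------------------------
# LTD slope series
# ---------------------------------------------------------------------------

def gen_ltd_series(baseline_slope: float = 0.20, early_level: float = 0.5218,
                   late_level: float = 0.7783, noise_sd: float = 0.05,
                   seed: int = 0, t_start: float = -10.0, t_end: float = 60.0,
                   sweeps_per_min: float = 1.8) -> SlopeSeries:
    """Simulate an fEPSP slope time course around DHPG-induced LTD.

    Times are minutes relative to DHPG washout.  The underlying profile is 1
    during the baseline (t < 0), ``early_level`` from washout through the end
    of the early window (25 min), a linear recovery to ``late_level`` by the
    start of the late window (50 min) and ``late_level`` thereafter, so at
    zero noise the window means equal the configured levels exactly.
    ``noise_sd`` is the SD of multiplicative sweep-to-sweep noise.  Default
    depression levels are typical of wild-type DHPG-LTD (early ~52 %, late
    ~78 % of baseline).
    """
    if early_level <= 0 or late_level <= 0 or baseline_slope <= 0:
        raise ParameterError("levels and baseline slope must be positive")
    if t_start >= 0 or t_end < 55.0:
        raise ParameterError("series must cover the baseline and both "
                             "LTD windows (t_start < 0, t_end >= 55)")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sweeps_per_min
    times = np.arange(t_start, t_end, dt)
    profile = np.where(times < 0, 1.0,
                       np.where(times <= 25.0, early_level,
                                np.where(times >= 50.0, late_level,
                                         early_level + (late_level - early_level)
                                         * (times - 25.0) / 25.0)))
    slopes = baseline_slope * profile
    if noise_sd > 0:
        slopes = slopes * (1.0 + rng.normal(0, noise_sd, size=times.size))
    return SlopeSeries(times, slopes)
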