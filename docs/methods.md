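# Methods

This document records the analysis model, the rationale behind each default
parameter, the scope of the synthetic-data generators, and known
limitations. Function-level behavior is documented in the docstrings; this
file explains the *choices*.

## 1. Breathing-cycle analysis (`breath`)

### Trinarization

A plethysmography signal `s(t)` is mapped frame-wise to

```
b(t) = +1  if s(t) >  0.15
       -1  if s(t) < -0.4
        0  otherwise
```

Inequalities are strict: samples exactly at +0.15 or −0.4 map to 0. The
asymmetric thresholds reflect asymmetric inspiration/expiration deflection
amplitudes in whole-body plethysmography; both are configurable
(`upper`, `lower`).

### Smoothing and re-trinarization

The trinary series is smoothed with a 25-frame *centered* moving average.
At the edges the window is truncated to the available frames (the mean is
over actual frames, not zero-padded), which keeps the first and last frames
well defined without inventing data. The smoothed value is re-trinarized
with sign; magnitudes below `1e-12` are treated as exact zeros so that
balanced windows (equal +1 and −1 content) deterministically map to 0
despite floating-point summation.

### Cycles and inter-cycle intervals

A cycle onset is the first frame of a maximal run of +1 (positive onsets)
or −1 (negative onsets). An ICI is `dt * (p[i+1] - p[i])` for consecutive
positive onsets with **at least one negative onset strictly between
them** — this guards against double-counted positive deflections that lack
an intervening expiration. `use_negative=True` applies the mirrored rule to
negative onsets. The empirical CDF is reported over unique interval values.

## 2. Group discrimination (`groupdisc`)

### Cliff's Delta

For samples `a`, `b`: `delta = (#{x>y} - #{x<y}) / (|a||b|)`. The
implementation sorts one sample and uses binary search
(`O((m+n) log n)`), and is tested to equal brute-force enumeration
*exactly*, including ties. `|delta|` is the per-pair distance.

### Clustering

Animals are rows of the |Delta| matrix; rows are compared by cosine
distance (scale-free: what matters is the *pattern* of separations, not its
magnitude) and joined by average linkage (default; complete, single and
ward are available — ward operates on unit-normalized row embeddings since
it requires Euclidean geometry). The tree is cut at `k = 3` clusters to
mirror the three nominal experimental groups.

### Effective clusters

Cutting at k = 3 always yields 3 populated clusters even when only 2 are
genuinely separated. `effective_clusters` chooses the cut by the largest
*multiplicative* gap between consecutive dendrogram merge heights (with a
small floor to ignore numerically-zero merges). A ratio criterion is
scale-invariant, consistent with the cosine geometry. This is a heuristic:
it assumes one dominant separation scale, which holds for the study design
(two well-separated phenotypes) but is not a general-purpose cluster-number
estimator.

### Significance

If `c` of a group's `n` animals land in the group's majority cluster, the
p-value is the exact binomial tail `P(X >= c)` with success probability
`1/3` (random assignment into 3 clusters), i.e. `binom.sf(c-1, n, 1/3)`.
This matches a label-randomization test in expectation and is validated
against Monte-Carlo randomization in the acceptance suite. It treats
cluster assignment as independent across animals, which is conservative in
the balanced designs used here.

## 3. Event analysis (`events`)

### Detection

The trace is median-centered and polarity-rectified. The threshold is
`3 x noise_sd`, with `noise_sd` estimated from an event-free window (or
supplied). Detection runs on a lightly smoothed copy (2 ms boxcar) so that
single noise excursions cannot cross threshold, while amplitudes and
charges are always measured on the raw trace. An event extends until the
detection signal falls below half threshold; a refractory re-arm (5 ms
default) prevents double counting. For traces with burst plateaus,
`detrend=0.2` subtracts a 200 ms running median first so within-burst
events are measured against the local plateau, not the global baseline.

### Drug effects and washout

`drug_effect` is the event-frequency ratio drug/baseline over
user-supplied disjoint windows. A recording passes washout QC only if the
washout-window frequency is within ±20% of baseline (`washout_tol=0.20`);
failures are flagged, not silently dropped.

### Bursts

The rectified trace is filtered with a 200 ms running median; epochs where
this exceeds the quiescent level by ≥60 pA (gap-closing at 50 ms to bridge
noise-induced fragmentation) and containing ≥3 detected events are bursts.
Charge, peak amplitude, duration and within-burst charge density are
reported per burst.

### QC

Whole-cell recordings are excluded when the holding current at −70 mV is
more negative than −30 pA (P0) or −40 pA (P15), or when holding current or
input resistance drifted by more than 15% during the recording. Exactly
one (the first triggered) exclusion reason is recorded.

## 4. Biophysics (`biophys`)

### DF_GABA

Cell-attached single-channel currents are fitted against pipette-potential
abscissa. In the `minus_vp` convention the fitted zero-current abscissa
**is** the GABA driving force; the `vp` convention negates it. A linear
model is the default; a quadratic option handles mild rectification (the
root nearest the sampled-range midpoint is taken). Fits extrapolating more
than 20 mV beyond the sampled range are flagged, as are potentials with
fewer than 20 channel openings (unreliable means).

### fEPSP slope and LTD

The slope is a least-squares line over the samples whose deviation from
baseline lies between 30% and 70% of the peak deviation, on the rising
phase only, in units per millisecond. Slope series are normalized to the
mean of the final 10 min before washout (= 100%). LTD is summarized as the
mean ± SEM of normalized slopes in the 20–25 min (early) and 50–55 min
(late) post-washout windows; a series not covering both windows is
rejected rather than silently truncated.

## 5. Synthetic data (`synthdata`)

Generators exist to provide *planted ground truth*, not to be
physiologically complete.

- **Breathing**: ICIs are log-normal (wild-type median 0.30 s, sigma 0.20;
  both Mecp2-like groups share 0.45 s / 0.35 — emulating a treatment that
  does not change breathing). Cycles are half-sine positive/negative lobe
  pairs at 1 kHz. Planted onsets are frame-quantized and the ground-truth
  onsets are expressed in the *analysis* convention (computed by
  independent window-sum arithmetic on the cycle template), so zero-noise
  recovery is exact by construction of the convention, not by tuning.
- **PSCs**: dead-time Poisson event times (50 ms minimum separation),
  double-exponential kernels (2 ms rise / 10 ms decay), amplitudes
  30 ± 8 pA. Pairs share a common event process whose rate fraction equals
  the requested correlation; shared events carry identical amplitudes.
  Bursts place one jittered event per equal slot of a raised-cosine-ramped
  plateau — ramps are used because step edges would register as spurious
  events, and slots guarantee in-burst events stay resolvable.
- **I/V**: linear single-channel relation with per-potential Gaussian noise
  scaled by 1/sqrt(openings).
- **LTD**: piecewise level profile (100% baseline, early level to 25 min,
  linear recovery to the late level by 50 min) plus optional noise. The
  default early/late levels (52.18% / 77.83%) are typical published
  wild-type DHPG-LTD magnitudes used as plausible defaults.

All generators draw from `numpy.random.default_rng` with per-animal
substreams `[seed, index]`, so cohorts are bit-identical under a fixed seed
and adding animals does not perturb existing ones.

## 6. Numerical choices

- Exact-equality guarantees (trinarization boundaries, Cliff's Delta vs
  enumeration, zero-noise recovery) are tested as exact, not approximate.
- The smoothing zero tolerance (1e-12) only absorbs float summation error;
  it is far below 1/25, the smallest nonzero window mean.
- Binomial tails use `scipy.stats.binom.sf` (exact, not normal
  approximation).
- Linear fits use closed-form least squares (`polyfit` / `linregress`);
  the noiseless I/V reversal recovers to ~1e-14 mV (float round-off), so
  "machine precision" tests use `abs tol 1e-8`.

## 7. Limitations

- The effective-cluster heuristic assumes one dominant separation scale.
- Burst detection at exactly the 60 pA elevation boundary is noise-marginal
  by definition; exact-boundary behavior is specified (and tested) at zero
  noise.
- EDF files can be read (optional `mne` dependency) but not written; all
  outputs are CSV/JSON.
- The generators do not model breathing apneas' full temporal structure,
  PSC kinetic variability, or channel gating; they are fixtures for
  validating the analysis code.
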