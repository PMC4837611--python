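# Methods

`gaitmatch` detects heel-strike events in short (~5 m) episodes of straight
walking from a single axis of acceleration — the anterior-posterior (AP)
component — recorded either at the lower back (L5) or at both heels, at
100 samples/s.  It also implements an optoelectronic reference method and
the statistics used to compare step durations between methods.  This note
describes the model behind each stage, the tunable constants, the synthetic
data the package is validated on, and the numerical choices made where the
design was genuinely open.

## The template-match detector

Walking is treated as a cyclo-stationary process: the AP trunk acceleration
repeats once per *step* (each heel strike, left or right, produces a
similar trunk pulse), while a heel acceleration repeats once per *stride*
(a heel only strikes once per gait cycle).  The detector estimates the
cycle length, builds an episode-specific average waveform of one cycle (the
*template*), and then finds every interval of the episode that matches the
template.  All algorithm constants scale with the template length TL, so
the method adapts to each subject's cadence.

### Template length (TL)

The unbiased autocovariance of the manually segmented episode is computed
over non-negative lags,

    c(k) = (1 / (n - k)) * sum_t (x_t - mean)(x_{t+k} - mean),

the per-lag normalization compensating the shrinking number of products at
long lags.  For the lower back, TL = round(fs / f_dom), where f_dom is the
dominant frequency of the positive-lag autocovariance.  f_dom is extracted
as the argmax of the magnitude spectrum of c(k), zero-padded to a 0.01 Hz
grid and restricted to a physiologic cadence band of 0.3–5 Hz (both
configurable); the extraction mechanism is a design choice of this package.
Aperiodic input is rejected before extraction: a periodic signal keeps a
normalized autocovariance above `min_periodicity` (default 0.2) at some lag
beyond the shortest period in the band, whereas for white noise c(k)/c(0)
decays like 1/sqrt(n−k).

For a heel, TL is the lag of the first interior peak of the normalized,
low-pass-filtered autocovariance that exceeds 0.5 (lag 0 counts as the
first peak).  The low-pass cutoff is twice f_dom; the filter is a
zero-phase (forward–backward) second-order Butterworth — the filter family
and order are this package's choice, only the cutoff is prescribed by the
method.  Normalization is applied before filtering.

### Template construction

Anchor peaks are local maxima of the signed AP signal inside the interior
`[round(1.15·TL), n − round(1.15·TL))`, admitted greedily in descending
amplitude under a minimum mutual distance of `round(0.40·TL)` samples
(ties break toward the earlier index).  Admission is additionally capped
at `floor(interior/TL)` peaks (at least 2): peaks anchor gait cycles and a
window of known cycle length cannot hold more cycles than fit in it.
Without the cap, the thresholdless spacing rule admits one low-amplitude
noise maximum between every pair of true cycle peaks — and near the
interior edges, where the suppressing neighbour peak has been trimmed away
— which pollutes the averaged template badly.  The cap is deliberately a
*count*, not an amplitude threshold, so it preserves the detector's exact
invariance to adding a constant to, or rescaling, the trace.

One section per anchor is cut, from `round(pre·TL)` samples before the
peak (pre = 0.15 for the lower back, 0.05 for a heel, capturing the slope
that precedes the peak) to TL samples after it.  Sections are reduced to a
single template by hierarchical dynamic-time-warping averaging: consecutive
pairs are DTW-aligned (absolute-difference local cost, symmetric unweighted
steps {(1,0),(0,1),(1,1)}, endpoints pinned, no window), the aligned
samples averaged along the path and linearly resampled back to the first
section's length; the list halves each round, an odd leftover is carried
unchanged, until one signal remains.

The final average is `pre + TL` samples long but the template must have
exactly TL samples.  Two fits are offered (`template_fit`): **truncate**
(default) keeps the first TL samples, so the template window starts exactly
`pre` samples before the anchor and the event shift below lands events on
the cycle peaks; **resample** linearly compresses the average onto TL
samples.  Truncation is the default because resampling compresses the
template's time base by TL/(pre+TL) (13 % for the lower back), which biases
detected heel events by up to ~10 samples on clean synthetic data.

DTW backtracking prefers the diagonal, then the vertical step; tie
comparisons carry a 1e-9 relative tolerance.  Minimum-cost warping paths
are frequently near-degenerate, and without the tolerance the chosen path —
and hence the average — can flip under floating-point-level perturbations
as small as adding a constant to the trace.

### Matching and event selection

The raw trace is *resegmented*: the manual segmentation is extended by TL
samples to the left and 2·TL to the right, so the first and last cycles can
be matched by full windows.  Over every TL-sample sliding window two
similarity signals are computed and each divided by its maximum:

- **SD-difference**: the population standard deviation of
  (window − template); zero where the window equals the template up to a
  constant offset, so its minima mark match starts.
- **Correlation**: the Pearson correlation of window and template,
  multiplied by the symmetric range ratio r = min(ρ, 1/ρ) with
  ρ = range(window)/range(template).  The ratio penalizes shape matches at
  the wrong amplitude, symmetrically for too-small and too-large windows.
  Whether the published method applied the ratio per window or globally is
  ambiguous; per-window symmetric is the default, with `per_window_raw`
  and `global` selectable (`range_ratio`).  Constant windows get
  correlation 0.

Their ratio, the **coefficient signal**
`corr / max(sd, ε)` with ε = 1e-3 (`coefficient_eps`), peaks at the start
of each matched cycle; the floor keeps near-perfect matches finite while
leaving them the global maxima.

Events are the selected coefficient peaks shifted forward by
`round(pre·TL)` samples.  Selection: local maxima with positive
coefficient (an anticorrelated window is not a match), whose shifted event
lands inside the original segmentation, admitted greedily by descending
value under a minimum spacing of `round(0.60·TL)` (spacing exactly equal
to the minimum is allowed), capped at `floor(len(segment)/TL) + 1` events.
Finally, selected peaks whose normalized correlation falls below
`event_rel_floor` (default 0.25) times the median over the selected set
are discarded: a genuine match resembles the template comparably to the
other matches in the episode, and the few samples of the segment edges not
covered by the spacing constraint would otherwise admit arbitrarily weak
noise maxima.  The floor is applied to the correlation signal rather than
the coefficient because the coefficient's scale blows up wherever the
SD-difference hits ε.  All three guards (positivity, count cap, relative
floor) are invariant to offset and scale of the trace.

Events are integer sample indices; no sub-sample interpolation is
attempted, so timing resolution is half a sample period on average.
Step durations are the intervals between consecutive events (lower back:
undifferentiated steps; the method cannot tell left from right).  For
heels, each foot yields stride events; the two series are merged and must
strictly alternate feet, giving step durations from the combined series.

## Marker-based reference

Marker trajectories (200 samples/s) are first resampled to 100 samples/s —
by plain decimation by default, which preserves measured values; linear
interpolation is available for non-integer ratios.  Visibility is
evaluated in 40-sample intervals centred on the heel-acceleration events;
from the candidate markers per body site the one with the most completely
visible intervals is selected (ties to the lowest marker id).  For each
interval in which both the heel and the lower-back marker are fully
visible, the heel strike is the sample maximizing the signed AP distance
heel − back (earliest sample on ties; the sign is configurable).
Incomplete intervals yield no event and are reported as missed.

## Comparing methods

Two event series over the same episode are paired by order.  Where the
reference missed event k, the step pairs (k−1,k) and (k,k+1) are replaced
by one **stride** pair (k−1,k+1) in both series; gaps spanning two or more
consecutive missed events are excluded with a warning.  Per-pair absolute
differences are summarized as mean ± SD in ms and as a percentage of the
average step duration of both systems; stride-fallback entries enter that
denominator as duration/2 so it remains an average *step* duration.
Aggregation across trials averages within trial first, then across trials.

Agreement uses ICC(2,1) — two-way random effects, absolute agreement,
single measures — computed from the ANOVA mean squares of the n×2 table
(this form, rather than consistency ICC, because a systematic offset
between two measurement systems should count as disagreement).  Systematic
bias is tested with a paired t-test when the Shapiro–Wilk test does not
reject normality of the paired differences at α = 0.05, and a Wilcoxon
signed-rank test otherwise; Shapiro–Wilk, t and Wilcoxon are delegated to
scipy.stats.  Identical vectors are reported under a zero-variance
convention with p = 1.

## Synthetic gait generator

No recordings ship with the package; `synthetic_gait` generates episodes
whose heel-strike instants are known exactly, which is the quantity the
detector is judged on.  The waveforms are parametric idealizations, not
biomechanical simulations.

- **Timing**: `n_steps` heel strikes (one detected event per step, so
  n_steps − 1 step durations); per-step durations are normal, truncated at
  ±3 SD, with mean 560 ms, CV `step_cv`, and a left/right mean offset of
  `asymmetry · mean` (strides stay at twice the mean).  The 560 ms default
  matches the cadence scale of healthy older adults walking short
  distances.
- **Lower back**: one biphasic pulse per strike — a raised-cosine positive
  lobe (half-width 0.12 step) peaking exactly at the strike and a shallow
  trailing negative lobe — with amplitude alternating ±10 % by side,
  riding on a step-frequency fundamental (amplitude 0.35) whose phase is
  pinned to the actual strike instants, plus an 0.08 second harmonic.
- **Heel**: per own-side strike a sharp impact spike (raised cosine,
  25 ms half-width), a rapidly damped 5 Hz oscillation, a small mid-swing
  bump, and a stride-frequency fundamental (amplitude 0.5) locked to the
  own-side strikes.
- The shape constants are chosen so each cycle has exactly **one** local
  maximum, at the heel strike.  Real trunk and heel AP signals satisfy
  this dominance property, and the published peak-admission rule depends
  on it (it has no amplitude criterion).
- **Noise**: additive white Gaussian, SD = `noise_sd` × the clean
  waveform's peak.  `noise_sd_for_snr_db` converts a target RMS
  signal-to-noise ratio into this parameter.
- **Markers**: the back marker advances piecewise-linearly through the
  strike positions (600 mm per step), extended one virtual step beyond
  each end because the trunk is already moving at the first strike and
  keeps moving after the last; each heel marker holds its stance position
  for 60 % of the stride and swings forward with a quadratic ease (zero
  lift-off velocity, high touch-down velocity), so the AP heel−back
  distance has a sharp maximum exactly at each own-side strike, preserved
  under decimation because strikes fall on shared sample instants.
  Heel markers suffer independent per-sample dropouts at rate
  `marker_dropout` (0.00116 per sample leaves ≈ 8.9 % of 40-sample
  intervals incomplete); the trunk marker stays visible, as it is rarely
  occluded in practice.  Gaussian position noise of 0.3 mm is far below
  the ~10 mm/sample slope of the AP distance around a strike, so argmax
  timing is unaffected.
- Episodes place the manual segmentation a few samples (0.08 step) around
  the heel-strike span, as the protocol's "some samples before the first
  heel-strike" suggests, and leave a generous lead-in/tail so
  resegmentation never runs out of raw signal.

What the generator does *not* emulate: turning or stopping, gait
initiation transients (the first real step differs in shape from the
rest), soft-tissue artefacts, sensor drift, axis cross-talk, or
non-stationary cadence.  Passing the synthetic suite therefore shows the
pipeline implements the method correctly and is robust to timing jitter
and additive noise — it does not certify accuracy on recorded data.

The validation suite uses episodes of 10–12 heel strikes.  Shorter
episodes (≤ 9 strikes) cannot support the heel pipeline at all: trimming
1.15 stride-lengths from each end of the segmented signal leaves fewer
than two same-foot spikes to anchor the template, and the pipeline
correctly raises a too-few-cycles error.

## Numerical conventions and degenerate inputs

- Indices are 0-based; windows are half-open [start, end).
- All "fraction of TL" quantities round half away from zero with a floor
  of one sample; an epsilon of 1e-9 absorbs binary floating-point error in
  products like 1.15 × 50.
- Local maxima are strict (greater than both neighbours); plateaus yield
  no candidate.
- Constant traces, white noise, and episodes shorter than three cycles
  raise typed errors (`DegenerateSignalError`, `PeriodicityNotFoundError`,
  `TooShortEpisodeError`, ...) tagged with the pipeline stage that failed.
- Single-pair comparisons report no SD; ICC requires at least 3 pairs and
  non-zero total variance.

## Problem sizes

The test suite validates detection on 200 seeded episodes per noise level
(clean and 10 dB SNR) of 10–12 steps each, reference recovery on 15–25
episodes, and statistics on 1000 replicates of n = 20; the acceptance
script emulates 20 subjects × 2 episodes.  Both complete in a few seconds
on one CPU.
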