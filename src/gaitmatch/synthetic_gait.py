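"""Synthetic gait signals with known heel-strike ground truth.

Short straight-walking episodes are emulated at the level that matters for
event timing: a lower-back AP acceleration that repeats once per *step*
(stereotyped biphasic pulse at each heel strike, alternating slightly in
amplitude between sides, plus a weak second harmonic), heel AP
accelerations that repeat once per *stride* (sharp impact spike at each
own-side strike, damped oscillation, mid-swing bump), and optoelectronic
marker trajectories whose anterior-posterior heel-minus-back distance is
maximal exactly at each heel strike.  The waveform shapes are parametric
idealizations, not biomechanical simulations; what they encode exactly is
the timing of the heel strikes, which is the quantity the detection
pipeline is judged on.

All randomness (step-duration variability, sensor noise, marker dropouts)
flows from the single seed in :class:`GaitParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import round_half_away
from .signal_model import AccelerationTrace, EventSeries, MarkerTrace, SegmentWindow

#: trace layout, in units of the mean step duration
LEAD_STEPS = 2.6  # quiet lead-in before the first heel strike
TAIL_STEPS = 4.8  # quiet tail after the last heel strike (room to resegment)
SEGMENT_MARGIN_STEPS = 0.08  # manual segmentation margin around the episode

#: lower-back pulse shape (fractions of the mean step duration)
LB_POS_HALFWIDTH = 0.12
LB_NEG_WIDTH = 0.18
LB_NEG_AMP = 0.12
LB_SIDE_AMP = 0.10  # left/right amplitude alternation
LB_FUND_AMP = 0.35  # step-frequency fundamental (trunk sway), strike-locked
LB_HARMONIC_AMP = 0.08

#: heel waveform shape
HEEL_SPIKE_RISE_S = 0.025  # impact spike half-width (s); rise < 30 ms
HEEL_OSC_AMP = 0.15
HEEL_OSC_FREQ_HZ = 5.0
HEEL_OSC_TAU_S = 0.03
HEEL_BUMP_AMP = 0.10
HEEL_BUMP_CENTER = 0.70  # of the stride
HEEL_BUMP_HALFWIDTH = 0.08
HEEL_FUND_AMP = 0.50  # stride-frequency fundamental, locked to own strikes

#: marker geometry (mm) and gait kinematics
STEP_LENGTH_MM = 600.0
STANCE_FRACTION = 0.6


@dataclass
class GaitParams:
    """Conditions of one synthetic gait episode.

    ``n_steps`` is the number of heel strikes in the episode (one detected
    event per step), so the episode yields ``n_steps - 1`` step durations.
    ``noise_sd`` is the additive Gaussian noise SD as a fraction of the
    clean waveform's peak amplitude.
    """

    n_steps: int = 10
    mean_step_ms: float = 560.0
    step_cv: float = 0.02
    asymmetry: float = 0.02
    noise_sd: float = 0.05
    fs: float = 100.0
    marker_fs: float = 200.0
    marker_dropout: float = 0.0
    marker_noise_mm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 4:
            raise ValueError(f"n_steps must be >= 4, got {self.n_steps}")
        if self.mean_step_ms <= 200:
            raise ValueError(f"mean_step_ms must exceed 200 ms, got {self.mean_step_ms}")
        if not 0 <= self.step_cv < 0.2:
            raise ValueError(f"step_cv must be in [0, 0.2), got {self.step_cv}")
        if not 0 <= self.asymmetry < 0.5:
            raise ValueError(f"asymmetry must be in [0, 0.5), got {self.asymmetry}")
        if self.noise_sd < 0 or self.fs <= 0 or self.marker_fs <= 0:
            raise ValueError("noise_sd must be >= 0 and rates positive")
        if not 0 <= self.marker_dropout <= 1:
            raise ValueError("marker_dropout must be in [0, 1]")

    @property
    def step_samples(self) -> float:
        return self.mean_step_ms * self.fs / 1000.0


@dataclass
class SyntheticTrial:
    """One generated episode with its ground truth."""

    lowback: AccelerationTrace
    heel_left: AccelerationTrace
    heel_right: AccelerationTrace
    markers: dict[str, MarkerTrace]
    truth_left: np.ndarray
    truth_right: np.ndarray
    truth_all: np.ndarray
    truth_durations_ms: np.ndarray  # continuous drawn step durations
    params: GaitParams

    @property
    def segment_window(self) -> SegmentWindow:
        """Manual segmentation: a few samples around the heel-strike span."""
        margin = max(3, round_half_away(SEGMENT_MARGIN_STEPS * self.params.step_samples))
        return SegmentWindow(int(self.truth_all[0]) - margin, int(self.truth_all[-1]) + margin + 1)

    def truth_events(self, which: str = "all") -> EventSeries:
        truth = {"all": self.truth_all, "left": self.truth_left, "right": self.truth_right}[which]
        return EventSeries(events=truth, method="ground_truth", fs=self.params.fs)

    @property
    def truth_step_durations_samples_ms(self) -> np.ndarray:
        """Step durations implied by the sample-quantized heel strikes."""
        return np.diff(self.truth_all) * 1000.0 / self.params.fs


def _draw_step_durations(params: GaitParams, rng: np.random.Generator) -> np.ndarray:
    """Per-step durations (ms): normal, truncated at +/- 3 SD, by side.

    The step ending at a left-foot strike has mean ``mean*(1+asym/2)``, the
    one ending at a right-foot strike ``mean*(1-asym/2)``; strides (one left
    plus one right step) stay at twice the mean.
    """
    n_int = params.n_steps - 1
    # strike i is left for even i; interval k ends at strike k+1
    ends_left = (np.arange(1, params.n_steps) % 2) == 0
    means = params.mean_step_ms * np.where(
        ends_left, 1.0 + params.asymmetry / 2.0, 1.0 - params.asymmetry / 2.0
    )
    if params.step_cv == 0.0:
        return means
    scale = params.step_cv * params.mean_step_ms
    draws = stats.truncnorm.rvs(-3.0, 3.0, size=n_int, random_state=rng)
    return means + scale * draws


def _strike_indices(params: GaitParams, durations_ms: np.ndarray) -> np.ndarray:
    t0 = round_half_away(LEAD_STEPS * params.step_samples)
    offsets = np.concatenate([[0.0], np.cumsum(durations_ms)]) * params.fs / 1000.0
    return t0 + np.array([round_half_away(o) for o in offsets], dtype=int)


def _trace_length(params: GaitParams, truth_all: np.ndarray) -> int:
    return int(truth_all[-1]) + round_half_away(TAIL_STEPS * params.step_samples) + 1


def lowback_waveform(
    truth_all: np.ndarray,
    params: GaitParams,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> AccelerationTrace:
    """Step-periodic lower-back AP acceleration with known strike instants.

    One asymmetric biphasic pulse per heel strike (raised-cosine positive
    lobe peaking exactly at the strike, trailing negative lobe), amplitude
    alternating +/-10 % between sides, riding on a strike-locked
    step-frequency fundamental (trunk sway) with a low-amplitude second
    harmonic, plus additive Gaussian noise.  The fundamental's phase is
    pinned to the actual strike instants, so its maxima coincide with the
    pulse peaks even under step-duration variability.
    """
    truth_all = np.asarray(truth_all, dtype=int)
    if n_samples is None:
        n_samples = _trace_length(params, truth_all)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x = np.zeros(n_samples)
    w1 = max(2, round_half_away(LB_POS_HALFWIDTH * params.step_samples))
    w2 = max(2, round_half_away(LB_NEG_WIDTH * params.step_samples))
    rel = np.arange(-w1, w1 + w2 + 1)
    pos = np.where(np.abs(rel) <= w1, np.cos(np.pi * rel / (2.0 * w1)) ** 2, 0.0)
    neg_mask = (rel >= w1) & (rel <= w1 + w2)
    neg = np.where(neg_mask, -LB_NEG_AMP * np.sin(np.pi * (rel - w1) / w2) ** 2, 0.0)
    pulse = pos + neg
    for i, c in enumerate(truth_all):
        amp = 1.0 + LB_SIDE_AMP if i % 2 == 0 else 1.0 - LB_SIDE_AMP
        lo, hi = c - w1, c + w1 + w2 + 1
        plo, phi = max(0, -lo), len(rel) - max(0, hi - n_samples)
        x[max(lo, 0) : min(hi, n_samples)] += amp * pulse[plo:phi]
    # strike-locked phase: 2*pi*k at strike k, linearly interpolated, with a
    # one-step linear fade outside the walking span; virtual strikes one step
    # beyond each end keep the phase advancing there
    idx = np.arange(n_samples, dtype=float)
    step = params.step_samples
    knots_t = np.concatenate([[truth_all[0] - step], truth_all, [truth_all[-1] + step]])
    knots_k = np.arange(-1, truth_all.size + 1, dtype=float)
    phase = 2.0 * np.pi * np.interp(idx, knots_t, knots_k)
    outside = np.maximum(truth_all[0] - idx, idx - truth_all[-1])
    envelope = np.clip(1.0 - outside / step, 0.0, 1.0)
    x += envelope * (LB_FUND_AMP * np.cos(phase) + LB_HARMONIC_AMP * np.sin(2.0 * phase))
    peak = np.max(np.abs(x))
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd * peak, n_samples)
    return AccelerationTrace(samples=x, fs=params.fs, placement="lower_back")


def heel_waveform(
    truth_side: np.ndarray,
    params: GaitParams,
    side: str,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> AccelerationTrace:
    """Stride-periodic heel AP acceleration for one foot.

    A sharp impact spike (raised cosine, < 30 ms rise) peaks exactly at
    each own-side heel strike, followed by a damped oscillation and a
    low-amplitude mid-swing bump, riding on a stride-frequency fundamental
    locked to the own-side strikes (the broad stride-periodic structure
    real heel signals carry); noise as configured.
    """
    truth_side = np.asarray(truth_side, dtype=int)
    if n_samples is None:
        ref_last = truth_side[-1] + round_half_away(params.step_samples)
        n_samples = ref_last + round_half_away(TAIL_STEPS * params.step_samples) + 1
    if rng is None:
        rng = np.random.default_rng(params.seed)
    stride = 2.0 * params.step_samples
    r = max(2, round_half_away(HEEL_SPIKE_RISE_S * params.fs))
    osc_len = round_half_away(0.35 * stride)
    bump_c = round_half_away(HEEL_BUMP_CENTER * stride)
    bump_hw = max(2, round_half_away(HEEL_BUMP_HALFWIDTH * stride))
    rel = np.arange(-r, bump_c + bump_hw + 1)
    shape = np.zeros(rel.size)
    spike = np.abs(rel) <= r
    shape[spike] = np.cos(np.pi * rel[spike] / (2.0 * r)) ** 2
    osc = (rel > r) & (rel <= r + osc_len)
    dt = (rel[osc] - r) / params.fs
    shape[osc] += (
        -HEEL_OSC_AMP * np.exp(-dt / HEEL_OSC_TAU_S) * np.sin(2.0 * np.pi * HEEL_OSC_FREQ_HZ * dt)
    )
    bump = np.abs(rel - bump_c) <= bump_hw
    shape[bump] += HEEL_BUMP_AMP * np.cos(np.pi * (rel[bump] - bump_c) / (2.0 * bump_hw)) ** 2
    x = np.zeros(n_samples)
    for c in truth_side:
        lo, hi = c - r, c - r + rel.size
        plo, phi = max(0, -lo), rel.size - max(0, hi - n_samples)
        x[max(lo, 0) : min(hi, n_samples)] += shape[plo:phi]
    # stride-frequency fundamental, phase-locked so its maxima coincide with
    # the impact spikes; linear fade over one stride outside the span, with
    # virtual strikes one stride beyond each end keeping the phase advancing
    idx = np.arange(n_samples, dtype=float)
    knots_t = np.concatenate([[truth_side[0] - stride], truth_side, [truth_side[-1] + stride]])
    knots_k = np.arange(-1, truth_side.size + 1, dtype=float)
    phase = 2.0 * np.pi * np.interp(idx, knots_t, knots_k)
    outside = np.maximum(truth_side[0] - idx, idx - truth_side[-1])
    envelope = np.clip(1.0 - outside / stride, 0.0, 1.0)
    x += envelope * HEEL_FUND_AMP * np.cos(phase)
    peak = np.max(np.abs(x))
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd * peak, n_samples)
    placement = "heel_left" if side == "left" else "heel_right"
    return AccelerationTrace(samples=x, fs=params.fs, placement=placement)


def _foot_trajectory(
    t: np.ndarray, strike_times: np.ndarray, strike_positions: np.ndarray, stride_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """AP position and swing phase (0 during stance) for one foot.

    Stance holds the heel at its planted position for 60 % of the stride;
    swing advances it with a quadratic ease (zero lift-off velocity, high
    touch-down velocity), so the heel-minus-back AP distance has a sharp
    maximum exactly at each own-side strike.
    """
    # virtual pre-episode strike one stride earlier keeps the first
    # touch-down a real distance maximum
    times = np.concatenate([[strike_times[0] - stride_s], strike_times])
    pos = np.concatenate([[strike_positions[0] - 2 * STEP_LENGTH_MM], strike_positions])
    x = np.empty_like(t)
    u_out = np.zeros_like(t)
    x[t >= times[-1]] = pos[-1]
    x[t < times[0]] = pos[0]
    for j in range(len(times) - 1):
        t0, t1, x0, x1 = times[j], times[j + 1], pos[j], pos[j + 1]
        mask = (t >= t0) & (t < t1)
        if not mask.any():
            continue
        t_sw = t0 + STANCE_FRACTION * (t1 - t0)
        u = np.clip((t[mask] - t_sw) / (t1 - t_sw), 0.0, 1.0)
        x[mask] = x0 + (x1 - x0) * u**2
        u_out[mask] = u
    return x, u_out


def marker_trajectories(
    truth_left: np.ndarray,
    truth_right: np.ndarray,
    params: GaitParams,
    n_samples_accel: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, MarkerTrace]:
    """Optoelectronic marker set sampled at ``marker_fs``.

    The lower-back marker advances piecewise-linearly between strikes; each
    heel marker alternates stance (fixed) and swing (quadratic advance), so
    its AP distance to the back marker peaks exactly at its own strikes.
    Heel markers suffer independent per-sample dropouts at rate
    ``marker_dropout``; the trunk marker stays visible (it is rarely
    occluded in practice).
    """
    truth_left = np.asarray(truth_left, dtype=int)
    truth_right = np.asarray(truth_right, dtype=int)
    truth_all = np.sort(np.concatenate([truth_left, truth_right]))
    if n_samples_accel is None:
        n_samples_accel = _trace_length(params, truth_all)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_m = int(round(n_samples_accel * params.marker_fs / params.fs))
    t = np.arange(n_m) / params.marker_fs
    # virtual strikes one step beyond each end: the trunk is already moving
    # at the first heel strike and keeps advancing past the last one
    step_s = params.mean_step_ms / 1000.0
    strike_times = np.concatenate(
        [[truth_all[0] / params.fs - step_s], truth_all / params.fs, [truth_all[-1] / params.fs + step_s]]
    )
    strike_pos = STEP_LENGTH_MM * np.arange(-1, truth_all.size + 1)
    back_ap = np.interp(t, strike_times, strike_pos)
    stride_s = 2.0 * params.mean_step_ms / 1000.0

    order = {int(s): i for i, s in enumerate(truth_all)}
    out: dict[str, MarkerTrace] = {}
    for site, truth_side in (("heel_left", truth_left), ("heel_right", truth_right)):
        side_pos = STEP_LENGTH_MM * np.array([order[int(s)] for s in truth_side], dtype=float)
        ap, u = _foot_trajectory(t, truth_side / params.fs, side_pos, stride_s)
        vt = 30.0 + 60.0 * np.sin(np.pi * u) ** 2
        ml = 40.0 if site == "heel_left" else -40.0
        positions = np.column_stack([ap, np.full(n_m, ml), vt])
        positions += rng.normal(0.0, params.marker_noise_mm, positions.shape)
        visible = rng.random(n_m) >= params.marker_dropout
        out[site] = MarkerTrace(
            positions=positions, visible=visible, fs=params.marker_fs, site=site,
            marker_id=f"{site}_M0",
        )
    back_positions = np.column_stack([back_ap, np.zeros(n_m), np.full(n_m, 1000.0)])
    back_positions += rng.normal(0.0, params.marker_noise_mm, back_positions.shape)
    out["lower_back"] = MarkerTrace(
        positions=back_positions, visible=np.ones(n_m, dtype=bool), fs=params.marker_fs,
        site="lower_back", marker_id="lower_back_M0",
    )
    return out


def generate_trial(params: GaitParams) -> SyntheticTrial:
    """Generate one complete synthetic episode (deterministic in the seed)."""
    rng = np.random.default_rng(params.seed)
    durations = _draw_step_durations(params, rng)
    truth_all = _strike_indices(params, durations)
    truth_left = truth_all[0::2]
    truth_right = truth_all[1::2]
    n = _trace_length(params, truth_all)
    lowback = lowback_waveform(truth_all, params, n, rng)
    heel_left = heel_waveform(truth_left, params, "left", n, rng)
    heel_right = heel_waveform(truth_right, params, "right", n, rng)
    markers = marker_trajectories(truth_left, truth_right, params, n, rng)
    return SyntheticTrial(
        lowback=lowback,
        heel_left=heel_left,
        heel_right=heel_right,
        markers=markers,
        truth_left=truth_left,
        truth_right=truth_right,
        truth_all=truth_all,
        truth_durations_ms=durations,
        params=params,
    )


def noise_sd_for_snr_db(params: GaitParams, snr_db: float) -> float:
    """Peak-relative noise SD giving the requested RMS signal-to-noise ratio.

    Computed on the noiseless lower-back waveform restricted to the
    segmented span (the quiet lead-in/tail would dilute the RMS).
    """
    clean = generate_trial(
        GaitParams(**{**params.__dict__, "noise_sd": 0.0})
    )
    w = clean.segment_window
    x = clean.lowback.samples[w.start : w.end]
    rms = float(np.sqrt(np.mean(x**2)))
    peak = float(np.max(np.abs(clean.lowback.samples)))
    return rms / (peak * 10.0 ** (snr_db / 20.0))
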