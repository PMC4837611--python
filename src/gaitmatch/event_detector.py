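"""Template matching, event selection, and the end-to-end detectors.

The segmented episode is first re-cut with extra margin (one TL to the
left, two TLs to the right) so that every cycle — including the first —
can be matched by a full sliding window.  Two similarity signals are
computed over all windows of TL samples: the normalized SD of the
amplitude difference (minimal at a good match) and the normalized,
range-weighted Pearson correlation (maximal at a good match).  Their
ratio, the coefficient signal, peaks at the start of each matched cycle;
peaks are greedily selected under a 60 % TL minimum spacing, restricted
to the span of the original segmentation, and shifted forward by the
section pre-peak fraction to land on the heel-strike instants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import DEFAULT_CONFIG, AlgorithmConfig, tl_samples
from .errors import (
    DegenerateMatchError,
    GaitError,
    InterleavingError,
    NoStepsFoundError,
    ResegmentationError,
)
from .signal_model import (
    AccelerationTrace,
    DurationSeries,
    EventSeries,
    SegmentWindow,
    segment,
)
from .template_builder import (
    TemplateLength,
    TemplateSignal,
    build_template,
    extract_sections,
    find_template_peaks,
    greedy_select,
    local_maxima,
    template_length_heel,
    template_length_lowback,
)


@dataclass
class MatchSignals:
    """Sliding-window similarity signals in resegmented coordinates."""

    sd_difference: np.ndarray
    correlation: np.ndarray
    coefficient: np.ndarray
    offset: int  # raw-trace index of window start 0

    def __post_init__(self) -> None:
        if not (len(self.sd_difference) == len(self.correlation) == len(self.coefficient)):
            raise ValueError("match signals must have equal length")


def resegment(
    raw: AccelerationTrace, window: SegmentWindow, tl: TemplateLength | int
) -> tuple[AccelerationTrace, SegmentWindow]:
    """Extend the segmentation by TL to the left and 2 TL to the right."""
    tl_n = tl.tl if isinstance(tl, TemplateLength) else int(tl)
    if tl_n <= 0:
        raise ValueError("template length must be positive")
    if window.start < tl_n:
        raise ResegmentationError(
            f"need {tl_n} raw samples left of the segment, have {window.start}"
        )
    if window.end + 2 * tl_n > len(raw):
        raise ResegmentationError(
            f"need {2 * tl_n} raw samples right of the segment, "
            f"have {len(raw) - window.end}"
        )
    new_window = SegmentWindow(window.start - tl_n, window.end + 2 * tl_n)
    return segment(raw, new_window), new_window


def _windows(reseg: np.ndarray, tl_n: int) -> np.ndarray:
    if reseg.size < tl_n:
        raise ValueError(f"resegmented signal shorter ({reseg.size}) than template ({tl_n})")
    return sliding_window_view(reseg, tl_n)


def sd_difference_signal(reseg: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized SD of (window - template), one value per window start.

    Population SD (divide by TL); insensitive to a constant offset between
    window and template; divided by its maximum so values lie in [0, 1].
    Zero exactly where the window matches the template up to a shift.
    """
    reseg = np.asarray(reseg, dtype=float)
    template = np.asarray(template, dtype=float)
    diff = _windows(reseg, template.size) - template
    sd = np.sqrt(np.maximum(np.mean(diff**2, axis=1) - np.mean(diff, axis=1) ** 2, 0.0))
    peak = sd.max()
    if peak == 0.0:
        raise DegenerateMatchError("SD-difference signal is zero everywhere (constant signals)")
    return sd / peak


def correlation_signal(
    reseg: np.ndarray,
    template: np.ndarray,
    config: AlgorithmConfig = DEFAULT_CONFIG,
    normalize: bool = True,
) -> np.ndarray:
    """Range-weighted sliding Pearson correlation with the template.

    Each window's correlation is multiplied by a range-ratio weight
    r = min(rho, 1/rho), rho = range(window)/range(template), penalizing
    shape matches at the wrong amplitude symmetrically for too-small and
    too-large windows.  Constant windows get correlation 0.  The signal is
    then divided by its maximum.
    """
    reseg = np.asarray(reseg, dtype=float)
    template = np.asarray(template, dtype=float)
    t_range = np.ptp(template)
    if t_range == 0.0:
        raise DegenerateMatchError("template is constant; correlation undefined")
    win = _windows(reseg, template.size)
    tc = template - template.mean()
    t_norm = np.sqrt(np.sum(tc**2))
    wc = win - win.mean(axis=1, keepdims=True)
    w_norm = np.sqrt(np.sum(wc**2, axis=1))
    corr = np.zeros(win.shape[0])
    ok = w_norm > 0
    corr[ok] = (wc[ok] @ tc) / (w_norm[ok] * t_norm)

    if config.range_ratio == "global":
        weight = 1.0
    else:
        rho = np.ptp(win, axis=1) / t_range
        if config.range_ratio == "per_window_sym":
            with np.errstate(divide="ignore"):
                weight = np.where(rho > 0, np.minimum(rho, 1.0 / np.maximum(rho, 1e-300)), 0.0)
        else:  # per_window_raw
            weight = rho
    raw = corr * weight
    if not normalize:
        return raw
    peak = raw.max()
    if peak <= 0.0:
        raise DegenerateMatchError("correlation signal has no positive maximum")
    return raw / peak


def coefficient_signal(
    match_or_corr, sd: np.ndarray | None = None, config: AlgorithmConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Ratio of the correlation signal to the (floored) SD-difference signal.

    The epsilon floor keeps near-perfect matches (SD ~ 0) from blowing up
    to infinity while preserving them as the global maxima.
    """
    if isinstance(match_or_corr, MatchSignals):
        corr, sd = match_or_corr.correlation, match_or_corr.sd_difference
    else:
        corr = np.asarray(match_or_corr, dtype=float)
        if sd is None:
            raise ValueError("sd_difference signal required")
    return corr / np.maximum(np.asarray(sd, dtype=float), config.coefficient_eps)


def compute_match_signals(
    reseg: AccelerationTrace | np.ndarray,
    template: TemplateSignal | np.ndarray,
    offset: int,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> MatchSignals:
    """Bundle the three sliding similarity signals for a resegmented episode."""
    x = reseg.samples if isinstance(reseg, AccelerationTrace) else np.asarray(reseg, float)
    t = template.values if isinstance(template, TemplateSignal) else np.asarray(template, float)
    sd = sd_difference_signal(x, t)
    corr = correlation_signal(x, t, config)
    coeff = coefficient_signal(corr, sd, config)
    return MatchSignals(sd_difference=sd, correlation=corr, coefficient=coeff, offset=offset)


def select_event_peaks(
    coeff: np.ndarray,
    tl: TemplateLength | int,
    seg_window: SegmentWindow,
    offset: int,
    shift_fraction: float,
    config: AlgorithmConfig = DEFAULT_CONFIG,
    correlation: np.ndarray | None = None,
) -> np.ndarray:
    """Select coefficient-signal peaks marking cycle starts (raw coordinates).

    Local maxima are admitted greedily by descending value under a minimum
    mutual spacing of 60 % TL (spacing exactly equal to the minimum is
    allowed), and only where the window-start position lies within the
    original segmentation span, widened to the left by the forward shift so
    that the shifted event can land on the segment's first sample.  The
    number of events is capped at the number of whole cycles the segment
    can hold (``floor(len(segment)/TL) + 1``), keeping the highest peaks,
    and, when the correlation signal is supplied, peaks whose normalized
    correlation falls below ``event_rel_floor`` times the median of the
    selected set are discarded (a genuine match resembles the template
    comparably to the other matches in the episode; the coefficient itself
    is unsuited to this check because its scale blows up wherever the
    SD-difference hits the epsilon floor).
    """
    coeff = np.asarray(coeff, dtype=float)
    if coeff.size == 0:
        raise NoStepsFoundError("empty coefficient signal")
    tl_n = tl.tl if isinstance(tl, TemplateLength) else int(tl)
    shift = tl_samples(shift_fraction, tl_n)
    cand = local_maxima(coeff)
    # a match peak must correlate positively with the template
    cand = cand[coeff[cand] > 0]
    pos = cand + offset
    # the shifted event must land inside the original segmentation
    admissible = (pos >= seg_window.start - shift) & (pos < seg_window.end - shift)
    cand = cand[admissible]
    if cand.size == 0:
        raise NoStepsFoundError("no coefficient peak inside the segmented span")
    cap = len(seg_window) // tl_n + 1
    kept = greedy_select(
        cand, coeff[cand], tl_samples(config.event_min_distance_fraction, tl_n), max_peaks=cap
    )
    if correlation is not None and kept.size:
        # discard stragglers far below the episode's typical match quality
        cv = np.asarray(correlation, dtype=float)[kept]
        kept = kept[cv >= config.event_rel_floor * float(np.median(cv))]
    if kept.size == 0:
        raise NoStepsFoundError("all selected coefficient peaks below the relative floor")
    return kept + offset


def shift_events(
    peaks: np.ndarray,
    tl: TemplateLength | int,
    shift_fraction: float,
    fs: float,
    method: str,
) -> EventSeries:
    """Shift selected peaks forward by the pre-peak fraction of TL.

    The template starts ``round(shift_fraction * TL)`` samples before its
    anchor peak, so the matched window start plus that shift approximates
    the heel-strike instant.
    """
    tl_n = tl.tl if isinstance(tl, TemplateLength) else int(tl)
    peaks = np.asarray(peaks, dtype=int)
    return EventSeries(events=peaks + tl_samples(shift_fraction, tl_n), method=method, fs=fs)


def durations_from_events(ev: EventSeries, kind: str = "step") -> DurationSeries:
    """Intervals between consecutive events, in milliseconds."""
    if len(ev) < 2:
        raise GaitError(f"need at least 2 events to compute durations, got {len(ev)}")
    return DurationSeries(durations_ms=np.diff(ev.events) * 1000.0 / ev.fs, kind=kind)


def combine_heel_events(left: EventSeries, right: EventSeries) -> EventSeries:
    """Merge left and right heel stride events into one step event series.

    The merged series must strictly alternate feet; a violation reports the
    offending raw indices.
    """
    if left.fs != right.fs:
        raise InterleavingError(f"sampling rates differ: {left.fs} vs {right.fs}")
    events = np.concatenate([left.events, right.events])
    sides = np.concatenate([np.zeros(len(left), int), np.ones(len(right), int)])
    order = np.argsort(events, kind="stable")
    events, sides = events[order], sides[order]
    same = np.flatnonzero(np.diff(sides) == 0)
    if same.size:
        k = int(same[0])
        raise InterleavingError(
            f"consecutive events {events[k]} and {events[k + 1]} come from the same foot"
        )
    return EventSeries(events=events, method="heel_accel_combined", fs=left.fs)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except GaitError as exc:
        exc.add_note(f"pipeline stage: {name}")
        raise


def _detect(
    raw: AccelerationTrace,
    window: SegmentWindow,
    tl_estimator,
    pre_fraction: float,
    method: str,
    kind: str,
    config: AlgorithmConfig,
) -> tuple[EventSeries, DurationSeries]:
    if config.invert_ap:
        raw = AccelerationTrace(-raw.samples, raw.fs, raw.placement, raw.unit)
    window.validate_for(len(raw))
    seg = _stage("segment", segment, raw, window)
    tl = _stage("template_length", tl_estimator, seg, config)
    peaks = _stage("find_template_peaks", find_template_peaks, seg, tl, config)
    sections = _stage("extract_sections", extract_sections, seg, peaks, tl, pre_fraction)
    template = _stage("build_template", build_template, sections, tl, pre_fraction, config)
    reseg, rwindow = _stage("resegment", resegment, raw, window, tl)
    match = _stage("match_signals", compute_match_signals, reseg, template, rwindow.start, config)
    sel = _stage(
        "select_event_peaks",
        select_event_peaks,
        match.coefficient,
        tl,
        window,
        rwindow.start,
        pre_fraction,
        config,
        match.correlation,
    )
    events = shift_events(sel, tl, pre_fraction, raw.fs, method)
    durations = _stage("durations", durations_from_events, events, kind)
    return events, durations


def detect_steps_lowback(
    raw: AccelerationTrace,
    window: SegmentWindow,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> tuple[EventSeries, DurationSeries]:
    """Full lower-back pipeline: one undifferentiated event per step."""
    return _detect(
        raw, window, template_length_lowback, config.pre_fraction_lowback,
        "lowback_accel", "step", config,
    )


def detect_strides_heel(
    raw: AccelerationTrace,
    window: SegmentWindow,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> tuple[EventSeries, DurationSeries]:
    """Full single-heel pipeline: one event per stride of that foot."""
    method = "heel_accel_left" if raw.placement == "heel_left" else "heel_accel_right"
    return _detect(
        raw, window, template_length_heel, config.pre_fraction_heel, method, "stride", config,
    )


def detect_steps_heel_combined(
    left: AccelerationTrace,
    right: AccelerationTrace,
    window: SegmentWindow,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> tuple[EventSeries, DurationSeries]:
    """Both-heel pipeline: merge per-foot stride events into step events."""
    ev_l, _ = detect_strides_heel(left, window, config)
    ev_r, _ = detect_strides_heel(right, window, config)
    combined = combine_heel_events(ev_l, ev_r)
    return combined, durations_from_events(combined, "step")
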