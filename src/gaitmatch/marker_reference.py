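"""Optoelectronic reference method for heel-strike timing.

Marker trajectories are resampled to the accelerometer rate, visibility is
evaluated in fixed-width intervals around anchor events (the heel-
accelerometry events), the best-seen marker per body site is selected, and
each heel strike is estimated as the instant of maximal anterior-posterior
distance between the selected heel marker and the lower-back marker.
Intervals with any hidden sample yield no event and are reported as
missed, feeding the stride-fallback pairing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, AlgorithmConfig
from .errors import ConfigurationError, GaitError
from .signal_model import AXES, EventSeries, MarkerTrace


@dataclass(frozen=True)
class VisibilityInterval:
    """Fixed-width half-open sample range around one anchor event."""

    center: int
    start: int
    end: int
    complete: bool


def visible_intervals(
    marker: MarkerTrace, anchors: EventSeries, width: int = 40
) -> list[VisibilityInterval]:
    """One interval of ``width`` samples per anchor; complete iff fully visible.

    Intervals clipped at the trace edges are marked incomplete.
    """
    if marker.fs != anchors.fs:
        raise ConfigurationError(
            f"marker rate {marker.fs} differs from anchor rate {anchors.fs}; resample first"
        )
    n = len(marker)
    half = width // 2
    out = []
    for a in anchors.events:
        start, end = int(a) - half, int(a) - half + width
        clipped = start < 0 or end > n
        s, e = max(start, 0), min(end, n)
        complete = (not clipped) and bool(marker.visible[s:e].all())
        out.append(VisibilityInterval(center=int(a), start=s, end=e, complete=complete))
    return out


def select_marker(
    candidates: list[MarkerTrace], anchors: EventSeries, width: int = 40
) -> MarkerTrace:
    """Candidate with the most complete intervals; ties go to lowest marker_id."""
    if not candidates:
        raise GaitError("no candidate markers for this site")
    scored = [
        (-sum(iv.complete for iv in visible_intervals(m, anchors, width)), m.marker_id, i)
        for i, m in enumerate(candidates)
    ]
    scored.sort()
    return candidates[scored[0][2]]


@dataclass
class ReferenceResult:
    """Marker-based heel strikes plus the bookkeeping of missed intervals."""

    events: EventSeries
    missed_anchor_indices: list[int]
    n_intervals: int

    @property
    def missed_fraction(self) -> float:
        return len(self.missed_anchor_indices) / self.n_intervals if self.n_intervals else 0.0


def heelstrike_from_markers(
    heel: MarkerTrace,
    back: MarkerTrace,
    intervals: list[VisibilityInterval],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> ReferenceResult:
    """Heel strikes as AP heel-minus-back distance maxima per complete interval.

    The distance is signed (positive = heel anterior of the trunk,
    configurable via ``ap_distance_sign``); argmax ties take the earliest
    sample.  Incomplete intervals yield no event and are counted as missed.
    """
    if heel.fs != back.fs or len(heel) != len(back):
        raise ConfigurationError("heel and back marker traces must share rate and length")
    if "AP" not in AXES:  # pragma: no cover - defensive
        raise ConfigurationError("AP axis not identified")
    distance = config.ap_distance_sign * (heel.ap - back.ap)
    events, missed = [], []
    for k, iv in enumerate(intervals):
        if not iv.complete:
            missed.append(k)
            continue
        events.append(iv.start + int(np.argmax(distance[iv.start : iv.end])))
    series = EventSeries(events=np.array(sorted(events), dtype=int), method="marker_reference", fs=heel.fs)
    return ReferenceResult(events=series, missed_anchor_indices=missed, n_intervals=len(intervals))


def detect_reference(
    heel_candidates: list[MarkerTrace],
    back_candidates: list[MarkerTrace],
    anchors: EventSeries,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> ReferenceResult:
    """End-to-end reference pipeline for one foot.

    Selects the best-seen heel and back markers, intersects their
    visibility (an interval is usable only if both markers are fully seen),
    and estimates one heel strike per usable interval.
    """
    width = config.visibility_width
    heel = select_marker(heel_candidates, anchors, width)
    back = select_marker(back_candidates, anchors, width)
    iv_h = visible_intervals(heel, anchors, width)
    iv_b = visible_intervals(back, anchors, width)
    merged = [
        VisibilityInterval(h.center, h.start, h.end, h.complete and b.complete)
        for h, b in zip(iv_h, iv_b)
    ]
    return heelstrike_from_markers(heel, back, merged, config)
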