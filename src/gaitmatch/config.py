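"""Algorithm constants, exposed in one place and loadable from YAML/JSON.

All the fractions that scale with the template length (TL), the
autocovariance band, filter order, thresholds and ambiguity switches sit in
:class:`AlgorithmConfig` with the published values as defaults.  Fractions
of TL are converted to integer sample counts by rounding half away from
zero with a floor of one sample (:func:`tl_samples`).
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass

import yaml


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    ``round_half_away(57.5) == 58``; symmetric for negative values.  A tiny
    epsilon absorbs binary floating-point error in products like
    ``1.15 * 50 == 57.49999999999999``.
    """
    eps = 1e-9
    return int(math.floor(x + 0.5 + eps)) if x >= 0 else int(math.ceil(x - 0.5 - eps))


def tl_samples(fraction: float, tl: int) -> int:
    """Convert a fraction of the template length to samples (minimum 1)."""
    return max(1, round_half_away(fraction * tl))


@dataclass
class AlgorithmConfig:
    # -- template length estimation --------------------------------------
    #: physiologic band (Hz) searched for the dominant cadence component
    freq_band: tuple[float, float] = (0.3, 5.0)
    #: frequency grid of the zero-padded spectrum (Hz)
    freq_grid_hz: float = 0.01
    #: the normalized autocovariance must reach this value at some lag
    #: beyond the shortest period of interest, else the signal is declared
    #: aperiodic (white noise decays like 1/sqrt(n - lag))
    min_periodicity: float = 0.2
    #: Butterworth order of the zero-phase low-pass in the heel TL rule
    heel_filter_order: int = 2
    #: normalized-autocovariance threshold for heel TL peaks
    heel_peak_threshold: float = 0.5

    # -- template building -------------------------------------------------
    #: edge trim for template peak search, as a fraction of TL
    peak_margin_fraction: float = 1.15
    #: minimum distance between template peaks, as a fraction of TL
    peak_min_distance_fraction: float = 0.40
    #: section starts this fraction of TL before the anchor peak
    pre_fraction_lowback: float = 0.15
    pre_fraction_heel: float = 0.05
    #: how the final averaged section (pre+TL samples) is fit to TL samples;
    #: truncation keeps the template time base aligned with the signal
    template_fit: str = "truncate"  # "truncate" | "resample"

    # -- matching / event selection ---------------------------------------
    #: minimum distance between selected coefficient peaks (fraction of TL)
    event_min_distance_fraction: float = 0.60
    #: floor applied to the normalized SD-difference signal in the ratio
    coefficient_eps: float = 1e-3
    #: selected peaks whose normalized correlation is below this fraction
    #: of the median over the selected set are discarded as spurious
    event_rel_floor: float = 0.25
    #: range-ratio weighting of the correlation signal
    range_ratio: str = "per_window_sym"  # | "per_window_raw" | "global"

    # -- I/O / orientation --------------------------------------------------
    #: negate the AP axis for sensors mounted with opposite polarity
    invert_ap: bool = False
    #: allow resample_to to increase the sampling rate
    allow_upsample: bool = False
    #: apply an anti-alias filter before integer decimation
    antialias: bool = False

    # -- marker reference ---------------------------------------------------
    #: visibility interval width around each anchor event (samples)
    visibility_width: int = 40
    #: sign of the AP heel-minus-back distance maximized at heel strike
    ap_distance_sign: float = 1.0

    def __post_init__(self) -> None:
        if self.template_fit not in ("resample", "truncate"):
            raise ValueError(f"template_fit: {self.template_fit!r}")
        if self.range_ratio not in ("per_window_sym", "per_window_raw", "global"):
            raise ValueError(f"range_ratio: {self.range_ratio!r}")
        lo, hi = self.freq_band
        if not (0 < lo < hi):
            raise ValueError(f"freq_band: {self.freq_band!r}")

    def replace(self, **kwargs) -> "AlgorithmConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "AlgorithmConfig":
        """Load constants from a YAML or JSON mapping; unknown keys rejected."""
        path = pathlib.Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config keys")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "freq_band" in data:
            data["freq_band"] = tuple(data["freq_band"])
        return cls(**data)


DEFAULT_CONFIG = AlgorithmConfig()
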