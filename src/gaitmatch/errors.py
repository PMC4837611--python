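"""Exception hierarchy for the gait event detection pipeline.

Every stage of the pipeline raises a subclass of :class:`GaitError`, so
callers can catch the whole family or react to specific failure modes
(degenerate signals, too-short episodes, pairing mismatches, ...).
"""


class GaitError(Exception):
    """Base class for all gaitmatch errors."""


class TraceParseError(GaitError):
    """A trace or marker file could not be parsed (names row/column)."""


class ConfigurationError(GaitError):
    """Inconsistent configuration or input metadata (axes, rates, ...)."""


class DegenerateSignalError(GaitError):
    """Signal carries no usable periodic structure (constant, pure noise)."""


class PeriodicityNotFoundError(DegenerateSignalError):
    """Autocovariance shows no second peak above threshold (heel rule)."""


class TooShortEpisodeError(GaitError):
    """Segmented episode too short relative to the estimated cycle length."""


class TooFewCyclesError(GaitError):
    """Fewer than two admissible template peaks/sections in the episode."""


class ResegmentationError(GaitError):
    """Raw trace lacks the margin needed to extend the segmentation."""


class DegenerateMatchError(GaitError):
    """Match signals cannot be normalized (zero SD / non-positive maxima)."""


class NoStepsFoundError(GaitError):
    """No admissible peak survives selection in the coefficient signal."""


class InterleavingError(GaitError):
    """Left/right heel event series do not alternate when merged."""


class PairingError(GaitError):
    """Two event series cannot be paired step-by-step."""


class ComparisonError(GaitError):
    """Agreement statistic undefined (e.g. zero total variance for ICC)."""
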