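"""Core data types and trace I/O shared by the whole pipeline.

An :class:`AccelerationTrace` holds a single-axis (anterior-posterior)
acceleration series with its sampling rate and sensor placement; a
:class:`MarkerTrace` holds 3-D optoelectronic marker positions with a
per-sample visibility mask.  Episodes of gait are addressed through
half-open 0-based :class:`SegmentWindow` ranges, so ``end - start`` is the
segment length.  Trace files are one-sample-per-row delimited text; the
sampling rate is always supplied by the caller, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TraceParseError

PLACEMENTS = ("lower_back", "heel_left", "heel_right")
#: axis order used throughout for marker positions
AXES = ("AP", "ML", "vertical")


def _readonly(a: np.ndarray) -> np.ndarray:
    view = a.view()
    view.flags.writeable = False
    return view


@dataclass
class AccelerationTrace:
    """Uniformly sampled 1-D AP acceleration.

    The amplitude unit (g or m/s^2) is recorded but never interpreted: the
    detection pipeline is scale-invariant by construction.
    """

    samples: np.ndarray
    fs: float
    placement: str
    unit: str = "g"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples in one dimension")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains missing/non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SegmentWindow:
    """Half-open sample range [start, end), 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def validate_for(self, n: int) -> None:
        if self.end > n:
            raise ValueError(f"window [{self.start}, {self.end}) exceeds trace length {n}")


@dataclass
class MarkerTrace:
    """3-D marker positions (mm) with per-sample visibility."""

    positions: np.ndarray  # (n, 3) in AXES order
    visible: np.ndarray  # (n,) bool
    fs: float
    site: str
    marker_id: str = "M0"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if self.visible.shape != (self.positions.shape[0],):
            raise ValueError("positions and visible must have equal length")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def ap(self) -> np.ndarray:
        """Anterior-posterior coordinate (first axis by convention)."""
        return self.positions[:, AXES.index("AP")]


def load_trace(
    path,
    *,
    fs: float,
    placement: str,
    column: int | str = 0,
    delimiter: str | None = None,
    header: bool = False,
    invert_ap: bool = False,
    unit: str = "g",
) -> AccelerationTrace:
    """Read a one-sample-per-row delimited text file into a trace.

    ``column`` selects by name (requires ``header=True``) or 0-based index.
    Parse failures name the offending row and column.
    """
    kwargs = dict(header=0 if header else None, dtype=str, skipinitialspace=True)
    if delimiter is None:
        # default: comma or any whitespace
        kwargs.update(sep=r"[,\s]+", engine="python")
    else:
        kwargs.update(sep=delimiter)
    try:
        frame = pd.read_csv(path, **kwargs)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"{path}: file is empty") from exc
    except Exception as exc:  # malformed text
        raise TraceParseError(f"{path}: {exc}") from exc

    if isinstance(column, str):
        if column not in frame.columns:
            raise TraceParseError(f"{path}: no column named {column!r} (have {list(frame.columns)})")
        raw = frame[column]
        col_label = column
    else:
        if column >= frame.shape[1]:
            raise TraceParseError(f"{path}: column index {column} out of range ({frame.shape[1]} columns)")
        raw = frame.iloc[:, column]
        col_label = str(column)

    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TraceParseError(
            f"{path}: non-numeric value {raw.iloc[row]!r} at row {row}, column {col_label}"
        )
    if values.isna().any():
        row = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise TraceParseError(f"{path}: missing value at row {row}, column {col_label}")

    samples = values.to_numpy(dtype=float)
    if invert_ap:
        samples = -samples
    return AccelerationTrace(samples=samples, fs=fs, placement=placement, unit=unit)


def write_trace(trace: AccelerationTrace, path, fmt: str = "%.6g") -> None:
    """Write a trace one sample per line (6 significant digits by default)."""
    np.savetxt(path, trace.samples, fmt=fmt)


def load_marker(
    path,
    *,
    fs: float,
    site: str,
    marker_id: str = "M0",
    columns: tuple[str, str, str] = ("ap", "ml", "vt"),
    visibility_column: str | None = None,
    delimiter: str = ",",
) -> MarkerTrace:
    """Read a marker CSV (header row, x/y/z columns in AP/ML/vertical order).

    A row with an empty/NaN coordinate is treated as not visible; an explicit
    boolean/0-1 ``visibility_column`` is combined with that rule.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"{path}: file is empty") from exc
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise TraceParseError(f"{path}: missing coordinate columns {missing}")
    coords = frame[list(columns)].apply(pd.to_numeric, errors="coerce")
    visible = coords.notna().all(axis=1).to_numpy()
    if visibility_column is not None:
        if visibility_column not in frame.columns:
            raise TraceParseError(f"{path}: missing visibility column {visibility_column!r}")
        flag = pd.to_numeric(frame[visibility_column], errors="coerce").fillna(0.0)
        visible &= flag.to_numpy() > 0
    positions = coords.fillna(0.0).to_numpy(dtype=float)
    return MarkerTrace(positions=positions, visible=visible, fs=fs, site=site, marker_id=marker_id)


def resample_to(obj, target_fs: float, *, allow_upsample: bool = False, mode: str = "decimate"):
    """Resample a trace or marker trace to ``target_fs``.

    ``mode="decimate"`` (default) keeps every k-th measured sample when the
    rate ratio is an integer, preserving original values; ``mode="linear"``
    interpolates onto the new time base.  Visibility masks are resampled
    conservatively: a target sample is visible only if all source samples it
    draws on are visible.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == obj.fs:
        return obj
    if target_fs > obj.fs and not allow_upsample:
        raise ConfigurationError(
            f"upsampling {obj.fs} -> {target_fs} samples/s not enabled (allow_upsample)"
        )
    ratio = obj.fs / target_fs
    integer = abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1

    if isinstance(obj, AccelerationTrace):
        if mode == "decimate" and integer:
            samples = obj.samples[:: int(round(ratio))]
        else:
            n_out = round_len(len(obj), obj.fs, target_fs)
            t_out = np.arange(n_out) / target_fs
            t_in = np.arange(len(obj)) / obj.fs
            samples = np.interp(t_out, t_in, obj.samples)
        return AccelerationTrace(samples=samples, fs=target_fs, placement=obj.placement, unit=obj.unit)

    if isinstance(obj, MarkerTrace):
        n = len(obj)
        if mode == "decimate" and integer:
            k = int(round(ratio))
            positions = obj.positions[::k]
            n_out = positions.shape[0]
            # conservative: target i visible only if its whole source block is
            pad = -(-n // k) * k - n
            vis = np.concatenate([obj.visible, np.zeros(pad, bool)]) if pad else obj.visible
            visible = vis.reshape(-1, k).all(axis=1)[:n_out]
            if pad:  # last partial block judged on its real samples only
                visible[-1] = obj.visible[(n_out - 1) * k :].all()
        else:
            n_out = round_len(n, obj.fs, target_fs)
            t_out = np.arange(n_out) / target_fs
            t_in = np.arange(n) / obj.fs
            positions = np.column_stack(
                [np.interp(t_out, t_in, obj.positions[:, j]) for j in range(3)]
            )
            lo = np.clip(np.floor(t_out * obj.fs).astype(int), 0, n - 1)
            hi = np.clip(np.ceil(t_out * obj.fs).astype(int), 0, n - 1)
            visible = obj.visible[lo] & obj.visible[hi]
        return MarkerTrace(
            positions=positions, visible=visible, fs=target_fs, site=obj.site, marker_id=obj.marker_id
        )

    raise TypeError(f"cannot resample {type(obj).__name__}")


def round_len(n: int, fs: float, target_fs: float) -> int:
    """Output length preserving duration within one sample period."""
    return max(2, int(round(n * target_fs / fs)))


def segment(trace: AccelerationTrace, window: SegmentWindow) -> AccelerationTrace:
    """Return a read-only view of ``trace`` restricted to ``window``.

    The result shares memory with the source but is write-protected, so
    mutating it can never alter the source.
    """
    window.validate_for(len(trace))
    view = AccelerationTrace.__new__(AccelerationTrace)
    view.samples = _readonly(trace.samples[window.start : window.end])
    view.fs = trace.fs
    view.placement = trace.placement
    view.unit = trace.unit
    if len(view.samples) < 2:
        raise ValueError("segment shorter than 2 samples")
    return view


@dataclass
class EventSeries:
    """Strictly increasing heel-strike sample indices in raw-trace coordinates."""

    events: np.ndarray
    method: str
    fs: float

    METHODS = (
        "lowback_accel",
        "heel_accel_left",
        "heel_accel_right",
        "heel_accel_combined",
        "marker_reference",
        "ground_truth",
    )

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=int)
        if self.events.ndim != 1:
            raise ValueError("events must be 1-D")
        if self.events.size > 1 and not np.all(np.diff(self.events) > 0):
            raise ValueError("events must be strictly increasing")
        if self.method not in self.METHODS:
            raise ValueError(f"method must be one of {self.METHODS}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.events.size

    @property
    def times_s(self) -> np.ndarray:
        return self.events / self.fs


@dataclass
class DurationSeries:
    """Step or stride durations in milliseconds."""

    durations_ms: np.ndarray
    kind: str  # "step" | "stride"

    def __post_init__(self) -> None:
        self.durations_ms = np.asarray(self.durations_ms, dtype=float)
        if self.kind not in ("step", "stride"):
            raise ValueError("kind must be 'step' or 'stride'")
        if np.any(self.durations_ms <= 0):
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return self.durations_ms.size


def events_frame(ev: EventSeries, durations: DurationSeries | None = None) -> pd.DataFrame:
    """Tabulate an event series as the tool's standard output table.

    Columns: method, event_index_samples, event_time_s, duration_ms (the
    duration of the interval ending at each event; first row NaN).
    """
    dur = np.full(len(ev), np.nan)
    if durations is not None and len(durations) == len(ev) - 1:
        dur[1:] = durations.durations_ms
    elif len(ev) > 1:
        dur[1:] = np.diff(ev.events) * 1000.0 / ev.fs
    return pd.DataFrame(
        {
            "method": ev.method,
            "event_index_samples": ev.events,
            "event_time_s": ev.times_s,
            "duration_ms": dur,
        }
    )
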