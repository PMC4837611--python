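"""Template length estimation and DTW-averaged template construction.

The template is a per-episode average waveform of one gait cycle: a *step*
cycle for the lower-back sensor (the AP trunk acceleration repeats every
step) and a *stride* cycle for a heel sensor (a heel only strikes once per
stride).  Its length TL is estimated from the periodicity of the unbiased
autocovariance of the segmented signal; candidate cycles are then anchored
at the highest AP peaks, cut into sections that start a small fraction of
TL before each peak, and hierarchically averaged with dynamic time warping
until a single template remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .config import DEFAULT_CONFIG, AlgorithmConfig, round_half_away, tl_samples
from .errors import (
    DegenerateSignalError,
    PeriodicityNotFoundError,
    TooFewCyclesError,
    TooShortEpisodeError,
)
from .signal_model import AccelerationTrace


@dataclass(frozen=True)
class TemplateLength:
    """Estimated gait-cycle length in samples."""

    tl: int
    dominant_freq: float
    placement: str

    def __post_init__(self) -> None:
        if self.tl < 4:
            raise TooShortEpisodeError(f"template length {self.tl} < 4 samples")


@dataclass
class TemplateSignal:
    """Averaged cycle waveform of exactly ``tl`` samples."""

    values: np.ndarray
    pre_fraction: float
    n_sections: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_sections < 2:
            raise TooFewCyclesError("template built from fewer than 2 sections")

    def __len__(self) -> int:
        return self.values.size


def unbiased_autocovariance(x: np.ndarray) -> np.ndarray:
    """Unbiased autocovariance over non-negative lags 0..n-1.

    Lag-k value is ``(1/(n-k)) * sum_t (x_t - mean)(x_{t+k} - mean)``, the
    'unbiased' normalization in which each lag is divided by its own number
    of products, counteracting the taper of the raw sum at long lags.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    xc = x - x.mean()
    if np.max(np.abs(xc)) == 0.0:
        raise DegenerateSignalError("constant signal has no autocovariance structure")
    acov = np.correlate(xc, xc, mode="full")[n - 1 :]
    return acov / (n - np.arange(n))


def dominant_frequency(
    acov: np.ndarray, fs: float, config: AlgorithmConfig = DEFAULT_CONFIG
) -> float:
    """Frequency (Hz) of the largest spectral component of the autocovariance.

    The positive-lag autocovariance is zero-padded onto a fine frequency
    grid and the magnitude spectrum searched inside the physiologic band.
    Aperiodic signals are rejected first: a periodic signal keeps a large
    positive normalized autocovariance at multiples of its period, whereas
    for white noise it decays like 1/sqrt(n - lag); if no lag beyond the
    shortest period of interest reaches ``min_periodicity``, there is no
    peak to extract.
    """
    acov = np.asarray(acov, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    k_min = int(np.ceil(fs / config.freq_band[1]))
    k_max = max(k_min + 1, acov.size // 2)
    if acov.size > k_min and np.max(acov[k_min:k_max]) < config.min_periodicity * acov[0]:
        raise DegenerateSignalError(
            "autocovariance shows no periodicity beyond lag 0 (aperiodic signal?)"
        )
    nfft = int(next_fast_len(max(acov.size, int(np.ceil(fs / config.freq_grid_hz)))))
    mag = np.abs(np.fft.rfft(acov, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    lo, hi = config.freq_band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        raise DegenerateSignalError(f"no spectral bins inside band {config.freq_band}")
    band_mag = mag[in_band]
    if band_mag.max() <= 0:
        raise DegenerateSignalError("no spectral energy inside the physiologic band")
    return float(freqs[in_band][int(np.argmax(band_mag))])


def _check_episode(n: int, tl: int, fs: float, freq: float) -> None:
    if n < 3 * fs / freq:
        raise TooShortEpisodeError(
            f"episode of {n} samples holds fewer than 3 cycles at {freq:.2f} Hz"
        )
    if tl >= n / 2:
        raise TooShortEpisodeError(f"template length {tl} >= half the episode ({n} samples)")


def template_length_lowback(
    seg: AccelerationTrace, config: AlgorithmConfig = DEFAULT_CONFIG
) -> TemplateLength:
    """Step-cycle length: sampling rate over the dominant cadence frequency."""
    acov = unbiased_autocovariance(seg.samples)
    freq = dominant_frequency(acov, seg.fs, config)
    tl = round_half_away(seg.fs / freq)
    _check_episode(len(seg), tl, seg.fs, freq)
    return TemplateLength(tl=tl, dominant_freq=freq, placement=seg.placement)


def template_length_heel(
    seg: AccelerationTrace, config: AlgorithmConfig = DEFAULT_CONFIG
) -> TemplateLength:
    """Stride-cycle length from the heel autocovariance peak structure.

    The autocovariance is normalized by its lag-0 value, low-pass filtered
    at twice the dominant frequency (zero-phase Butterworth), and TL is the
    lag distance between the first two peaks exceeding the 0.5 threshold —
    lag 0 counting as the first peak, so TL is the lag of the first interior
    peak above threshold.
    """
    acov = unbiased_autocovariance(seg.samples)
    freq = dominant_frequency(acov, seg.fs, config)
    norm = acov / acov[0]
    cutoff = 2.0 * freq
    nyq = seg.fs / 2.0
    if cutoff >= nyq:
        cutoff = 0.99 * nyq
    sos = sps.butter(config.heel_filter_order, cutoff, btype="low", fs=seg.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, norm)
    interior = np.flatnonzero(
        (filtered[1:-1] > filtered[:-2])
        & (filtered[1:-1] > filtered[2:])
        & (filtered[1:-1] > config.heel_peak_threshold)
    )
    if interior.size == 0:
        raise PeriodicityNotFoundError(
            f"no autocovariance peak above {config.heel_peak_threshold} beyond lag 0"
        )
    tl = int(interior[0]) + 1
    _check_episode(len(seg), tl, seg.fs, seg.fs / tl)
    return TemplateLength(tl=tl, dominant_freq=freq, placement=seg.placement)


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima of a 1-D signal."""
    x = np.asarray(x, dtype=float)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def greedy_select(
    candidates: np.ndarray,
    values: np.ndarray,
    min_distance: int,
    max_peaks: int | None = None,
) -> np.ndarray:
    """Greedy peak admission: descending value, earlier index on ties.

    A candidate is kept only if it lies at least ``min_distance`` samples
    from every already-kept peak.  ``max_peaks`` caps the number admitted
    (the highest win); peaks anchor gait cycles, and a signal of known
    cycle length cannot hold more cycles than fit in it.  Returns kept
    indices sorted ascending.
    """
    order = np.lexsort((candidates, -values))
    kept: list[int] = []
    for j in order:
        if max_peaks is not None and len(kept) >= max_peaks:
            break
        c = int(candidates[j])
        if all(abs(c - k) >= min_distance for k in kept):
            kept.append(c)
    return np.array(sorted(kept), dtype=int)


def find_template_peaks(
    seg: AccelerationTrace | np.ndarray,
    tl: TemplateLength | int,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Anchor peaks for the template sections (segment coordinates).

    Local maxima of the signed AP signal inside the edge-trimmed interior
    ``[round(1.15 TL), n - round(1.15 TL))``, greedily admitted in order of
    descending amplitude under a minimum mutual distance of 40 % TL, and
    capped at the number of whole cycles the interior can hold
    (``floor(interior/TL)``, at least 2) so low-amplitude noise maxima
    between cycle peaks — or near the interior edges, where their parent
    cycle peak is trimmed away — cannot become template anchors.
    """
    x = seg.samples if isinstance(seg, AccelerationTrace) else np.asarray(seg, float)
    tl_n = tl.tl if isinstance(tl, TemplateLength) else int(tl)
    n = x.size
    margin = round_half_away(config.peak_margin_fraction * tl_n)
    if n <= 2 * margin + tl_n:
        raise TooShortEpisodeError(
            f"segment of {n} samples too short for edge trim of {margin} samples each side"
        )
    cand = local_maxima(x)
    cand = cand[(cand >= margin) & (cand < n - margin)]
    if cand.size < 2:
        raise TooFewCyclesError(
            f"only {cand.size} candidate peak(s) inside [{margin}, {n - margin})"
        )
    cap = max(2, (n - 2 * margin) // tl_n)
    peaks = greedy_select(
        cand, x[cand], tl_samples(config.peak_min_distance_fraction, tl_n), max_peaks=cap
    )
    if peaks.size < 2:
        raise TooFewCyclesError("fewer than 2 admissible template peaks")
    return peaks


def extract_sections(
    seg: AccelerationTrace | np.ndarray,
    peaks: np.ndarray,
    tl: TemplateLength | int,
    pre_fraction: float,
) -> list[np.ndarray]:
    """Cut one section per anchor peak: ``[p - pre, p + TL)`` samples.

    ``pre = round(pre_fraction * TL)`` captures the slope preceding the
    peak.  Sections that would cross the segment boundary are dropped with
    a warning; fewer than two survivors is an error.
    """
    x = seg.samples if isinstance(seg, AccelerationTrace) else np.asarray(seg, float)
    tl_n = tl.tl if isinstance(tl, TemplateLength) else int(tl)
    pre = tl_samples(pre_fraction, tl_n)
    sections = []
    for p in np.asarray(peaks, dtype=int):
        if p - pre < 0 or p + tl_n > x.size:
            warnings.warn(
                f"section at peak {p} crosses the segment boundary; dropped", stacklevel=2
            )
            continue
        sections.append(x[p - pre : p + tl_n].copy())
    if len(sections) < 2:
        raise TooFewCyclesError(f"only {len(sections)} section(s) survive boundary checks")
    return sections


def dtw_path(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal DTW alignment path and its cumulative cost.

    Absolute-difference local cost, symmetric unweighted steps
    {(1,0), (0,1), (1,1)}, endpoints pinned, no window constraint.  The
    accumulated-cost matrix is filled row by row: within a row, the
    left-neighbour dependency is resolved in closed form with a running
    minimum over cost prefix sums, so the fill is fully vectorized.
    Backtracking prefers the diagonal step, then the vertical, on ties;
    ties are judged with a small relative tolerance so that the chosen
    path — and hence the DTW average — is stable under floating-point
    perturbations of the inputs (e.g. adding a constant to both).

    Returns an (L, 2) array of index pairs and the total cost.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot align empty sequences")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    D = np.empty((n, m))
    D[0] = np.cumsum(cost[0])
    for i in range(1, n):
        # v[j] = best cost of entering (i, j) from row i-1
        v = np.empty(m)
        v[0] = D[i - 1, 0]
        v[1:] = np.minimum(D[i - 1, 1:], D[i - 1, :-1])
        # D[i, j] = S[j] + min_{k <= j} (v[k] - S[k-1]),  S = prefix sums of row cost
        s = np.cumsum(cost[i])
        s_prev = np.concatenate(([0.0], s[:-1]))
        D[i] = s + np.minimum.accumulate(v - s_prev)
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            best = min(diag, up, left)
            tol = 1e-9 * max(1.0, abs(best))
            if diag <= best + tol:
                i, j = i - 1, j - 1
            elif up <= best + tol:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return np.array(path, dtype=int), float(D[n - 1, m - 1])


def _resample_linear(x: np.ndarray, length: int) -> np.ndarray:
    if x.size == length:
        return x
    return np.interp(np.linspace(0.0, 1.0, length), np.linspace(0.0, 1.0, x.size), x)


def dtw_average_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Average two sequences along their optimal DTW alignment.

    Aligned pairs are averaged along the path and the result linearly
    resampled back to ``len(a)``, so repeated pairwise averaging keeps a
    stable length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    path, _ = dtw_path(a, b)
    averaged = 0.5 * (a[path[:, 0]] + b[path[:, 1]])
    return _resample_linear(averaged, a.size)


def build_template(
    sections: list[np.ndarray],
    tl: TemplateLength | int,
    pre_fraction: float,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> TemplateSignal:
    """Hierarchically DTW-average sections into a single TL-sample template.

    Consecutive pairs are averaged, halving the list each round (an odd
    leftover is carried unchanged), until one signal remains.  The sections
    are ``pre + TL`` samples long; the final average is fitted to exactly
    TL samples either by linear resampling (default) or by truncation,
    per ``config.template_fit``.
    """
    if len(sections) < 2:
        raise TooFewCyclesError("need at least 2 sections to build a template")
    lengths = {len(s) for s in sections}
    if len(lengths) != 1:
        raise ValueError(f"sections have unequal lengths {sorted(lengths)}")
    tl_n = tl.tl if isinstance(tl, TemplateLength) else int(tl)
    current = [np.asarray(s, dtype=float) for s in sections]
    while len(current) > 1:
        nxt = [dtw_average_pair(current[i], current[i + 1]) for i in range(0, len(current) - 1, 2)]
        if len(current) % 2:
            nxt.append(current[-1])
        current = nxt
    final = current[0]
    if config.template_fit == "truncate":
        values = final[:tl_n]
    else:
        values = _resample_linear(final, tl_n)
    return TemplateSignal(values=values, pre_fraction=pre_fraction, n_sections=len(sections))
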