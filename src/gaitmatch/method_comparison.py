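"""Between-method agreement statistics for step durations.

Two event series covering the same episode are paired step by step; where
the reference method missed a heel strike, the two step comparisons
touching it collapse into a single stride comparison spanning the gap
(the stride fallback).  Agreement is summarized as per-pair absolute
differences (ms and % of the average step duration of both systems),
ICC(2,1) absolute agreement, and a normality-gated paired test: paired t
if the Shapiro-Wilk test does not reject normality of the differences at
alpha = 0.05, Wilcoxon signed-rank otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ComparisonError, PairingError
from .signal_model import EventSeries

ALPHA = 0.05


@dataclass
class PairedDurations:
    """Order-matched duration pairs; stride-fallback entries flagged."""

    a_ms: np.ndarray
    b_ms: np.ndarray
    kinds: list[str]  # "step" | "stride" per entry
    methods: tuple[str, str]

    def __post_init__(self) -> None:
        self.a_ms = np.asarray(self.a_ms, dtype=float)
        self.b_ms = np.asarray(self.b_ms, dtype=float)
        if not (len(self.a_ms) == len(self.b_ms) == len(self.kinds)):
            raise ValueError("paired vectors must have equal length")
        if len(self.a_ms) < 1:
            raise ValueError("need at least one pair")
        if np.any(self.a_ms <= 0) or np.any(self.b_ms <= 0):
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return len(self.a_ms)


@dataclass
class ComparisonResult:
    abs_diff_ms: np.ndarray
    mean_abs_diff_ms: float
    sd_abs_diff_ms: float | None
    pct_of_mean_step: float
    icc: float | None = None
    normality_p: float | None = None
    test_name: str | None = None
    test_p: float | None = None
    alpha: float = ALPHA
    methods: tuple[str, str] = ("", "")
    n_step_pairs: int = 0
    n_stride_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "n_pairs": int(len(self.abs_diff_ms)),
            "n_step_pairs": self.n_step_pairs,
            "n_stride_pairs": self.n_stride_pairs,
            "mean_abs_diff_ms": self.mean_abs_diff_ms,
            "sd_abs_diff_ms": self.sd_abs_diff_ms,
            "pct_of_mean_step": self.pct_of_mean_step,
            "icc": self.icc,
            "normality_p": self.normality_p,
            "test_name": self.test_name,
            "test_p": self.test_p,
            "alpha": self.alpha,
        }


def pair_events(
    a: EventSeries, b: EventSeries, missed: set[int] | frozenset[int] = frozenset()
) -> PairedDurations:
    """Pair durations of two series by order, with stride fallback.

    ``missed`` holds positions (indices into ``a``'s event order) at which
    ``b`` has no event, so ``len(b) + len(missed) == len(a)`` must hold.
    For an isolated missed event k the step pairs (k-1,k) and (k,k+1) are
    replaced by one stride pair (k-1,k+1) in both series; gaps spanning
    more than one missed event are excluded with a warning.
    """
    missed = set(int(k) for k in missed)
    n = len(a)
    if bad := [k for k in missed if not 0 <= k < n]:
        raise PairingError(f"missed indices {bad} outside 0..{n - 1}")
    if len(b) + len(missed) != n:
        raise PairingError(
            f"cannot align {len(a)} events of {a.method} with {len(b)} events of "
            f"{b.method} given {len(missed)} missed; alignment: "
            f"a={a.events.tolist()} b={b.events.tolist()} missed={sorted(missed)}"
        )
    present = [k for k in range(n) if k not in missed]
    if len(present) < 2:
        raise PairingError("fewer than 2 events of b survive; nothing to pair")
    b_at = dict(zip(present, b.events))

    a_ms, b_ms, kinds = [], [], []
    for i, j in zip(present[:-1], present[1:]):
        span = j - i
        if span == 1:
            kind = "step"
        elif span == 2:
            kind = "stride"
        else:
            warnings.warn(
                f"gap of {span - 1} consecutive missed events between {i} and {j}; "
                "excluded from pairing",
                stacklevel=2,
            )
            continue
        a_ms.append((a.events[j] - a.events[i]) * 1000.0 / a.fs)
        b_ms.append((b_at[j] - b_at[i]) * 1000.0 / b.fs)
        kinds.append(kind)
    if not a_ms:
        raise PairingError("no pairable intervals remain")
    return PairedDurations(
        a_ms=np.array(a_ms), b_ms=np.array(b_ms), kinds=kinds, methods=(a.method, b.method)
    )


def absolute_differences(p: PairedDurations) -> ComparisonResult:
    """Per-pair absolute differences with summary statistics.

    ``pct_of_mean_step`` divides the mean absolute difference by the mean
    step duration pooled over both series (stride-fallback entries enter
    the denominator as duration/2, i.e. as step equivalents).
    """
    diff = np.abs(p.a_ms - p.b_ms)
    halves = np.array([2.0 if k == "stride" else 1.0 for k in p.kinds])
    pooled = np.concatenate([p.a_ms / halves, p.b_ms / halves])
    mean_step = float(pooled.mean())
    return ComparisonResult(
        abs_diff_ms=diff,
        mean_abs_diff_ms=float(diff.mean()),
        sd_abs_diff_ms=float(diff.std(ddof=1)) if diff.size > 1 else None,
        pct_of_mean_step=100.0 * float(diff.mean()) / mean_step,
        methods=p.methods,
        n_step_pairs=sum(k == "step" for k in p.kinds),
        n_stride_pairs=sum(k == "stride" for k in p.kinds),
    )


def icc_absolute_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares of the n x 2 table of
    paired durations:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-target, MSC the between-rater and MSE the residual
    mean square.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ComparisonError(f"need at least 3 pairs for ICC, got {n}")
    y = np.column_stack([a, b])
    k = 2
    grand = y.mean()
    sst = np.sum((y - grand) ** 2)
    if sst == 0.0:
        raise ComparisonError("zero total variance; ICC undefined")
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def normality_gated_test(
    diffs_x: np.ndarray, diffs_y: np.ndarray, alpha: float = ALPHA
) -> tuple[str, float, float]:
    """Shapiro-Wilk-gated paired comparison of two matched vectors.

    Returns ``(test_name, test_p, normality_p)``: a paired t-test when the
    differences pass the Shapiro-Wilk normality check (p > alpha), a
    Wilcoxon signed-rank test otherwise.  Identical vectors are reported
    under the zero-variance convention with p = 1.
    """
    x = np.asarray(diffs_x, dtype=float)
    y = np.asarray(diffs_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D vectors with n >= 3")
    d = x - y
    if np.ptp(d) == 0.0:
        return ("zero_variance", 1.0, float("nan"))
    normality_p = float(stats.shapiro(d).pvalue)
    if normality_p > alpha:
        return ("paired_t", float(stats.ttest_rel(x, y).pvalue), normality_p)
    res = stats.wilcoxon(x, y)
    return ("wilcoxon_signed_rank", float(res.pvalue), normality_p)


def compare_methods(
    a: EventSeries,
    b: EventSeries,
    missed: set[int] | frozenset[int] = frozenset(),
) -> ComparisonResult:
    """Full comparison of two event series: pairing, differences, ICC, test."""
    paired = pair_events(a, b, missed)
    result = absolute_differences(paired)
    if len(paired) >= 3:
        try:
            result.icc = icc_absolute_agreement(paired.a_ms, paired.b_ms)
        except ComparisonError:
            result.icc = None
        result.test_name, result.test_p, result.normality_p = normality_gated_test(
            paired.a_ms, paired.b_ms
        )
    return result


@dataclass
class ComparisonSummary:
    """Trial-mean aggregation of several per-trial comparisons."""

    mean_abs_diff_ms: float
    sd_abs_diff_ms: float
    mean_pct_of_mean_step: float
    sd_pct_of_mean_step: float
    icc_pooled: float | None
    n_trials: int
    n_pairs: int


def summarize_comparisons(
    per_trial: list[PairedDurations],
) -> ComparisonSummary:
    """Average absolute differences within trials, then across trials.

    The pooled ICC is computed over all pairs of all trials at once.
    """
    if not per_trial:
        raise ComparisonError("no trials to summarize")
    trial_means = []
    trial_pcts = []
    for p in per_trial:
        r = absolute_differences(p)
        trial_means.append(r.mean_abs_diff_ms)
        trial_pcts.append(r.pct_of_mean_step)
    all_a = np.concatenate([p.a_ms for p in per_trial])
    all_b = np.concatenate([p.b_ms for p in per_trial])
    try:
        icc = icc_absolute_agreement(all_a, all_b) if all_a.size >= 3 else None
    except ComparisonError:
        icc = None
    tm = np.array(trial_means)
    tp = np.array(trial_pcts)
    return ComparisonSummary(
        mean_abs_diff_ms=float(tm.mean()),
        sd_abs_diff_ms=float(tm.std(ddof=1)) if tm.size > 1 else 0.0,
        mean_pct_of_mean_step=float(tp.mean()),
        sd_pct_of_mean_step=float(tp.std(ddof=1)) if tp.size > 1 else 0.0,
        icc_pooled=icc,
        n_trials=len(per_trial),
        n_pairs=int(all_a.size),
    )
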