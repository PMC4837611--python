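import numpy as np
import pytest

from gaitmatch import (
    AccelerationTrace,
    DegenerateSignalError,
    EventSeries,
    InterleavingError,
    NoStepsFoundError,
    ResegmentationError,
    SegmentWindow,
    coefficient_signal,
    combine_heel_events,
    correlation_signal,
    detect_steps_heel_combined,
    detect_steps_lowback,
    detect_strides_heel,
    durations_from_events,
    resegment,
    sd_difference_signal,
    select_event_peaks,
    shift_events,
)
from gaitmatch.config import AlgorithmConfig, round_half_away
from gaitmatch.errors import GaitError


class TestResegment:
    def test_extends_one_tl_left_two_right(self):
        raw = AccelerationTrace(np.arange(1000.0), 100.0, "lower_back")
        reseg, window = resegment(raw, SegmentWindow(100, 600), 50)
        assert (window.start, window.end) == (50, 700)
        assert len(reseg) == 650

    def test_insufficient_left_margin(self):
        raw = AccelerationTrace(np.arange(1000.0), 100.0, "lower_back")
        with pytest.raises(ResegmentationError, match="left"):
            resegment(raw, SegmentWindow(30, 600), 50)

    def test_insufficient_right_margin(self):
        raw = AccelerationTrace(np.arange(700.0), 100.0, "lower_back")
        with pytest.raises(ResegmentationError, match="right"):
            resegment(raw, SegmentWindow(100, 620), 50)

    def test_nonpositive_tl_rejected(self):
        raw = AccelerationTrace(np.arange(100.0), 100.0, "lower_back")
        with pytest.raises(ValueError):
            resegment(raw, SegmentWindow(10, 50), 0)


def naive_sd_difference(reseg, template):
    tl = len(template)
    out = []
    for i in range(len(reseg) - tl + 1):
        d = reseg[i : i + tl] - template
        out.append(np.sqrt(np.mean((d - d.mean()) ** 2)))
    out = np.array(out)
    return out / out.max()


def naive_correlation(reseg, template):
    tl = len(template)
    t_range = template.max() - template.min()
    out = []
    for i in range(len(reseg) - tl + 1):
        win = reseg[i : i + tl]
        if np.ptp(win) == 0:
            out.append(0.0)
            continue
        corr = np.corrcoef(win, template)[0, 1]
        rho = np.ptp(win) / t_range
        out.append(corr * min(rho, 1.0 / rho))
    out = np.array(out)
    return out / out.max()


class TestMatchSignals:
    def test_exact_template_copy_gives_zero_sd(self, rng):
        template = rng.normal(size=30)
        reseg = np.concatenate([rng.normal(size=40), template, rng.normal(size=40)])
        sd = sd_difference_signal(reseg, template)
        assert sd[40] == 0.0

    def test_sd_is_offset_invariant(self, rng):
        template = rng.normal(size=30)
        reseg = np.concatenate([rng.normal(size=20), template + 4.2, rng.normal(size=20)])
        sd = sd_difference_signal(reseg, template)
        assert sd[20] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_sd_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        reseg, template = rng.normal(size=200), rng.normal(size=40)
        np.testing.assert_allclose(
            sd_difference_signal(reseg, template), naive_sd_difference(reseg, template),
            atol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_correlation_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        reseg, template = rng.normal(size=200), rng.normal(size=40)
        np.testing.assert_allclose(
            correlation_signal(reseg, template), naive_correlation(reseg, template),
            atol=1e-10,
        )

    def test_correlation_raw_values_identity_and_scale(self, rng):
        template = rng.normal(size=30)
        reseg = np.concatenate([template, 2.0 * template, -template])
        raw = correlation_signal(reseg, template, normalize=False)
        assert raw[0] == pytest.approx(1.0, abs=1e-12)  # corr 1, range ratio 1
        assert raw[30] == pytest.approx(0.5, abs=1e-12)  # corr 1, r = min(2, 1/2)
        assert raw[60] <= 0.0  # anticorrelated window

    def test_coefficient_peaks_at_embedded_template(self, rng):
        template = np.sin(2 * np.pi * np.arange(40) / 40.0)
        reseg = 0.1 * rng.normal(size=160)
        reseg[60:100] += template
        sd = sd_difference_signal(reseg, template)
        corr = correlation_signal(reseg, template)
        coeff = coefficient_signal(corr, sd)
        assert len(coeff) == len(reseg) - 40 + 1
        assert int(np.argmax(coeff)) == 60

    def test_coefficient_sign_follows_correlation(self):
        corr = np.array([-0.5, 0.2, 0.9])
        sd = np.array([0.5, 0.5, 0.5])
        coeff = coefficient_signal(corr, sd)
        assert coeff[0] < 0 < coeff[1] < coeff[2]


def oracle_select(coeff, tl, window, offset, shift_frac, dist_frac=0.60):
    shift = max(1, round_half_away(shift_frac * tl))
    cands = [i for i in range(1, len(coeff) - 1)
             if coeff[i] > coeff[i - 1] and coeff[i] > coeff[i + 1] and coeff[i] > 0
             and window.start - shift <= i + offset < window.end - shift]
    min_dist = max(1, round_half_away(dist_frac * tl))
    cap = len(window) // tl + 1
    kept = []
    for c in sorted(cands, key=lambda i: (-coeff[i], i)):
        if len(kept) >= cap:
            break
        if all(abs(c - k) >= min_dist for k in kept):
            kept.append(c)
    return sorted(k + offset for k in kept)


class TestSelectEventPeaks:
    def test_greedy_order_respects_heights(self):
        coeff = np.zeros(200)
        coeff[10], coeff[40], coeff[100] = 1.0, 2.0, 3.0
        window = SegmentWindow(0, 200)
        peaks = select_event_peaks(coeff, 50, window, 0, 0.15)
        # 40 and 10 are exactly round(0.6*50)=30 apart: inclusive rule keeps both
        assert list(peaks) == oracle_select(coeff, 50, window, 0, 0.15) == [10, 40, 100]
        coeff[10] = 0.0
        coeff[25] = 1.0  # 15 < 30 from the taller peak at 40: suppressed
        peaks = select_event_peaks(coeff, 50, window, 0, 0.15)
        assert list(peaks) == [40, 100]

    def test_monotone_signal_has_no_peaks(self):
        coeff = np.linspace(0.0, 1.0, 100)
        with pytest.raises(NoStepsFoundError):
            select_event_peaks(coeff, 50, SegmentWindow(0, 100), 0, 0.15)

    def test_spacing_exactly_min_distance_is_kept(self):
        coeff = np.zeros(200)
        coeff[50], coeff[80] = 1.0, 1.0  # distance 30 == round(0.6*50)
        peaks = select_event_peaks(coeff, 50, SegmentWindow(0, 200), 0, 0.15)
        assert list(peaks) == [50, 80]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coeff = rng.normal(size=300) + np.sin(2 * np.pi * np.arange(300) / 56.0)
        window = SegmentWindow(20, 260)
        got = select_event_peaks(coeff, 56, window, 5, 0.15)
        assert list(got) == oracle_select(coeff, 56, window, 5, 0.15)


class TestShiftAndDurations:
    def test_shift_lowback_fraction(self):
        ev = shift_events(np.array([20, 76]), 50, 0.15, 100.0, "lowback_accel")
        assert list(ev.events) == [28, 84]  # round(7.5) = 8

    def test_shift_heel_fraction(self):
        ev = shift_events(np.array([20, 76]), 100, 0.05, 100.0, "heel_accel_left")
        assert list(ev.events) == [25, 81]

    def test_empty_peaks_empty_series(self):
        ev = shift_events(np.array([], dtype=int), 50, 0.15, 100.0, "lowback_accel")
        assert len(ev) == 0

    def test_durations_forced_arithmetic(self):
        ev = EventSeries(np.array([28, 84, 140]), "lowback_accel", 100.0)
        np.testing.assert_allclose(durations_from_events(ev).durations_ms, [560.0, 560.0])
        ev2 = EventSeries(np.array([0, 100]), "lowback_accel", 100.0)
        np.testing.assert_allclose(durations_from_events(ev2).durations_ms, [1000.0])

    def test_single_event_rejected(self):
        ev = EventSeries(np.array([28]), "lowback_accel", 100.0)
        with pytest.raises(GaitError):
            durations_from_events(ev)


class TestCombineHeels:
    def test_alternating_merge_and_step_durations(self):
        left = EventSeries(np.array([100, 212]), "heel_accel_left", 100.0)
        right = EventSeries(np.array([156, 270]), "heel_accel_right", 100.0)
        combined = combine_heel_events(left, right)
        assert list(combined.events) == [100, 156, 212, 270]
        np.testing.assert_allclose(
            durations_from_events(combined).durations_ms, [560.0, 560.0, 580.0]
        )

    def test_unequal_lengths_still_alternate(self):
        left = EventSeries(np.array([100]), "heel_accel_left", 100.0)
        right = EventSeries(np.array([50, 156]), "heel_accel_right", 100.0)
        combined = combine_heel_events(left, right)
        assert list(combined.events) == [50, 100, 156]

    def test_same_foot_adjacency_is_error(self):
        left = EventSeries(np.array([100, 150]), "heel_accel_left", 100.0)
        right = EventSeries(np.array([300]), "heel_accel_right", 100.0)
        with pytest.raises(InterleavingError, match="100"):
            combine_heel_events(left, right)


class TestFullPipelines:
    def test_lowback_noiseless_recovers_truth(self, noiseless_trial):
        tr = noiseless_trial
        events, durations = detect_steps_lowback(tr.lowback, tr.segment_window)
        assert len(events) == len(tr.truth_all)
        assert np.abs(events.events - tr.truth_all).max() <= 2
        err = np.abs(durations.durations_ms - tr.truth_step_durations_samples_ms)
        assert err.mean() <= 20.0

    def test_lowback_noisy_keeps_exact_count(self, snr10_noise_sd):
        from gaitmatch import GaitParams, generate_trial

        tr = generate_trial(GaitParams(n_steps=10, noise_sd=snr10_noise_sd, seed=21))
        events, _ = detect_steps_lowback(tr.lowback, tr.segment_window)
        assert len(events) == len(tr.truth_all)

    def test_constant_signal_is_degenerate(self):
        raw = AccelerationTrace(np.zeros(2000) + 1.0, 100.0, "lower_back")
        with pytest.raises(DegenerateSignalError):
            detect_steps_lowback(raw, SegmentWindow(300, 1500))

    def test_heel_strides_and_combination(self, noiseless_trial):
        tr = noiseless_trial
        ev_l, dur_l = detect_strides_heel(tr.heel_left, tr.segment_window)
        assert len(ev_l) == len(tr.truth_left)
        assert np.abs(ev_l.events - tr.truth_left).max() <= 2
        assert np.abs(
            dur_l.durations_ms - np.diff(tr.truth_left) * 10.0
        ).max() <= 20.0
        combined, _ = detect_steps_heel_combined(tr.heel_left, tr.heel_right, tr.segment_window)
        assert len(combined) == len(tr.truth_all)

    def test_invert_ap_round_trip(self, noiseless_trial):
        tr = noiseless_trial
        flipped = AccelerationTrace(-tr.heel_left.samples, 100.0, "heel_left")
        cfg = AlgorithmConfig(invert_ap=True)
        ev_flip, _ = detect_strides_heel(flipped, tr.segment_window, cfg)
        ev, _ = detect_strides_heel(tr.heel_left, tr.segment_window)
        np.testing.assert_array_equal(ev_flip.events, ev.events)

    def test_pipeline_errors_carry_stage_notes(self):
        raw = AccelerationTrace(np.ones(2000) * 5.0, 100.0, "lower_back")
        try:
            detect_steps_lowback(raw, SegmentWindow(300, 1500))
        except DegenerateSignalError as exc:
            assert any("pipeline stage" in n for n in getattr(exc, "__notes__", []))
        else:  # pragma: no cover
            pytest.fail("expected a degenerate-signal error")


class TestInvariances:
    @pytest.mark.parametrize("transform", [lambda x: x + 3.7, lambda x: 5.1 * x,
                                           lambda x: 0.02 * x - 11.0])
    def test_events_invariant_to_offset_and_scale(self, jittered_trial, transform):
        tr = jittered_trial
        base, _ = detect_steps_lowback(tr.lowback, tr.segment_window)
        mod = AccelerationTrace(transform(tr.lowback.samples), 100.0, "lower_back")
        got, _ = detect_steps_lowback(mod, tr.segment_window)
        np.testing.assert_array_equal(got.events, base.events)
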