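import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sappa.errors import InsufficientTurnsError, MeasurementError
from sappa.integrator import Turn
from sappa.measure import (
    LEADLAG_FRACTION_PER_MS,
    assess_synchrony,
    cycle_completion_times,
    find_peaks,
    find_valleys,
    lead_lag,
    leadlag_fraction,
    mean_asynchrony,
    stimulus_reference_times,
)


class TestFindPeaks:
    def test_cosine_maxima_recovered(self):
        t = np.arange(0.0, 3.0, 1e-3)
        peaks = find_peaks(np.cos(2 * math.pi * t), t)
        assert peaks == pytest.approx([1.0, 2.0], abs=5e-4)

    def test_constant_signal_has_no_peaks(self):
        t = np.arange(0.0, 1.0, 1e-3)
        assert len(find_peaks(np.ones_like(t), t)) == 0

    def test_parabola_apex_interpolated_between_samples(self):
        # y = 1 - (t - apex)^2 sampled coarsely; the apex falls off-grid.
        apex = 0.5037
        t = np.arange(0.0, 1.0, 0.01)
        peaks = find_peaks(1 - (t - apex) ** 2, t)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(apex, abs=1e-6)

    def test_refinement_never_moves_peak_more_than_one_sample(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 5.0, 1e-2)
        sig = np.sin(2 * math.pi * t) + 0.1 * rng.standard_normal(len(t))
        raw_idx = np.flatnonzero(
            (sig[1:-1] > sig[:-2]) & (sig[1:-1] >= sig[2:])
        ) + 1
        refined = find_peaks(sig, t)
        for p in refined:
            assert np.min(np.abs(t[raw_idx] - p)) <= 1e-2 + 1e-12

    def test_valleys_are_negated_peaks(self):
        t = np.arange(0.0, 3.0, 1e-3)
        sig = np.cos(2 * math.pi * t)
        assert find_valleys(sig, t) == pytest.approx([0.5, 1.5, 2.5], abs=5e-4)

    def test_min_distance_suppresses_crest_ripple(self):
        t = np.arange(0.0, 2.0, 1e-3)
        sig = np.cos(2 * math.pi * (t - 0.5)) + 0.01 * np.cos(2 * math.pi * 40 * t)
        raw = find_peaks(sig, t)
        dedup = find_peaks(sig, t, min_distance_s=0.4)
        assert len(raw) > len(dedup)
        # Separation is enforced and both true crests survive deduplication.
        assert np.all(np.diff(dedup) >= 0.4 - 1e-9)
        for crest in (0.5, 1.5):
            assert np.min(np.abs(dedup - crest)) < 0.02


class TestCycleCompletionTimes:
    def test_uniform_rotation_crossings(self):
        t = np.arange(0.0, 5.0, 1e-3)
        z = np.exp(1j * 2 * math.pi * t)
        events = cycle_completion_times(z, t)
        assert events == pytest.approx([1.0, 2.0, 3.0, 4.0], abs=1e-9)

    def test_insensitive_to_amplitude_modulation(self):
        t = np.arange(0.0, 5.0, 1e-3)
        z = (1 + 0.3 * np.cos(2 * math.pi * 7 * t)) * np.exp(1j * 2 * math.pi * t)
        events = cycle_completion_times(z, t)
        assert events == pytest.approx([1.0, 2.0, 3.0, 4.0], abs=1e-6)


class TestAssessSynchrony:
    def test_constant_series_synchronized_from_start(self):
        ok, onset = assess_synchrony(np.full(12, -0.03))
        assert ok and onset == 0

    def test_steady_drift_never_synchronizes(self):
        ok, _ = assess_synchrony(np.arange(30) * 1e-3)
        assert not ok

    def test_onset_at_first_window_meeting_range_criterion(self):
        # Exponentially converging differences; compute the onset directly
        # from the window ranges.
        diffs = -0.05 * np.exp(-np.arange(25) / 3.0)
        ok, onset = assess_synchrony(diffs)
        windows = np.lib.stride_tricks.sliding_window_view(diffs, 5)
        ranges = windows.max(axis=1) - windows.min(axis=1)
        expected = int(np.nonzero(ranges >= 1e-3)[0][-1]) + 1
        assert ok and onset == expected

    def test_too_short_series_not_synchronized(self):
        ok, _ = assess_synchrony(np.zeros(4))
        assert not ok


class TestMeanAsynchrony:
    def test_reference_times_peak_and_valley(self):
        refs = stimulus_reference_times(2.0, 0.0, 2.0, mode="peak")
        assert refs == pytest.approx([0.0, 0.5, 1.0, 1.5, 2.0])
        refs = stimulus_reference_times(2.0, 0.0, 2.0, mode="valley")
        assert refs == pytest.approx([0.25, 0.75, 1.25, 1.75])

    def test_identical_event_trains_give_zero(self):
        peaks = np.arange(12, dtype=float)
        series = mean_asynchrony(peaks, fs=1.0, t_start=0.0, t_end=11.0)
        assert series.synchronized
        assert series.mean_ms == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_reported_exactly(self):
        peaks = np.arange(12, dtype=float) - 0.05
        series = mean_asynchrony(peaks, fs=1.0, t_start=0.0, t_end=11.0)
        assert series.mean_ms == pytest.approx(-50.0, abs=1e-9)
        assert series.sd_ms == pytest.approx(0.0, abs=1e-9)

    def test_antiphase_train_scored_against_valleys(self):
        peaks = np.arange(12, dtype=float) + 0.5
        valley_series = mean_asynchrony(peaks, fs=1.0, t_start=0.0, t_end=12.0, mode="valley")
        assert valley_series.mean_ms == pytest.approx(0.0, abs=1e-9)
        peak_series = mean_asynchrony(peaks, fs=1.0, t_start=0.0, t_end=12.0, mode="peak")
        assert abs(peak_series.mean_ms) == pytest.approx(500.0, abs=1e-6)

    @given(shift=st.floats(-0.2, 0.2))
    def test_shift_equivariance_below_quarter_period(self, shift):
        peaks = np.arange(3.0, 15.0)
        base = mean_asynchrony(peaks, fs=1.0, t_start=3.0, t_end=14.0)
        moved = mean_asynchrony(peaks + shift, fs=1.0, t_start=3.0, t_end=14.0)
        assert moved.mean_ms - base.mean_ms == pytest.approx(shift * 1e3, abs=1e-6)

    def test_no_model_peaks_is_an_error(self):
        with pytest.raises(MeasurementError):
            mean_asynchrony(np.empty(0), fs=1.0, t_start=0.0, t_end=5.0)

    def test_unsynchronized_series_has_undefined_mean(self):
        drift = np.arange(20, dtype=float) * 1.01  # 10 ms/cycle drift
        series = mean_asynchrony(drift, fs=1.0, t_start=0.0, t_end=19.0)
        assert not series.synchronized
        assert math.isnan(series.mean_ms) and math.isnan(series.sd_ms)


def _three_turn_setup(x1: float, x2: float, y: float):
    """Turns of 1 s; oscillator claps at the seams with adjustable offsets.

    For the middle turn (held by oscillator 1): a1 = 1 + x1, b1 = 1,
    a2 = 2 + y, b2 = 2 + x2, so L = x1 + (x2 - y).
    """
    turns = [Turn(0.0, 1.0, 0), Turn(1.0, 2.0, 1), Turn(2.0, 3.0, 0)]
    claps0 = np.array([0.0, 1.0, 2.0 + x2, 3.0])
    claps1 = np.array([1.0 + x1, 2.0 + y])
    return (claps0, claps1), turns


class TestLeadLag:
    def test_abutting_turns_give_zero(self):
        claps, turns = _three_turn_setup(0.0, 0.0, 0.0)
        result = lead_lag(claps, turns, skip_turns=1)
        assert result.per_turn_L_s == pytest.approx([0.0])
        assert result.mean_fraction == pytest.approx(0.0)

    def test_eq9_hand_example_positive_L(self):
        # a1-b1 = +10 ms, b2-a2 = -5 ms -> L = 5 ms, fraction -0.0075.
        claps, turns = _three_turn_setup(0.010, 0.005, 0.010)
        result = lead_lag(claps, turns, skip_turns=1)
        assert result.per_turn_L_s == pytest.approx([0.005])
        assert result.per_turn_fraction == pytest.approx([-0.0075])

    def test_eq9_hand_example_negative_L(self):
        # a1-b1 = -20 ms, b2-a2 = -20 ms -> L = -40 ms, fraction +0.06.
        claps, turns = _three_turn_setup(-0.020, -0.020, 0.0)
        result = lead_lag(claps, turns, skip_turns=1)
        assert result.per_turn_L_s == pytest.approx([-0.040])
        assert result.per_turn_fraction == pytest.approx([0.06])

    def test_fewer_than_three_turns_is_an_error(self):
        claps = (np.array([0.0, 1.0]), np.array([0.5]))
        with pytest.raises(InsufficientTurnsError):
            lead_lag(claps, [Turn(0.0, 1.0, 0), Turn(1.0, 2.0, 1)])

    @given(L_ms=st.floats(-100, 100))
    def test_fraction_conversion_is_linear_in_L(self, L_ms):
        assert leadlag_fraction(L_ms * 1e-3) == pytest.approx(
            LEADLAG_FRACTION_PER_MS * L_ms
        )
        assert leadlag_fraction(0.0) == 0.0
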