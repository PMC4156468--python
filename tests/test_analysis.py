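"""Oscillation detection, phase statistics and the synchronization index."""

import numpy as np
import pytest

from fofr.analysis import (InsufficientDataError, burst_phases,
                           compute_phases, detect_oscillation,
                           estimate_period_amplitude, phase_sd, sync_index)

HOUR = 3600.0


def _grid(hours, dt=20.0):
    return np.arange(0.0, hours * HOUR + dt / 2, dt)


class TestDetectOscillation:
    def test_constant_series_is_not_oscillating(self):
        t = _grid(21)
        assert not detect_oscillation(t, np.full(t.size, 5.0)).oscillating

    def test_sine_above_threshold_detected_with_period(self):
        t = _grid(21)
        x = 10.0 + 2.0 * np.sin(2 * np.pi * t / (30 * 60.0))
        st = detect_oscillation(t, x)
        assert st.oscillating
        assert st.period_min == pytest.approx(30.0, rel=0.02)
        assert st.amplitude == pytest.approx(2.0, rel=0.05)

    def test_sine_below_relative_threshold_rejected(self):
        t = _grid(21)
        x = 10.0 + 0.4 * np.sin(2 * np.pi * t / (30 * 60.0))  # 8% p2t
        assert not detect_oscillation(t, x).oscillating

    def test_damped_oscillation_rejected(self):
        t = _grid(21)
        x = 10.0 + 5.0 * np.exp(-t / (2 * HOUR)) * np.sin(
            2 * np.pi * t / (30 * 60.0))
        assert not detect_oscillation(t, x).oscillating

    def test_short_series_is_undefined_not_false(self):
        t = _grid(10)
        x = 10.0 + 2.0 * np.sin(2 * np.pi * t / (30 * 60.0))
        with pytest.raises(InsufficientDataError):
            detect_oscillation(t, x)


class TestPeriodAmplitude:
    def test_synthetic_sine_period(self):
        t = _grid(6)
        x = 3.0 + np.sin(2 * np.pi * t / (30 * 60.0))
        per, amp = estimate_period_amplitude(t, x)
        assert per == pytest.approx(30.0, abs=0.5)
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_too_few_peaks_raises(self):
        t = _grid(1)
        x = np.sin(2 * np.pi * t / (50 * 60.0))
        with pytest.raises(InsufficientDataError):
            estimate_period_amplitude(t, x)

    def test_peak_picking_agrees_with_spectral_estimate(self, free_run_8h):
        """Independent spectral oracle: the periodogram peak of the
        firing-rate series agrees with peak-picking within 5%."""
        from scipy.signal import periodogram
        t, x = free_run_8h.t, free_run_8h.firing_rate
        sel = t >= 2.5 * HOUR
        per, _ = estimate_period_amplitude(t[sel], x[sel])
        f, pxx = periodogram(x[sel] - x[sel].mean(), fs=1.0 / (t[1] - t[0]))
        per_spec = 1.0 / f[1 + np.argmax(pxx[1:])] / 60.0
        assert abs(per_spec - per) / per < 0.05


class TestPhases:
    def test_rectangular_burst_center_of_mass(self):
        t = _grid(24, dt=60.0)
        x = np.zeros(t.size)
        x[(t >= 5 * HOUR) & (t <= 7 * HOUR)] = 4.0
        ph = compute_phases(t, x[None, :])
        assert ph.shape == (1, 1)
        assert ph[0, 0] == pytest.approx(6 * HOUR, abs=60.0)

    def test_constant_activity_phase_at_midpoint(self):
        t = _grid(24, dt=60.0)
        ph = compute_phases(t, np.full((1, t.size), 3.0))
        assert ph[0, 0] == pytest.approx(12 * HOUR, rel=0.01)

    def test_zero_window_gives_nan(self):
        t = _grid(24, dt=60.0)
        ph = compute_phases(t, np.zeros((1, t.size)))
        assert np.isnan(ph[0, 0])

    def test_negative_activity_rejected(self):
        t = _grid(24, dt=60.0)
        with pytest.raises(ValueError):
            compute_phases(t, -np.ones((1, t.size)))

    def test_known_phase_shifts_recovered(self):
        """Cells whose activity is a shifted copy of the same waveform get
        center-of-mass phases separated by the shifts."""
        t = _grid(24, dt=60.0)
        shifts = np.array([0.0, 1.0, 3.0]) * HOUR
        A = np.stack([np.exp(-0.5 * ((t - 10 * HOUR - s) / HOUR) ** 2)
                      for s in shifts])
        ph = compute_phases(t, A)
        d = ph[0] - ph[0][0]
        np.testing.assert_allclose(d, shifts, atol=120.0)

    def test_burst_phases_of_shifted_trains(self):
        """Burst-peak phases of identical spike trains shifted by known
        offsets recover those offsets modulo the period."""
        t = np.arange(0.0, 6 * HOUR, 10.0)
        T = 30 * 60.0
        offs = [0.0, 300.0, 600.0]
        A = np.stack([np.maximum(np.sin(2 * np.pi * (t - o) / T), 0.0) ** 4
                      for o in offs])
        ph, period = burst_phases(t, A, t_start=HOUR, t_stop=6 * HOUR)
        assert period == pytest.approx(T, rel=0.02)
        d = (ph - ph[0]) % period
        np.testing.assert_allclose(d, offs, atol=30.0)


class TestSyncIndex:
    def test_identical_phases_give_one(self):
        assert sync_index(np.full(10, 3.3), 24.0) == pytest.approx(1.0)

    def test_antiphase_pair_gives_zero(self):
        assert sync_index(np.array([0.0, 12.0]), 24.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_uniform_random_phases_near_zero(self):
        """Monte-Carlo oracle: for n=1000 uniform phases SI is O(n^-1/2)."""
        rng = np.random.default_rng(42)
        vals = [sync_index(rng.uniform(0, 24.0, 1000), 24.0)
                for _ in range(20)]
        assert np.mean(vals) < 3.0 / np.sqrt(1000)

    def test_invariant_under_common_shift(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(0, 24.0, 50)
        a = sync_index(ph, 24.0)
        b = sync_index((ph + 7.31) % 24.0, 24.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            si = sync_index(rng.uniform(0, 24.0, 7), 24.0)
            assert 0.0 <= si <= 1.0

    def test_needs_two_phases(self):
        with pytest.raises(ValueError):
            sync_index(np.array([1.0]), 24.0)


class TestPhaseSD:
    def test_tight_cluster_matches_ordinary_sd(self):
        rng = np.random.default_rng(3)
        ph = 5.0 + 0.1 * rng.standard_normal(2000)
        assert phase_sd(ph, 24.0) == pytest.approx(ph.std(), rel=0.02)

    def test_nonnegative(self):
        assert phase_sd(np.array([1.0, 2.0, 3.0]), 24.0) >= 0.0
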