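"""Baseline estimation, peak detection, area integration, scan summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadpulse import (
    Peak,
    SyntheticSpec,
    Trace,
    detect_peaks,
    estimate_baseline,
    generate_scan,
    peak_area,
    summarize_scan,
)


def gaussian_train(t, events):
    """Sum of (time, amplitude, sigma) Gaussian pulses on a grid."""
    y = np.zeros_like(t)
    for t0, a, s in events:
        y += a * np.exp(-0.5 * ((t - t0) / s) ** 2)
    return y


@pytest.fixture()
def grid():
    return np.arange(0, 30.0, 1e-3)


class TestBaseline:
    def test_exact_polynomial_recovered(self, grid):
        y = 1.5 + 0.3 * grid - 0.01 * grid**2
        trace = Trace(t=grid, y=y)
        base = estimate_baseline(trace, degree=2)
        assert np.max(np.abs(base - y)) < 1e-8

    def test_all_zero_trace_gives_zero_baseline(self, grid):
        base = estimate_baseline(Trace(t=grid, y=np.zeros_like(grid)))
        assert np.max(np.abs(base)) < 1e-12

    def test_flat_baseline_under_sparse_pulses(self, grid):
        events = [(3.0, 20.0, 0.05), (11.0, 15.0, 0.05), (22.0, 30.0, 0.05)]
        y = 5.0 + gaussian_train(grid, events)
        base = estimate_baseline(Trace(t=grid, y=y), degree=3)
        assert np.max(np.abs(base - 5.0)) < 0.02 * 5.0

    def test_degree_exceeding_samples_rejected(self):
        trace = Trace(t=np.array([0.0, 1.0, 2.0]), y=np.zeros(3))
        with pytest.raises(ValueError):
            estimate_baseline(trace, degree=3)


class TestDetection:
    def test_relative_ten_percent_rule(self, grid):
        """Apexes {100, 50, 9}: 9 < 10% of 100 is classified as noise."""
        events = [(5.0, 100.0, 0.05), (15.0, 50.0, 0.05), (25.0, 9.0, 0.05)]
        trace = Trace(t=grid, y=gaussian_train(grid, events))
        peaks = detect_peaks(trace, np.zeros_like(grid))
        assert len(peaks) == 2
        assert [round(p.apex_time) for p in peaks] == [5, 15]
        amps = sorted(p.amplitude for p in peaks)
        assert amps[0] == pytest.approx(50.0, rel=1e-3)
        assert amps[1] == pytest.approx(100.0, rel=1e-3)

    def test_single_pulse_apex_within_one_sample(self, grid):
        trace = Trace(t=grid, y=gaussian_train(grid, [(12.345, 10.0, 0.05)]))
        peaks = detect_peaks(trace, np.zeros_like(grid))
        assert len(peaks) == 1
        assert abs(peaks[0].apex_time - 12.345) <= 1e-3 + 1e-12

    def test_empty_trace_gives_empty_list(self):
        assert detect_peaks(Trace(t=np.array([]), y=np.array([])), np.array([])) == []

    def test_pure_noise_below_zero_gives_empty_list(self, grid):
        trace = Trace(t=grid, y=-np.ones_like(grid))
        assert detect_peaks(trace, np.zeros_like(grid)) == []

    def test_recovers_injected_events_against_ground_truth(self):
        """30 well-separated events, small noise: >= 29 found, none spurious."""
        rng = np.random.default_rng(0)
        t = np.arange(0, 30.0, 1e-3)
        times = np.arange(0.5, 30.0, 1.0) + rng.uniform(-0.2, 0.2, 30)
        amps = 10.0 * rng.lognormal(0, 0.2, 30)
        y = gaussian_train(t, [(t0, a, 0.05) for t0, a in zip(times, amps)])
        y += rng.normal(0, 0.05, len(t))
        trace = Trace(t=t, y=y)
        peaks = detect_peaks(trace, estimate_baseline(trace), min_distance_s=0.05)
        matched = sum(np.min(np.abs(times - p.apex_time)) < 0.1 for p in peaks)
        assert matched >= 29
        assert len(peaks) == matched  # no spurious detections

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.02, max_value=0.9))
    def test_raising_threshold_never_adds_peaks(self, threshold):
        spec = SyntheticSpec(seed=21)
        traces, _ = generate_scan(spec)
        trace = traces["ch605"]
        base = estimate_baseline(trace)
        n_ref = len(detect_peaks(trace, base, rel_threshold=0.10))
        n = len(detect_peaks(trace, base, rel_threshold=threshold))
        if threshold >= 0.10:
            assert n <= n_ref
        else:
            assert n >= n_ref

    def test_scale_equivariance(self):
        """Scaling the trace scales amplitudes/areas and keeps the peak set."""
        traces, _ = generate_scan(SyntheticSpec(seed=33))
        trace = traces["ch655"]
        c = 7.3
        scaled = Trace(t=trace.t, y=c * trace.y, channel=trace.channel)
        p1 = detect_peaks(trace, estimate_baseline(trace), min_distance_s=0.05)
        p2 = detect_peaks(scaled, estimate_baseline(scaled), min_distance_s=0.05)
        assert [p.apex_index for p in p1] == [p.apex_index for p in p2]
        a1 = np.array([p.amplitude for p in p1])
        a2 = np.array([p.amplitude for p in p2])
        np.testing.assert_allclose(a2, c * a1, rtol=1e-9)
        ar1 = np.array([p.area for p in p1])
        ar2 = np.array([p.area for p in p2])
        np.testing.assert_allclose(ar2, c * ar1, rtol=1e-9)


class TestArea:
    def test_triangle_area_exact_on_grid(self):
        t = np.arange(0, 2.0 + 1e-9, 1e-3)
        y = 10.0 * np.clip(1.0 - np.abs(t - 1.0) / 0.5, 0.0, None)
        trace = Trace(t=t, y=y)
        pk = Peak(apex_index=1000, apex_time=1.0, amplitude=10.0,
                  left_time=0.5, right_time=1.5)
        area = peak_area(trace, np.zeros_like(t), pk)
        assert area == pytest.approx(5.0, abs=1e-9)

    def test_gaussian_area_matches_analytic(self):
        sigma = 0.02
        t = np.arange(0, 1.0, 1e-3)
        y = 20.0 * np.exp(-0.5 * ((t - 0.5) / sigma) ** 2)
        trace = Trace(t=t, y=y)
        pk = Peak(apex_index=500, apex_time=0.5, amplitude=20.0,
                  left_time=0.5 - 4 * sigma, right_time=0.5 + 4 * sigma)
        area = peak_area(trace, np.zeros_like(t), pk)
        assert area == pytest.approx(20.0 * sigma * math.sqrt(2 * math.pi), rel=5e-3)

    def test_zero_height_peak_zero_area(self):
        t = np.arange(0, 1.0, 1e-3)
        trace = Trace(t=t, y=np.zeros_like(t))
        pk = Peak(apex_index=500, apex_time=0.5, amplitude=1.0,
                  left_time=0.4, right_time=0.6)
        assert peak_area(trace, np.zeros_like(t), pk) == 0.0

    def test_out_of_range_boundaries_rejected(self):
        t = np.arange(0, 1.0, 1e-3)
        trace = Trace(t=t, y=np.zeros_like(t))
        pk = Peak(apex_index=500, apex_time=0.5, amplitude=1.0,
                  left_time=-0.5, right_time=0.6)
        with pytest.raises(ValueError):
            peak_area(trace, np.zeros_like(t), pk)


def _peak_at(t):
    return Peak(apex_index=0, apex_time=t, amplitude=1.0,
                left_time=t - 0.01, right_time=t + 0.01, area=1.0)


class TestScanSummary:
    def test_ten_peaks_in_thirty_seconds_is_valid(self):
        peaks = [_peak_at(t) for t in np.linspace(1, 29, 10)]
        s = summarize_scan(peaks, (0.0, 30.0))
        assert s.valid and s.n_peaks == 10

    def test_nine_peaks_is_invalid_but_counted(self):
        peaks = [_peak_at(t) for t in np.linspace(1, 29, 9)]
        s = summarize_scan(peaks, (0.0, 30.0))
        assert not s.valid
        assert s.n_peaks == 9

    def test_every_full_window_must_pass(self):
        # 60-s scan: 10 peaks in the first 30 s, none later -> invalid.
        peaks = [_peak_at(t) for t in np.linspace(1, 29, 10)]
        s = summarize_scan(peaks, (0.0, 60.0))
        assert not s.valid

    def test_trailing_partial_window_exempt(self):
        # 45-s scan: only the first full 30-s window is checked.
        peaks = [_peak_at(t) for t in np.linspace(1, 29, 12)]
        s = summarize_scan(peaks, (0.0, 45.0))
        assert s.valid

    def test_f1_is_arithmetic_mean_of_areas(self):
        peaks = [_peak_at(5.0), _peak_at(10.0), _peak_at(15.0)]
        for p, a in zip(peaks, (2.0, 4.0, 6.0)):
            p.area = a
        s = summarize_scan(peaks, (0.0, 30.0), min_peaks_per_30s=3)
        assert s.F1 == pytest.approx(4.0)

    def test_no_peaks_gives_nan_f1(self):
        s = summarize_scan([], (0.0, 30.0))
        assert math.isnan(s.F1)
        assert not s.valid

    def test_f_ratio_uses_reference(self):
        peaks = [_peak_at(t) for t in np.linspace(1, 29, 10)]
        for p in peaks:
            p.area = 3.0
        s = summarize_scan(peaks, (0.0, 30.0), f0=1.5)
        assert s.F_ratio == pytest.approx(2.0)


class TestRobustness:
    def test_baseline_drift_absorbed_in_f1(self):
        """Injecting a cubic drift changes F1 by < 2%."""
        traces, _ = generate_scan(SyntheticSpec(seed=4))
        trace = traces["ch605"]

        def f1_of(y):
            tr = Trace(t=trace.t, y=y, channel="ch605")
            pks = detect_peaks(tr, estimate_baseline(tr), min_distance_s=0.05)
            return np.mean([p.area for p in pks])

        drift = 4.0 + 0.3 * trace.t - 0.012 * trace.t**2 + 1.2e-4 * trace.t**3
        f1_plain = f1_of(trace.y)
        f1_drift = f1_of(trace.y + drift)
        assert abs(f1_drift - f1_plain) / f1_plain < 0.02
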