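"""Synthetic trace generator: determinism, event statistics, ground truth."""

import dataclasses
import math

import numpy as np
import pytest

from beadpulse import SyntheticSpec, generate_experiment, generate_scan
from beadpulse.pipeline import SAMPLE_PAIRS, ChannelMap
from beadpulse.synth import default_signal_models


class TestValidation:
    def test_undersampled_pulse_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            SyntheticSpec(sample_rate=100.0, pulse_width_mean=0.05)

    def test_bead_loss_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(bead_loss=1.5)

    def test_crosstalk_off_diagonal_bound(self):
        with pytest.raises(ValueError):
            SyntheticSpec(crosstalk=((1.0, 1.0), (0.0, 1.0)))


class TestGenerateScan:
    def test_silent_configuration_gives_flat_zero_trace(self):
        spec = SyntheticSpec(event_rate=0.0, noise_sd=0.0, baseline_coeffs=(0.0,),
                             contaminant_rate=0.0)
        traces, truth = generate_scan(spec)
        for tr in traces.values():
            assert np.all(tr.y == 0.0)
        assert all(len(ct.event_times) == 0 for ct in truth.channels.values())

    def test_deterministic_under_seed(self):
        spec = SyntheticSpec(seed=123)
        t1, _ = generate_scan(spec)
        t2, _ = generate_scan(spec)
        for c in t1:
            np.testing.assert_array_equal(t1[c].y, t2[c].y)

    def test_different_seeds_differ(self):
        a, ta = generate_scan(SyntheticSpec(seed=1))
        b, tb = generate_scan(SyntheticSpec(seed=2))
        assert not np.array_equal(
            ta.channels["ch655"].event_times, tb.channels["ch655"].event_times
        )

    def test_event_count_matches_poisson_rate(self):
        """~1 bead/s: mean count over many seeds within 3 SE of rate*duration."""
        duration, rate = 30.0, 1.0
        counts = []
        for seed in range(500):
            spec = SyntheticSpec(duration=duration, sample_rate=200.0, event_rate=rate,
                                 bead_loss=0.0, contaminant_rate=0.0, seed=seed)
            _, truth = generate_scan(spec)
            counts.append(len(truth.channels["ch655"].event_times))
        mean = np.mean(counts)
        se = math.sqrt(rate * duration / len(counts))
        assert abs(mean - rate * duration) < 3 * se

    def test_bead_loss_thins_the_stream(self):
        kept, lost = [], []
        for seed in range(200):
            base = dict(duration=30.0, sample_rate=200.0, event_rate=1.0,
                        contaminant_rate=0.0, seed=seed)
            _, t0 = generate_scan(SyntheticSpec(bead_loss=0.0, **base))
            _, t1 = generate_scan(SyntheticSpec(bead_loss=0.5, **base))
            kept.append(len(t0.channels["ch655"].event_times))
            lost.append(len(t1.channels["ch655"].event_times))
        assert np.mean(lost) == pytest.approx(0.5 * np.mean(kept), rel=0.1)

    def test_single_event_apex_equals_baseline_plus_amplitude(self):
        spec = SyntheticSpec(event_rate=1.0 / 60.0, noise_sd=0.0, height_cv=0.0,
                             pulse_width_sd=0.0, contaminant_rate=0.0, bead_loss=0.0,
                             baseline_coeffs=(3.0,), seed=6)
        traces, truth = generate_scan(spec)
        ct = truth.channels["ch655"]
        assert len(ct.event_times) == 1
        tr = traces["ch655"]
        apex = np.argmax(tr.y)
        assert tr.y[apex] == pytest.approx(3.0 + ct.amplitudes[0], rel=1e-3)

    def test_truth_areas_are_analytic_gaussian_integrals(self):
        _, truth = generate_scan(SyntheticSpec(seed=3))
        for ct in truth.channels.values():
            np.testing.assert_allclose(
                ct.areas, ct.amplitudes * ct.widths * math.sqrt(2 * math.pi)
            )

    def test_empirical_pulse_area_matches_truth_as_noise_vanishes(self):
        """Integrating the noiseless trace over an isolated pulse reproduces
        the analytic amplitude*width*sqrt(2*pi) area."""
        spec = SyntheticSpec(event_rate=1.0 / 60.0, noise_sd=0.0, baseline_coeffs=(0.0,),
                             contaminant_rate=0.0, bead_loss=0.0, seed=8)
        traces, truth = generate_scan(spec)
        ct = truth.channels["ch605"]
        assert len(ct.event_times) == 1
        tr = traces["ch605"]
        empirical = np.trapezoid(tr.y, tr.t)
        assert empirical == pytest.approx(ct.areas[0], rel=1e-3)

    def test_identity_crosstalk_isolates_channels(self):
        """With no crosstalk, changing one channel's amplitude leaves the
        other channel's samples bit-identical (independent substreams)."""
        lo = SyntheticSpec(seed=17, amplitude_mean={"ch605": 15.0, "ch655": 6.5})
        hi = SyntheticSpec(seed=17, amplitude_mean={"ch605": 80.0, "ch655": 6.5})
        ta, _ = generate_scan(lo)
        tb, _ = generate_scan(hi)
        np.testing.assert_array_equal(ta["ch655"].y, tb["ch655"].y)
        assert not np.array_equal(ta["ch605"].y, tb["ch605"].y)

    def test_crosstalk_injects_into_other_channel(self):
        base = dict(seed=17, noise_sd=0.0, baseline_coeffs=(0.0,))
        clean, _ = generate_scan(SyntheticSpec(**base))
        mixed, _ = generate_scan(
            SyntheticSpec(crosstalk=((1.0, 0.2), (0.0, 1.0)), **base)
        )
        expected = clean["ch605"].y + 0.2 * clean["ch655"].y
        np.testing.assert_allclose(mixed["ch605"].y, expected, atol=1e-12)


class TestGenerateExperiment:
    def test_unknown_analyte_rejected(self):
        cm = ChannelMap()
        with pytest.raises(ValueError, match="unknown analyte"):
            generate_experiment([{"cortisol": 10.0}], SyntheticSpec(),
                                cm.channel_to_analyte)

    def test_blank_sequence_uses_background_amplitudes(self):
        cm = ChannelMap()
        models = default_signal_models()
        exp = generate_experiment([{}], SyntheticSpec(seed=2), cm.channel_to_analyte,
                                  models, seed=2)
        for channel, analyte in cm.channel_to_analyte.items():
            amp = exp.scans[0].spec.amplitude_mean[channel]
            assert amp == models[analyte].blank_amplitude

    def test_pair_sequence_orders_mean_amplitudes_with_concentration(self):
        """Pairs A-D: per-channel true mean amplitude follows concentration."""
        cm = ChannelMap()
        pairs = [SAMPLE_PAIRS[k] for k in "ABCD"]
        exp = generate_experiment(pairs, SyntheticSpec(seed=0), cm.channel_to_analyte,
                                  seed=0)
        for channel, analyte in cm.channel_to_analyte.items():
            amps = [s.spec.amplitude_mean[channel] for s in exp.scans]
            concs = [p[analyte] for p in pairs]
            assert np.all(np.argsort(amps) == np.argsort(concs))

    def test_repeated_call_bit_identical(self):
        cm = ChannelMap()
        pairs = [{}, SAMPLE_PAIRS["A"]]
        e1 = generate_experiment(pairs, SyntheticSpec(), cm.channel_to_analyte, seed=9)
        e2 = generate_experiment(pairs, SyntheticSpec(), cm.channel_to_analyte, seed=9)
        for c in e1.traces:
            np.testing.assert_array_equal(e1.traces[c].y, e2.traces[c].y)

    def test_boundaries_tile_the_run(self):
        cm = ChannelMap()
        exp = generate_experiment([{}, {}, {}], SyntheticSpec(duration=30.0),
                                  cm.channel_to_analyte, seed=1)
        assert exp.boundaries == [(0.0, 30.0), (30.0, 60.0), (60.0, 90.0)]
        assert len(exp.traces["ch605"].t) == 3 * 30 * 1000
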