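import numpy as np
import pytest

from ecochg.errors import DegenerateCycleError, InsufficientSteadyStateError
from ecochg.forward_model import ANNParams, CMParams, cm_waveform, synthesize_average_cycle
from ecochg.signal_core import (
    AverageCycle,
    SteadyStateWindow,
    StimulusSpec,
    SweepRecording,
    alignment_shift,
    average_cycle,
    combine_phases,
    extract_cycles,
    normalize_and_align,
)


def _burst(frequency=500.0, rate=48000.0, n_cycles=20, phase=0.0):
    duration_ms = n_cycles / frequency * 1000.0
    stim = StimulusSpec(frequency, 70, burst_duration_ms=duration_ms,
                        sampling_rate=rate)
    t = np.arange(int(round(duration_ms / 1000 * rate))) / rate
    return SweepRecording(np.sin(2 * np.pi * frequency * t + phase), stim)


class TestExtractCycles:
    def test_counts_and_length_for_stated_window(self):
        # 500 Hz at 48 kHz, 20 cycles, skip 2 onset + 1 offset -> 17 x 96
        cycles = extract_cycles(_burst(), SteadyStateWindow(2, 1))
        assert len(cycles) == 17
        assert all(len(c) == 96 for c in cycles)

    def test_pure_sinusoid_gives_identical_cycles(self):
        cycles = extract_cycles(_burst(phase=0.4))
        ref = cycles[0]
        for c in cycles[1:]:
            assert np.allclose(c, ref, rtol=1e-9, atol=1e-9 * np.max(np.abs(ref)))

    def test_fractional_samples_per_cycle_no_drift(self):
        # 750 Hz at 48 kHz -> 64 samples exactly; 440 Hz -> 109.09 samples
        cycles = extract_cycles(_burst(frequency=440.0, n_cycles=22))
        assert all(len(c) == 109 for c in cycles)
        assert np.allclose(cycles[0], cycles[-1], atol=1e-6)

    def test_too_short_burst_raises(self):
        with pytest.raises(InsufficientSteadyStateError):
            extract_cycles(_burst(n_cycles=3), SteadyStateWindow(2, 1))


class TestAverageCycle:
    def test_idempotent_on_identical_cycles(self):
        c = np.sin(np.linspace(0, 2 * np.pi, 96, endpoint=False))
        assert np.allclose(average_cycle([c] * 5), c)

    def test_cancellation(self):
        c = np.random.default_rng(0).normal(size=96)
        assert np.allclose(average_cycle([c, -c]), 0.0)

    def test_noise_averaging_follows_sqrt_n_law(self):
        # mean RMS of the average of 100 unit-variance cycles ~ 0.1
        rng = np.random.default_rng(42)
        rms = [
            np.sqrt(np.mean(average_cycle(list(rng.normal(size=(100, 64)))) ** 2))
            for _ in range(200)
        ]
        se = np.std(rms) / np.sqrt(len(rms))
        assert abs(np.mean(rms) - 0.1) < 3 * se + 5e-4

    def test_errors(self):
        with pytest.raises(ValueError):
            average_cycle([])
        with pytest.raises(ValueError):
            average_cycle([np.zeros(10), np.zeros(11)])


class TestCombinePhases:
    def test_pure_odd_component(self):
        s = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        out = combine_phases(s, -s)
        assert np.allclose(out["difference"], s)
        assert np.allclose(out["alternating"], 0.0)

    def test_pure_even_component(self):
        r = np.maximum(np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False)), 0)
        out = combine_phases(r, r)
        assert np.allclose(out["alternating"], r)
        assert np.allclose(out["difference"], 0.0)

    def test_exact_linear_bijection(self):
        rng = np.random.default_rng(1)
        cond, rare = rng.normal(size=(2, 100))
        out = combine_phases(cond, rare)
        assert np.allclose(out["alternating"] + out["difference"], cond)
        assert np.allclose(out["alternating"] - out["difference"], rare)

    def test_component_separation_on_forward_model(self, stim_500):
        rec = synthesize_average_cycle(
            CMParams(7.0, 1.0, 0.5, 3.0), ANNParams(3.0, 0.6), stim_500
        )
        # difference retains the CM (odd part); alternating only ANN harmonics
        spec_alt = np.abs(np.fft.rfft(rec.alternating))
        assert spec_alt[2] > 5 * spec_alt[1]  # 2 f0 dominates the alternating
        cm_only = cm_waveform(stim_500, CMParams(7.0, 1.0, 0.5, 3.0))
        # the difference waveform is CM-dominated: the generating CM carries
        # several times the energy of the leftover (the ANN's odd part)
        ann_odd = rec.difference - cm_only
        assert np.sum(cm_only**2) > 2 * np.sum(ann_odd**2)
        # and the alternating waveform contains no CM fundamental
        assert np.abs(np.fft.rfft(rec.alternating))[1] < 1e-9

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_phases(np.zeros(10), np.zeros(12))


class TestNormalizeAndAlign:
    def test_sine_at_arbitrary_phase(self):
        theta = np.arange(96) / 96 * 2 * np.pi
        out = normalize_and_align(5 * np.sin(theta + 1.2), 100)
        target = np.sin(np.arange(100) / 100 * 2 * np.pi)
        assert len(out) == 100
        assert np.ptp(out) / 2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(out, target, atol=1e-6)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        theta = np.arange(100) / 100 * 2 * np.pi
        y = np.sin(theta + 0.7) + 0.3 * np.sin(2 * theta + 0.2)
        once = normalize_and_align(y, 100)
        twice = normalize_and_align(once, 100)
        assert np.max(np.abs(twice - once)) < 1e-6

    def test_alignment_recovers_generating_phase(self, stim_500):
        phi = 2.3
        w = cm_waveform(stim_500, CMParams(5.0, phi, 0.3, 2.0))
        shift = alignment_shift(w)
        # the saturated CM's fundamental sits at the generating phase, so the
        # alignment shift must undo it (mod one period)
        assert ((-shift * 2 * np.pi - phi) % (2 * np.pi)) == pytest.approx(
            0.0, abs=2 * np.pi / 100
        ) or ((-shift * 2 * np.pi - phi) % (2 * np.pi)) == pytest.approx(
            2 * np.pi, abs=2 * np.pi / 100
        )

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateCycleError):
            normalize_and_align(np.full(64, 2.5), 100)
        with pytest.raises(ValueError):
            normalize_and_align(np.sin(np.arange(64)), 16)


class TestAverageCycleContainer:
    def test_end_to_end_reproduces_generating_cycle(self):
        # noiseless forward burst -> extract + average == generating cycle
        frequency, rate = 500.0, 48000.0
        stim = StimulusSpec(frequency, 70, burst_duration_ms=40,
                            sampling_rate=rate)
        gen = cm_waveform(stim, CMParams(5.0, 0.9, 0.4, 2.0), n_points=96)
        waveform = np.tile(gen, 20)
        rec = SweepRecording(waveform, stim)
        avg = average_cycle(extract_cycles(rec))
        rel = np.sqrt(np.mean((avg - gen) ** 2)) / np.sqrt(np.mean(gen**2))
        assert rel < 1e-4

    def test_tensor_channels_normalized(self, cm_ann_cycle):
        t = cm_ann_cycle.tensor()
        assert t.shape == (100, 4)
        for ch in range(4):
            half_pp = np.ptp(t[:, ch]) / 2
            assert half_pp == pytest.approx(1.0, abs=1e-9) or half_pp == 0.0

    def test_zero_alternating_channel_stored_as_zeros(self, stim_500):
        rec = synthesize_average_cycle(
            CMParams(10.0, 0.5), ANNParams(0.0), stim_500
        )
        assert np.all(rec.tensor()[:, 3] == 0.0)
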