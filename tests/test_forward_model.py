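import numpy as np
import pytest

from ecochg.forward_model import (
    ANNParams,
    CMParams,
    CohortSpec,
    UnitPotentialShape,
    ann_waveform,
    cm_waveform,
    cycle_histogram,
    saturator,
    simulate_cohort,
    synthesize_average_cycle,
)
from ecochg.signal_core import StimulusSpec


class TestSaturator:
    def test_linear_limit(self, stim_500):
        w = cm_waveform(stim_500, CMParams(3.0, 0.7, 1e6, 1e6))
        theta = np.arange(100) / 100 * 2 * np.pi
        assert np.allclose(w, 3.0 * np.sin(theta + 0.7), atol=1e-4 * 3.0)

    def test_asymmetric_saturation_shape(self, stim_500):
        # flattened peak, fuller trough before rescaling
        theta = np.arange(1000) / 1000 * 2 * np.pi
        g = saturator(np.sin(theta), 0.2, 5.0)
        assert np.abs(g.min()) > g.max()

    def test_pointwise_against_dense_brute_force(self):
        # closed form vs direct evaluation of the piecewise definition
        xs = np.sin(np.array([0.0, np.pi / 2, np.pi, 1.1, -2.2]))
        s_p = s_t = 0.5
        expected = np.array(
            [
                s_p * (1 - np.exp(-x / s_p)) if x >= 0 else -s_t * (1 - np.exp(x / s_t))
                for x in xs
            ]
        )
        assert np.allclose(saturator(xs, s_p, s_t), expected, rtol=1e-12)

    def test_monotone_and_bounded(self):
        x = np.linspace(-50, 50, 10001)
        g = saturator(x, 0.3, 1.7)
        assert np.all(np.diff(g) >= 0)
        # open-interval bounds, reached only asymptotically (equality at
        # extreme drive is float round-off)
        assert g.max() <= 0.3 and g.min() >= -1.7
        assert saturator(np.array([1.0]), 0.3, 1.7)[0] < 0.3

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            saturator(np.zeros(3), -1.0, 1.0)
        with pytest.raises(ValueError):
            CMParams(1.0, 0.0, 0.0, 1.0)


class TestComponentWaveforms:
    @pytest.mark.parametrize("params", [
        CMParams(10.0, 0.3, 0.2, 5.0),
        CMParams(0.5, 4.0, 1e6, 1e6),
        CMParams(123.0, 2.0, 0.08, 0.4),
    ])
    def test_cm_amplitude_contract(self, stim_500, params):
        w = cm_waveform(stim_500, params)
        assert np.ptp(w) / 2 == pytest.approx(params.amplitude, rel=1e-9)

    @pytest.mark.parametrize("params", [
        ANNParams(3.0, 0.0),
        ANNParams(7.0, 0.9),
    ])
    def test_ann_amplitude_and_zero_mean(self, stim_500, params):
        w = ann_waveform(stim_500, params)
        assert np.ptp(w) / 2 == pytest.approx(params.amplitude, rel=1e-9)
        assert abs(np.mean(w)) < 1e-10 * params.amplitude

    def test_ann_zero_amplitude(self, stim_500):
        assert np.all(ann_waveform(stim_500, ANNParams(0.0)) == 0.0)

    def test_harmonic_distinctness_falls_with_frequency(self):
        # the unit potential has fixed time widths, so its phase footprint
        # widens with frequency and washes out ANN harmonics near 1 kHz
        def distinctness(freq):
            stim = StimulusSpec(freq, 70, sampling_rate=max(48000, 20 * freq))
            w = ann_waveform(stim, ANNParams(1.0, 0.3))
            spec = np.abs(np.fft.rfft(w)) ** 2
            return np.sum(spec[2:]) / spec[1]

        assert distinctness(1000) < distinctness(250)

    def test_unit_potential_exceeding_cycle_support(self):
        stim = StimulusSpec(4000, 70, sampling_rate=80000)
        with pytest.raises(ValueError, match="cycle support"):
            ann_waveform(stim, ANNParams(1.0, 0.3))

    def test_unit_potential_validation(self):
        with pytest.raises(ValueError):
            UnitPotentialShape(neg_width_ms=-0.1)
        with pytest.raises(ValueError):
            UnitPotentialShape(amplitudes=(1.0, 0.5))


class TestSynthesize:
    def test_cm_cancels_in_alternating(self, stim_500):
        rec = synthesize_average_cycle(CMParams(10.0, 0.8), ANNParams(0.0), stim_500)
        cond_rms = np.sqrt(np.mean(rec.condensation**2))
        assert np.sqrt(np.mean(rec.alternating**2)) < 1e-6 * cond_rms

    def test_alternating_dominated_by_second_harmonic(self, cm_ann_cycle):
        spec = np.abs(np.fft.rfft(cm_ann_cycle.alternating)) ** 2
        assert np.sqrt(np.mean(cm_ann_cycle.alternating**2)) > 0
        assert spec[2] > 0.5 * np.sum(spec[1:])

    def test_determinism(self, stim_500):
        a = synthesize_average_cycle(
            CMParams(5.0, 1.0, 0.5, 2.0), ANNParams(2.0, 0.4), stim_500,
            snr_db=20, seed=11,
        )
        b = synthesize_average_cycle(
            CMParams(5.0, 1.0, 0.5, 2.0), ANNParams(2.0, 0.4), stim_500,
            snr_db=20, seed=11,
        )
        assert np.array_equal(a.condensation, b.condensation)
        assert np.array_equal(a.rarefaction, b.rarefaction)

    def test_linearity_of_components(self, stim_500):
        cm, ann = CMParams(6.0, 1.2, 0.4, 2.0), ANNParams(2.5, 0.5)
        both = synthesize_average_cycle(cm, ann, stim_500)
        cm_only = synthesize_average_cycle(cm, ANNParams(0.0), stim_500)
        ann_only = synthesize_average_cycle(CMParams(0.0, 1.2), ann, stim_500)
        assert np.allclose(
            both.condensation, cm_only.condensation + ann_only.condensation
        )

    def test_nonfinite_snr_rejected(self, stim_500):
        with pytest.raises(ValueError):
            synthesize_average_cycle(
                CMParams(1.0), ANNParams(0.0), stim_500, snr_db=np.nan, seed=0
            )

    def test_snr_scaling(self, stim_500):
        rng_free = synthesize_average_cycle(CMParams(10.0, 0.3), ANNParams(0.0), stim_500)
        noisy = synthesize_average_cycle(
            CMParams(10.0, 0.3), ANNParams(0.0), stim_500, snr_db=20, seed=5
        )
        noise = noisy.condensation - rng_free.condensation
        signal_rms = np.sqrt(np.mean(rng_free.condensation**2))
        # one 100-sample draw: expect RMS near signal/10 within ~30%
        assert np.sqrt(np.mean(noise**2)) == pytest.approx(signal_rms / 10, rel=0.3)


class TestCohortSimulator:
    def test_record_counts_and_labels(self, small_cohort):
        spec = small_cohort.spec
        assert len(small_cohort) == spec.n_subjects * len(spec.frequencies) * len(
            spec.levels
        )
        frame = small_cohort.to_frame()
        low = frame[frame.frequency_hz <= 750]
        high = frame[frame.frequency_hz >= 2000]
        assert low.ann_present.all()
        assert not high.ann_present.any()

    def test_determinism_digest(self):
        spec = CohortSpec(preset="NH", n_subjects=2, seed=5,
                          frequencies=(500.0, 2000.0), levels=(50.0, 80.0))
        assert simulate_cohort(spec).digest() == simulate_cohort(spec).digest()

    def test_proportion_decreases_with_level(self):
        spec = CohortSpec(preset="NH", n_subjects=8, seed=2,
                          frequencies=(500.0,), levels=(30.0, 90.0))
        frame = simulate_cohort(spec).to_frame()
        p30 = frame[frame.level_db == 30].ann_proportion.mean()
        p90 = frame[frame.level_db == 90].ann_proportion.mean()
        assert p90 < p30

    def test_ka_reduces_ann(self):
        base = dict(n_subjects=6, seed=3, frequencies=(250.0, 500.0, 750.0),
                    levels=(40.0, 60.0, 80.0))
        nh = simulate_cohort(CohortSpec(preset="NH", **base)).to_frame()
        ka = simulate_cohort(CohortSpec(preset="NH_KA", **base)).to_frame()
        assert ka.ann_proportion.mean() < nh.ann_proportion.mean()

    def test_hfnihl_cm_plateau(self):
        base = dict(n_subjects=6, seed=4, frequencies=(500.0,),
                    levels=(30.0, 50.0, 70.0, 90.0))
        nh = simulate_cohort(CohortSpec(preset="NH", **base)).to_frame()
        hf = simulate_cohort(CohortSpec(preset="HFNIHL", **base)).to_frame()
        nh_growth = (
            nh[nh.level_db == 90].a_cm.mean() / nh[nh.level_db == 70].a_cm.mean()
        )
        hf_growth = (
            hf[hf.level_db == 90].a_cm.mean() / hf[hf.level_db == 70].a_cm.mean()
        )
        assert hf_growth < nh_growth

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            CohortSpec(preset="XX")

    def test_histogram_is_rectified_sine(self):
        h = cycle_histogram(100)
        theta = np.arange(100) / 100 * 2 * np.pi
        assert np.allclose(h, np.maximum(np.sin(theta), 0.0))
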