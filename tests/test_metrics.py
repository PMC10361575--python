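import numpy as np
import pytest

from ecochg.metrics import (
    SIGNIFICANCE_FLOOR_UV,
    cohort_summary,
    db_re_1uV,
    harmonic_magnitudes,
    residual_similarity,
    threshold_from_level_series,
    threshold_from_single_level,
    total_response,
)


@pytest.fixture
def library():
    rng = np.random.default_rng(0)
    theta = np.arange(100) / 100 * 2 * np.pi
    return [
        np.sin(theta) + 0.2 * rng.uniform() * np.sin(2 * theta + rng.uniform())
        for _ in range(5)
    ]


class TestResidualSimilarity:
    def test_exact_member(self, library):
        sim = residual_similarity(library[2], library)
        assert sim.best_library_match == 2
        assert sim.best_lag == 0
        assert sim.best_scale == pytest.approx(1.0)
        assert sim.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_scaled_shifted_member(self, library):
        query = 0.7 * np.roll(library[1], 17)
        sim = residual_similarity(query, library)
        assert sim.residual_rms <= 1e-9

    def test_scale_and_shift_invariance_of_query(self, library):
        rng = np.random.default_rng(1)
        query = library[0] + 0.3 * rng.normal(size=100)
        a = residual_similarity(query, library).residual_rms
        b = residual_similarity(3.7 * np.roll(query, 31), library).residual_rms
        assert a == pytest.approx(b, rel=1e-9)

    def test_empty_library(self):
        with pytest.raises(ValueError):
            residual_similarity(np.ones(10), [])


class TestTotalResponse:
    def test_no_significant_peaks(self):
        out = total_response({500.0: (0.001, 0.002, 0.0)})
        assert out.total_uv == 0.0
        assert out.total_db is None

    def test_single_peak_of_one_microvolt(self):
        out = total_response({500.0: (1.0, 0.0, 0.0)})
        assert out.total_uv == pytest.approx(1.0)
        assert out.total_db == pytest.approx(0.0)

    def test_hand_sum_across_frequencies(self):
        out = total_response({250.0: (2.0, 0.5, 0.0), 500.0: (1.0, 0.0, 0.0)})
        assert out.total_uv == pytest.approx(3.5)

    def test_explicit_significance_flags(self):
        out = total_response(
            {500.0: (2.0, 1.0, 0.5)},
            significance={500.0: (True, False, True)},
        )
        assert out.total_uv == pytest.approx(2.5)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            total_response({500.0: (-1.0, 0.0, 0.0)})

    def test_monotone_in_each_magnitude(self):
        low = total_response({500.0: (1.0, 0.5, 0.1)}).total_uv
        high = total_response({500.0: (1.5, 0.5, 0.1)}).total_uv
        assert high > low

    def test_harmonic_magnitudes_of_known_cycle(self):
        theta = np.arange(100) / 100 * 2 * np.pi
        cycle = 3.0 * np.sin(theta) + 0.5 * np.sin(2 * theta + 0.3)
        mags, flags = harmonic_magnitudes(cycle)
        assert mags[0] == pytest.approx(3.0, rel=1e-9)
        assert mags[1] == pytest.approx(0.5, rel=1e-9)
        assert flags[0] and flags[1] and not flags[2]


class TestDbConversion:
    @pytest.mark.parametrize("uv,db", [(1.0, 0.0), (10.0, 20.0)])
    def test_reference_points(self, uv, db):
        assert db_re_1uV(uv) == pytest.approx(db)

    def test_significance_floor_is_minus_34_db(self):
        assert round(db_re_1uV(SIGNIFICANCE_FLOOR_UV)) == -34

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            db_re_1uV(0.0)


class TestSingleLevelThreshold:
    def test_response_at_floor(self):
        est = threshold_from_single_level(0.02, 90.0)
        assert est.threshold_db == pytest.approx(90.0)

    def test_one_microvolt_at_90(self):
        est = threshold_from_single_level(1.0, 90.0)
        assert est.threshold_db == pytest.approx(90.0 - (0.0 - db_re_1uV(0.02)))
        assert est.threshold_db == pytest.approx(56.0, abs=0.03)

    def test_two_microvolts_at_90(self):
        est = threshold_from_single_level(2.0, 90.0)
        assert est.threshold_db == pytest.approx(50.0, abs=0.05)

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError, match="below significance floor"):
            threshold_from_single_level(0.01, 90.0)

    def test_round_trip_with_1db_per_db_decay(self):
        # synthesize a response decaying 1 dB/dB from a known threshold
        threshold = 37.0
        level = 85.0
        response = SIGNIFICANCE_FLOOR_UV * 10 ** ((level - threshold) / 20.0)
        est = threshold_from_single_level(response, level)
        assert est.threshold_db == pytest.approx(threshold, abs=1e-9)


class TestLevelSeriesThreshold:
    def test_interpolated_crossing(self):
        est = threshold_from_level_series([50.0, 40.0], [0.2, 0.01])
        assert 40.0 < est.threshold_db < 50.0
        # linear interpolation oracle in (level, dB response) space
        db_s, db_ns = db_re_1uV(0.2), db_re_1uV(0.01)
        db_floor = db_re_1uV(0.02)
        expected = 50.0 + (40.0 - 50.0) * (db_s - db_floor) / (db_s - db_ns)
        assert est.threshold_db == pytest.approx(expected)

    def test_all_significant_gives_lower_bound(self):
        est = threshold_from_level_series([60.0, 50.0, 40.0], [1.0, 0.5, 0.1])
        assert est.bound == "le"
        assert est.threshold_db == 40.0

    def test_none_significant_gives_upper_bound(self):
        est = threshold_from_level_series([60.0, 50.0], [0.01, 0.001])
        assert est.bound == "gt"
        assert est.threshold_db == 60.0

    def test_saturated_series_beats_single_level_estimate(self):
        # flat (saturated) top of the series: the measured threshold comes
        # out lower (better) than extrapolating from the 90 dB point alone
        levels = [90.0, 80.0, 70.0, 60.0, 50.0, 40.0]
        responses = [1.0, 1.0, 0.9, 0.3, 0.05, 0.01]
        series = threshold_from_level_series(levels, responses)
        single = threshold_from_single_level(responses[0], levels[0])
        assert series.threshold_db < single.threshold_db

    def test_bad_series_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_level_series([50.0, 45.0], [0.2, 0.01])
        with pytest.raises(ValueError):
            threshold_from_level_series([50.0], [0.2])


class TestCohortSummary:
    def test_mean_and_sd(self):
        out = cohort_summary({"g": [0.2, 0.4]})
        assert out.loc[0, "mean"] == pytest.approx(0.3)
        assert out.loc[0, "sd"] == pytest.approx(np.sqrt(0.02))

    def test_all_absent_group(self):
        out = cohort_summary({"g": [0.0, 0.0, 0.0]})
        assert out.loc[0, "fraction_absent"] == 1.0
        assert out.loc[0, "mean"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary({"g": []})
        with pytest.raises(ValueError):
            cohort_summary({})
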