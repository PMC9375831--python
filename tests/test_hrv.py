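"""RR intervals and HRV features: time, frequency, and nonlinear domains."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsebench import (
    PeakSeries,
    PeakValidation,
    RRSeries,
    SynthConfig,
    feature_vector,
    frequency_features,
    rr_intervals,
    sample_entropy,
    sliding_hr,
    synth_ppg,
    time_domain_features,
    validate_peaks,
)
from pulsebench.errors import DegenerateSeries, InsufficientData, UndefinedMetric


def validation_all_valid(indices, fs):
    pk = PeakSeries(np.asarray(indices, dtype=np.int64), fs)
    return PeakValidation(pk, np.ones(len(pk), dtype=bool), pk.ibi_ms())


def sampen_bruteforce(x, m=2, r_frac=0.2):
    """Independent template-counting oracle (explicit O(n^2) loops)."""
    x = np.asarray(x, float)
    r = r_frac * np.std(x, ddof=1)

    def count(mm):
        n = len(x) - m
        total = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.max(np.abs(x[i : i + mm] - x[j : j + mm])) <= r:
                    total += 1
        return total

    B, A = count(m), count(m + 1)
    if A == 0:
        return float("inf")
    return -math.log(A / B)


class TestRRIntervals:
    def test_uniform_peaks(self):
        rr = rr_intervals(validation_all_valid([0, 30, 60], 30.0))
        np.testing.assert_allclose(rr.rr_ms, [1000.0, 1000.0])

    def test_nonuniform_peaks(self):
        rr = rr_intervals(validation_all_valid([0, 15, 45, 75], 30.0))
        np.testing.assert_allclose(rr.rr_ms, [500.0, 1000.0, 1000.0])

    def test_interval_across_invalid_peak_excluded(self):
        pk = PeakSeries(np.array([0, 30, 60, 90, 120]), 30.0)
        valid = np.array([True, True, False, True, True])
        v = PeakValidation(pk, valid, pk.ibi_ms())
        rr = rr_intervals(v)
        # pairs (0,30) and (90,120) survive; nothing spans the invalid peak
        np.testing.assert_allclose(rr.rr_ms, [1000.0, 1000.0])

    def test_insufficient_valid_peaks(self):
        pk = PeakSeries(np.array([0, 30, 60]), 30.0)
        v = PeakValidation(pk, np.array([False, True, False]), pk.ibi_ms())
        with pytest.raises(InsufficientData):
            rr_intervals(v)


class TestTimeDomain:
    def test_constant_rr(self):
        f = time_domain_features(RRSeries([1000.0, 1000.0, 1000.0]))
        assert f["mean_hr"] == pytest.approx(60.0)
        assert f["ibi"] == pytest.approx(1000.0)
        assert f["rmssd"] == 0.0 and f["sdnn"] == 0.0 and f["nni20"] == 0

    def test_hand_computed_case(self):
        f = time_domain_features(RRSeries([800.0, 850.0, 900.0]))
        assert f["ibi"] == pytest.approx(850.0)
        assert f["mean_hr"] == pytest.approx(70.588, abs=0.001)
        assert f["rmssd"] == pytest.approx(50.0)
        assert f["sdnn"] == pytest.approx(50.0)
        assert f["nni20"] == 2

    def test_hr_from_mean_interval(self):
        # a mean RR of 745.18 ms corresponds to 60000/745.18 = 80.517 bpm
        rr = RRSeries([745.18, 745.18])
        assert time_domain_features(rr)["mean_hr"] == pytest.approx(80.517, abs=0.001)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=300.0, max_value=1400.0), min_size=2, max_size=40)
    )
    def test_hr_ibi_coupling_identity(self, rr_values):
        f = time_domain_features(RRSeries(rr_values))
        assert f["mean_hr"] * f["ibi"] == pytest.approx(60000.0, rel=1e-9)

    def test_sdnn_shift_invariance(self):
        rng = np.random.default_rng(2)
        base = 800 + rng.normal(0, 40, 30)
        f1 = time_domain_features(RRSeries(base))
        f2 = time_domain_features(RRSeries(base + 100.0))
        assert f2["sdnn"] == pytest.approx(f1["sdnn"])
        assert f2["ibi"] == pytest.approx(f1["ibi"] + 100.0)

    def test_too_short(self):
        with pytest.raises(InsufficientData):
            time_domain_features(RRSeries([800.0]))


class TestSampleEntropy:
    @pytest.mark.parametrize("n", [8, 12, 20, 30])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        x = 800 + rng.normal(0, 30, n)
        ours = sample_entropy(RRSeries(x), r_frac=0.5)
        oracle = sampen_bruteforce(x, r_frac=0.5)
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_periodic_below_noise(self):
        rng = np.random.default_rng(7)
        periodic = 800 + 25 * np.tile([1.0, -1.0], 15)
        noise = 800 + 25 * rng.standard_normal(30)
        assert sample_entropy(RRSeries(periodic), r_frac=0.5) < sample_entropy(
            RRSeries(noise), r_frac=0.5
        )

    def test_too_short(self):
        with pytest.raises(InsufficientData):
            sample_entropy(RRSeries([800.0, 810.0, 820.0]), m=2)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeries):
            sample_entropy(RRSeries([800.0] * 10))


class TestFrequencyFeatures:
    @staticmethod
    def modulated_tachogram(freq_hz, n=300, depth=50.0):
        t = np.cumsum(np.full(n, 0.8))
        return RRSeries(800.0 + depth * np.sin(2 * np.pi * freq_hz * t))

    def test_lf_modulation_dominates(self):
        f = frequency_features(self.modulated_tachogram(0.1))
        assert f["lf_hf"] > 5.0

    def test_hf_modulation_dominates(self):
        f = frequency_features(self.modulated_tachogram(0.3))
        assert f["hf"] > f["lf"]

    def test_equal_band_injection_ratio_near_one(self):
        n = 300
        t = np.cumsum(np.full(n, 0.8))
        rr = RRSeries(
            800.0
            + 30 * np.sin(2 * np.pi * 0.1 * t)
            + 30 * np.sin(2 * np.pi * 0.3 * t)
        )
        assert frequency_features(rr)["lf_hf"] == pytest.approx(1.0, abs=0.25)

    def test_short_span_rejected(self):
        with pytest.raises(InsufficientData):
            frequency_features(RRSeries([800.0] * 10))  # 8 s of data


class TestFeatureVector:
    def test_clean_series_has_all_core_features(self):
        rng = np.random.default_rng(4)
        rr = RRSeries(800 + rng.normal(0, 40, 200))
        features, status = feature_vector(rr)
        core = {"mean_hr", "ibi", "rmssd", "sdnn", "nni20", "sampen", "lf", "hf", "lf_hf"}
        assert core.issubset(features)
        assert all(v == "ok" for v in status.values())

    def test_short_series_reports_missing_frequency(self):
        features, status = feature_vector(RRSeries([800.0, 850.0, 900.0]))
        assert "mean_hr" in features and "lf" not in features
        assert status["frequency"].startswith("missing")
        assert "lf" not in features  # missing, not zero


class TestSlidingHr:
    def test_window_count_180s(self, clean_ppg_72):
        _, _, truth, _ = clean_ppg_72
        v = validate_peaks(truth)
        centers, hr = sliding_hr(v, 30.0, 1.0, duration_s=180.0)
        assert len(centers) == 151

    def test_steady_rate_recovered_everywhere(self):
        cfg = SynthConfig(hr_bpm=72.0, sdnn_ms=5.0, duration_s=120.0, seed=6)
        _, truth, _ = synth_ppg(cfg)
        v = validate_peaks(truth)
        _, hr = sliding_hr(v, 30.0, 1.0, duration_s=120.0)
        assert np.nanmax(np.abs(hr - 72.0)) < 1.0

    def test_empty_window_is_nan_not_zero(self):
        pk = PeakSeries(np.array([0, 30, 60, 2970, 3000]), 30.0)
        valid = np.array([True, True, True, True, True])
        v = PeakValidation(pk, valid, pk.ibi_ms())
        _, hr = sliding_hr(v, 30.0, 1.0, duration_s=100.0)
        assert np.isnan(hr).any() and not (hr == 0).any()

    def test_recording_shorter_than_window(self):
        v = validate_peaks(PeakSeries(np.arange(10) * 30, 30.0))
        with pytest.raises(InsufficientData):
            sliding_hr(v, 30.0, 1.0, duration_s=9.0)


class TestParameterRecovery:
    @pytest.mark.parametrize("target_sdnn", [10.0, 50.0, 100.0])
    def test_sdnn_recovered_within_15_percent(self, target_sdnn):
        cfg = SynthConfig(
            hr_bpm=70.0, sdnn_ms=target_sdnn, duration_s=180.0, rr_phi=0.7, seed=21
        )
        _, truth, _ = synth_ppg(cfg)
        v = validate_peaks(truth)
        measured = time_domain_features(rr_intervals(v))["sdnn"]
        assert measured == pytest.approx(target_sdnn, rel=0.15)
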