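import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctgfusion.features import (AUTOCORR_FEATURES, EMG_FEATURES, FAMILY_SIZES,
                                FEATURE_NAMES, MORPH_FEATURES,
                                SPECTRAL_FEATURES, TIME_FEATURES,
                                FeatureConfig, autocorr_features,
                                autocorrelation, emg_features,
                                estimate_baseline, extract_all,
                                morphological_features,
                                spectral_band_energies, time_features)

FS = 4.0


def brute_force_acf(x, n_lags):
    """O(N^2) definitional autocorrelation oracle."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = sum(v * v for v in xc)
    out = []
    for k in range(1, n_lags + 1):
        s = sum(xc[i] * xc[i + k] for i in range(len(x) - k))
        out.append(s / denom if denom else 0.0)
    return np.array(out)


class TestTimeFeatures:
    def test_constant_signal_degenerate_conventions(self):
        f = time_features(np.full(100, 140.0))
        assert f["mean"] == 140.0
        assert f["std"] == 0.0
        assert f["mad"] == 0.0
        assert f["diff"] == 0.0
        assert f["skew"] == 0.0
        assert f["kurtosis"] == 0.0
        assert f["pulseindicator"] == 1.0
        assert f["cumsum"] == 100 * 140.0

    def test_direct_arithmetic(self):
        f = time_features(np.array([120.0, 124.0, 128.0, 132.0]))
        assert f["mean"] == 126.0
        assert f["diff"] == 12.0  # telescoped sum of successive differences

    def test_exactly_the_documented_keys(self, synthetic_segment):
        assert tuple(time_features(synthetic_segment)) == TIME_FEATURES


class TestSpectralBandEnergies:
    def test_constant_signal_all_zero(self):
        f = spectral_band_energies(np.full(2400, 140.0), sampling_rate=FS)
        assert all(v == 0.0 for v in f.values())

    def test_pure_tone_lands_in_its_band(self):
        t = np.arange(2400) / FS  # 60 cycles of 0.1 Hz: integer count
        x = 140 + 10 * np.sin(2 * np.pi * 0.1 * t)
        f = spectral_band_energies(x, sampling_rate=FS)
        total = sum(f.values())
        assert f["SP_VLF"] / total >= 0.99  # 0.1 Hz is in (0.03, 0.15]

    def test_energy_conservation_when_bands_tile(self, synthetic_segment):
        x = synthetic_segment.samples
        f = spectral_band_energies(x, sampling_rate=FS)
        power = np.abs(np.fft.rfft(x - x.mean())) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        total = power[freqs > 0].sum()
        assert sum(f.values()) == pytest.approx(total, rel=1e-8)

    @pytest.mark.parametrize("edges", [(0.0, 0.5), (0.0, 0.2, 0.1, 0.3, 0.5),
                                       (0.0, 0.1, 0.2, 0.3, 3.0)])
    def test_malformed_edges_rejected(self, edges):
        with pytest.raises(ValueError):
            spectral_band_energies(np.ones(64), band_edges=edges,
                                   sampling_rate=FS)


class TestAutocorrFeatures:
    @given(arrays(float, st.integers(8, 64),
                  elements=st.floats(-100, 100, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_acf_equals_brute_force_oracle(self, x):
        n_lags = min(6, x.size - 2)
        if n_lags < 1:
            return
        np.testing.assert_allclose(autocorrelation(x, n_lags),
                                   brute_force_acf(x, n_lags),
                                   rtol=1e-9, atol=1e-9)

    def test_monotone_acf_has_no_extrema(self):
        # AR(1)-like smoothly decaying series -> strictly decreasing acf
        x = np.sin(np.arange(300) / 200.0) * 50 + 140
        f = autocorr_features(x, n_lags=40)
        assert f["MAX_MINS"] == 0
        assert all(f[k] == 0.0 for k in AUTOCORR_FEATURES if k != "MAX_MINS")

    def test_periodic_signal_peak_near_period(self):
        x = 140 + 10 * np.sin(2 * np.pi * np.arange(2400) / 40.0)
        r = autocorrelation(x, 240)
        interior = r[1:-1]
        maxima_lags = 2 + np.flatnonzero(
            (interior > r[:-2]) & (interior > r[2:]))
        assert np.any(np.abs(maxima_lags - 40) <= 1)

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            autocorr_features(np.arange(100.0), n_lags=2)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            autocorr_features(np.arange(10.0), n_lags=240)


class TestEmgFeatures:
    def test_constant_signal(self):
        f = emg_features(np.full(50, 3.0))
        assert f["card"] == 1.0
        assert f["zc"] == 0.0
        assert f["wl"] == 0.0
        assert f["ae"] == 9.0
        assert f["ssc"] == 0.0

    def test_alternating_signal_direct_definitions(self):
        f = emg_features(np.array([1.0, -1.0, 1.0, -1.0]))
        assert f["zc"] == 3.0
        assert f["wl"] == 6.0
        assert f["mav"] == 1.0
        assert f["rms"] == 1.0
        assert f["iemg"] == 4.0

    def test_cardinality_counts_distinct_values(self):
        assert emg_features(np.array([1.0, 2.0, 2.0, 3.0]))["card"] == 3.0

    def test_returns_all_36_keys(self, synthetic_segment):
        assert tuple(emg_features(synthetic_segment.samples)) == EMG_FEATURES

    def test_shift_invariance_of_shape_features(self, synthetic_segment):
        x = synthetic_segment.samples
        a = emg_features(x)
        b = emg_features(x + 37.0)
        for key in ("zc", "ssc", "wa", "myop", "wl", "damv", "dasdv", "fzc"):
            assert a[key] == pytest.approx(b[key]), key

    def test_shift_changes_amplitude_features(self, synthetic_segment):
        x = synthetic_segment.samples
        a, b = emg_features(x), emg_features(x + 37.0)
        assert a["iemg"] != b["iemg"]
        assert a["mav"] != b["mav"]


class TestTimeFeatureShiftInvariance:
    def test_moments_invariant_under_offset(self, synthetic_segment):
        x = synthetic_segment.samples
        a, b = time_features(x), time_features(x + 25.0)
        for key in ("std", "mad", "skew", "kurtosis"):
            assert a[key] == pytest.approx(b[key]), key
        assert b["mean"] == pytest.approx(a["mean"] + 25.0)


class TestBaseline:
    def test_constant_signal_fixed_point(self):
        b = estimate_baseline(np.full(2400, 140.0), sampling_rate=FS)
        np.testing.assert_allclose(b.values, 140.0)

    def test_excursion_is_trimmed_out(self):
        x = np.full(2400, 140.0)
        x[1000:1080] += 20.0  # +20 bpm for 20 s
        b = estimate_baseline(x, sampling_rate=FS)
        assert np.all(b.values >= 138.0)
        assert np.all(b.values <= 142.0)

    def test_iteration_deltas_decrease_to_tolerance(self, synthetic_segment):
        b = estimate_baseline(synthetic_segment.samples, sampling_rate=FS)
        d = b.iteration_deltas
        assert len(d) >= 1
        assert all(x2 <= x1 + 1e-9 for x1, x2 in zip(d, d[1:]))
        assert d[-1] < FeatureConfig().baseline_tol_bpm or len(d) == 10

    def test_output_in_physiological_range(self, synthetic_segment):
        b = estimate_baseline(synthetic_segment.samples, sampling_rate=FS)
        assert np.all((b.values >= 50) & (b.values <= 200))


class TestMorphologicalFeatures:
    def _flat(self, n=2400):
        return np.full(n, 140.0)

    def test_flat_signal_no_events(self):
        x = self._flat()
        _, f = morphological_features(x, self._flat(), sampling_rate=FS)
        assert all(v == 0.0 for v in f.values())

    def test_constructed_deceleration(self):
        x = self._flat()
        x[1000:1120] -= 20.0  # -20 bpm, 30 s
        events, f = morphological_features(x, self._flat(), sampling_rate=FS)
        assert f["num_dec"] == 1.0
        assert 18.0 <= f["avg_dec_amp"] <= 20.0
        assert f["avg_dec_dur"] == pytest.approx(30.0, abs=2.0)
        assert f["num_prolonged_dec"] == 0.0
        assert len(events.decelerations) == 1

    def test_shallow_dip_not_an_event(self):
        x = self._flat()
        x[1000:1300] -= 10.0  # deep enough in duration, too shallow in bpm
        _, f = morphological_features(x, self._flat(), sampling_rate=FS)
        assert f["num_dec"] == 0.0

    def test_brief_dip_not_an_event(self):
        x = self._flat()
        x[1000:1040] -= 30.0  # 10 s < 15 s minimum
        _, f = morphological_features(x, self._flat(), sampling_rate=FS)
        assert f["num_dec"] == 0.0

    def test_prolonged_deceleration_flagged(self):
        x = self._flat()
        x[200:1000] -= 25.0  # 200 s
        events, f = morphological_features(x, self._flat(), sampling_rate=FS)
        assert f["num_prolonged_dec"] == 1.0
        assert events.decelerations[0].prolonged

    def test_acceleration_detected(self):
        x = self._flat()
        x[500:600] += 20.0  # 25 s
        _, f = morphological_features(x, self._flat(), sampling_rate=FS)
        assert f["num_acc"] == 1.0
        assert f["num_dec"] == 0.0

    def test_misaligned_baseline_rejected(self):
        with pytest.raises(ValueError):
            morphological_features(self._flat(), np.full(100, 140.0),
                                   sampling_rate=FS)


class TestExtractAll:
    def test_exactly_68_features_with_family_sizes(self, synthetic_segment):
        fv = extract_all(synthetic_segment)
        assert len(fv) == 68
        assert fv.names == FEATURE_NAMES
        assert sum(FAMILY_SIZES.values()) == 68
        assert FAMILY_SIZES == {"time": 8, "spectral": 4,
                                "autocorrelation": 7, "emg": 36,
                                "morphological": 13}

    def test_determinism(self, synthetic_segment):
        a = extract_all(synthetic_segment)
        b = extract_all(synthetic_segment)
        np.testing.assert_array_equal(a.values, b.values)

    def test_no_missing_values(self, synthetic_segment):
        assert np.all(np.isfinite(extract_all(synthetic_segment).values))

    def test_family_order_is_documented_concatenation(self):
        assert FEATURE_NAMES == (TIME_FEATURES + SPECTRAL_FEATURES
                                 + AUTOCORR_FEATURES + EMG_FEATURES
                                 + MORPH_FEATURES)
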