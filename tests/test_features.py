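"""Differential-entropy features, context windows and standardisation."""

import numpy as np
import pytest
from scipy import signal as sps

from sleepgcn.features import (
    EpochedRecording,
    FeatureMatrix,
    Standardizer,
    build_context_windows,
    differential_entropy,
    extract_de_features,
    standardize_features,
)
from sleepgcn.synthetic import ring_montage


def make_recording(signal, fs):
    n = signal.shape[0]
    L = signal.shape[2]
    return EpochedRecording(
        signal=signal,
        sampling_rate=fs,
        labels=np.zeros(L, dtype=int),
        subject_id="T",
        montage=ring_montage(n),
    )


class TestDifferentialEntropy:
    def test_white_noise_full_band_matches_gaussian_closed_form(self, rng):
        fs = 128.0
        sig = rng.standard_normal((2, int(30 * fs), 3))
        rec = make_recording(sig, fs)
        feats = extract_de_features(rec, bands=((0.2, 63.5),))
        # nearly the full band survives the filter, so DE ~ 0.5*ln(2*pi*e)
        assert np.allclose(feats[0].values, 0.5 * np.log(2 * np.pi * np.e), atol=0.1)

    def test_sinusoid_energy_concentrates_in_its_band(self):
        fs = 128.0
        t = np.arange(int(30 * fs)) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)[None, :, None] * np.ones((2, 1, 1))
        rec = make_recording(sig, fs)
        feats = extract_de_features(rec, bands=((8.0, 13.0), (16.0, 30.0)))
        alpha, beta = feats[0].values[:, 0], feats[0].values[:, 1]
        assert np.all(alpha > beta)

    def test_matches_independent_filter_variance_log_oracle(self, rng):
        fs, bands = 256.0, ((0.5, 4.0), (8.0, 13.0))
        sig = rng.standard_normal((2, int(30 * fs), 2))
        rec = make_recording(sig, fs)
        feats = extract_de_features(rec, bands=bands)
        for b, (lo, hi) in enumerate(bands):
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            for epoch in range(2):
                for ch in range(2):
                    filtered = sps.sosfiltfilt(sos, sig[ch, :, epoch])
                    expected = 0.5 * np.log(2 * np.pi * np.e * filtered.var())
                    assert feats[epoch].values[ch, b] == pytest.approx(expected, abs=1e-8)

    def test_silent_channel_hits_variance_floor(self):
        fs = 128.0
        sig = np.zeros((2, int(30 * fs), 1))
        rec = make_recording(sig, fs)
        feats = extract_de_features(rec, bands=((1.0, 4.0),), var_floor=1e-12)
        assert np.allclose(feats[0].values, differential_entropy(1e-12))

    def test_band_above_nyquist_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 30 * 64, 1)), 64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            extract_de_features(rec, bands=((10.0, 40.0),))


class TestContextWindows:
    def make_features(self, L, n=3, fd=2):
        return [FeatureMatrix(np.full((n, fd), float(i))) for i in range(L)]

    def test_window_count_and_centres(self):
        windows = build_context_windows(self.make_features(10), np.arange(10) % 5, "s", d=2)
        assert len(windows) == 6
        assert [w.center_index for w in windows] == list(range(2, 8))
        # oldest -> newest ordering inside the window
        assert np.array_equal(windows[0].features[0, 0, :], [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_d_zero_keeps_every_epoch(self):
        windows = build_context_windows(self.make_features(7), np.zeros(7, int), "s", d=0)
        assert len(windows) == 7
        assert windows[0].features.shape[2] == 1

    def test_single_window_gets_centre_label(self):
        windows = build_context_windows(self.make_features(5), np.array([0, 1, 2, 3, 4]), "s", d=2)
        assert len(windows) == 1
        assert windows[0].label == 2

    def test_too_short_sequence_names_l_and_d(self):
        with pytest.raises(ValueError, match="L=4, d=2"):
            build_context_windows(self.make_features(4), np.zeros(4, int), "s", d=2)

    @pytest.mark.parametrize("L,d", [(5, 1), (21, 4), (50, 0), (9, 3)])
    def test_count_is_l_minus_2d(self, L, d):
        windows = build_context_windows(self.make_features(L), np.zeros(L, int), "s", d)
        assert len(windows) == L - 2 * d


class TestStandardization:
    def test_training_set_becomes_zero_mean_unit_variance(self, rng, tiny_windows):
        out = standardize_features(tiny_windows, stats_from=tiny_windows)
        data = np.concatenate([w.features for w in out], axis=2)
        assert np.allclose(data.mean(axis=2), 0.0, atol=1e-10)
        assert np.allclose(data.var(axis=2), 1.0, atol=1e-8)

    def test_constant_feature_left_untouched_with_warning(self, tiny_windows):
        frozen = []
        for w in tiny_windows[:10]:
            feats = w.features.copy()
            feats[0, 0, :] = 4.2
            frozen.append(type(w)(feats, w.label, w.subject_id, w.center_index))
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_features(frozen, stats_from=frozen)
        assert np.allclose(out[0].features[0, 0], 4.2)

    def test_affine_transform_invariance(self, tiny_windows):
        shifted = [
            type(w)(3.0 * w.features - 7.0, w.label, w.subject_id, w.center_index)
            for w in tiny_windows
        ]
        a = standardize_features(tiny_windows, stats_from=tiny_windows)
        b = standardize_features(shifted, stats_from=shifted)
        for wa, wb in zip(a, b):
            assert np.allclose(wa.features, wb.features, atol=1e-10)

    def test_idempotent_with_same_statistics(self, tiny_windows):
        scaler = Standardizer().fit(tiny_windows)
        once = scaler.transform(tiny_windows)
        # re-applying the identity affine map (stats of standardized data)
        twice = Standardizer().fit(once).transform(once)
        for w1, w2 in zip(once, twice):
            assert np.allclose(w1.features, w2.features, atol=1e-10)
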