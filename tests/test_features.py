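"""Band-variance, differential-entropy and tensor bookkeeping behavior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from sgcsrm.features import (
    BAND_PRESETS,
    BandDefinition,
    DEFAULT_BANDS,
    RawRecording,
    SEED12_CHANNELS,
    differential_entropy,
    extract_feature_tensor,
    normalize_subject,
    pad_or_truncate,
    select_bands,
    select_channels,
    window_band_variance,
)

ALPHA = BandDefinition("alpha", 8.0, 13.0)


def _recording(samples, fs=200.0, label="neutral", subject="s00", trial="t00"):
    names = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return RawRecording(samples, fs, names, subject, trial, label)


class TestWindowBandVariance:
    def test_stationary_sinusoid_constant_across_windows(self):
        fs, secs = 200.0, 20
        t = np.arange(int(fs * secs)) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)[None, :]  # 10 Hz, inside alpha
        v = window_band_variance(_recording(sig, fs), ALPHA, 1.0)
        assert v.shape == (1, secs)
        cov = v.std() / v.mean()
        assert cov < 0.05
        assert (v >= 0).all()

    def test_white_noise_band_fraction(self):
        # flat spectrum: band variance ~ sigma^2 * bandwidth / Nyquist
        fs, sigma2 = 200.0, 4.0
        rng = np.random.default_rng(3)
        sig = rng.normal(0, np.sqrt(sigma2), size=(1, int(fs) * 150))
        v = window_band_variance(_recording(sig, fs), ALPHA, 1.0)
        expected = sigma2 * (ALPHA.hi - ALPHA.lo) / (fs / 2)
        assert v.shape[1] >= 100
        assert abs(v.mean() - expected) / expected < 0.15

    def test_window_count_and_partial_window_discarded(self):
        fs = 200.0
        sig = np.zeros((2, int(60.5 * fs))) + np.random.default_rng(0).normal(
            size=(2, int(60.5 * fs))
        )
        v = window_band_variance(_recording(sig, fs), ALPHA, 1.0)
        assert v.shape == (2, 60)

    def test_errors(self):
        short = _recording(np.zeros((1, 50)), 200.0)
        with pytest.raises(ValueError, match="trial too short"):
            window_band_variance(short, ALPHA, 1.0)
        rec = _recording(np.random.default_rng(0).normal(size=(1, 400)), 200.0)
        with pytest.raises(ValueError, match="Nyquist"):
            window_band_variance(rec, BandDefinition("hf", 90.0, 120.0), 1.0)


class TestDifferentialEntropy:
    def test_zero_point(self):
        assert differential_entropy(1.0 / (2 * np.pi * np.e)) == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_matches_integral_oracle(self):
        # independent oracle: -\int f log f for the standard normal density
        def integrand(x):
            f = np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
            return -f * np.log(f)

        oracle, _ = quad(integrand, -12, 12)
        assert differential_entropy(1.0) == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(1.41894, abs=1e-5)

    def test_quadrupling_variance_adds_ln2(self):
        for s2 in (0.01, 1.0, 37.5):
            diff = differential_entropy(4 * s2) - differential_entropy(s2)
            assert diff == pytest.approx(np.log(2.0), abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="nonpositive variance"):
            differential_entropy(0.0)

    @given(st.floats(min_value=-5, max_value=5))
    def test_round_trip_with_inverse(self, h):
        s2 = np.exp(2 * h) / (2 * np.pi * np.e)
        assert differential_entropy(s2) == pytest.approx(h, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e6), st.floats(min_value=1.01, max_value=100))
    def test_strictly_increasing(self, s2, factor):
        assert differential_entropy(s2 * factor) > differential_entropy(s2)


class TestExtractFeatureTensor:
    def _recordings(self, n_trials=2, n_ch=3, secs=10, fs=200.0, seed=0):
        rng = np.random.default_rng(seed)
        return [
            _recording(
                rng.normal(size=(n_ch, int(secs * fs))), fs,
                subject=f"s{i % 2}", trial=f"t{i}",
            )
            for i in range(n_trials)
        ]

    def test_axis_order_and_shape(self):
        tensor = extract_feature_tensor(self._recordings(), DEFAULT_BANDS, "DE", 1.0)
        assert tensor.values.shape == (2, 3, 5, 10)
        assert tensor.band_names == tuple(b.name for b in DEFAULT_BANDS)

    def test_de_composes_variance_and_entropy(self):
        recs = self._recordings(n_trials=1)
        de = extract_feature_tensor(recs, DEFAULT_BANDS, "DE", 1.0)
        for b_idx, band in enumerate(DEFAULT_BANDS):
            var = window_band_variance(recs[0], band, 1.0)
            np.testing.assert_allclose(
                de.values[0, :, b_idx, :], differential_entropy(var), atol=1e-10
            )

    def test_psd_equals_inverted_de(self):
        recs = self._recordings()
        de = extract_feature_tensor(recs, DEFAULT_BANDS, "DE", 1.0)
        psd = extract_feature_tensor(recs, DEFAULT_BANDS, "PSD", 1.0)
        np.testing.assert_allclose(
            psd.values, np.exp(2 * de.values) / (2 * np.pi * np.e), rtol=1e-10
        )

    def test_mixed_inputs_rejected(self):
        recs = self._recordings()
        bad_fs = _recording(np.zeros((3, 400)) + 1e-3, fs=100.0)
        with pytest.raises(ValueError, match="sampling rates"):
            extract_feature_tensor([recs[0], bad_fs], DEFAULT_BANDS[:2], "DE", 1.0)
        other = RawRecording(
            recs[0].samples, 200.0, ("x0", "x1", "x2"), "s", "t", "neutral"
        )
        with pytest.raises(ValueError, match="channel sets"):
            extract_feature_tensor([recs[0], other], DEFAULT_BANDS[:2], "DE", 1.0)


class TestPadTruncateNormalizeSelect:
    def test_pad_appends_zeros(self, random_tensor):
        out = pad_or_truncate(random_tensor, 265)
        assert out.values.shape[3] == 265
        np.testing.assert_array_equal(out.values[..., :6], random_tensor.values)
        assert np.all(out.values[..., 6:] == 0)

    def test_identity_and_truncation(self, random_tensor):
        same = pad_or_truncate(random_tensor, 6)
        np.testing.assert_array_equal(same.values, random_tensor.values)
        cut = pad_or_truncate(random_tensor, 4)
        np.testing.assert_array_equal(cut.values, random_tensor.values[..., :4])

    @given(st.integers(min_value=1, max_value=300))
    def test_padding_conserves_mass(self, target):
        rng = np.random.default_rng(1)
        from sgcsrm.features import BandFeatureTensor

        t = BandFeatureTensor(
            rng.normal(size=(3, 2, 2, 7)), ("a", "b"), ("alpha", "beta"),
            np.array(["s"] * 3), np.array([0, 1, 2]),
        )
        out = pad_or_truncate(t, target)
        total_in = np.abs(t.values).sum()
        total_out = np.abs(out.values).sum()
        if target >= 7:
            assert total_out == pytest.approx(total_in)
        else:
            assert total_out <= total_in + 1e-12

    def test_normalize_moments_and_idempotence(self, random_tensor):
        out = normalize_subject(random_tensor)
        for s in ("s0", "s1"):
            block = out.values[out.subject_ids == s]
            assert np.abs(block.mean(axis=0)).max() < 1e-9
            assert np.abs(block.std(axis=0) - 1).max() < 1e-6
        again = normalize_subject(out)
        np.testing.assert_allclose(again.values, out.values, atol=1e-6)

    def test_normalize_constant_feature_maps_to_zero(self, random_tensor):
        t = random_tensor.copy_with(values=random_tensor.values.copy())
        t.values[:, 0, 0, 0] = 3.14  # constant across all trials/subjects
        out = normalize_subject(t)
        assert np.all(out.values[:, 0, 0, 0] == 0.0)

    def test_normalize_removes_subject_offsets(self, random_tensor):
        # two subjects whose within-subject structure matches exactly
        v = random_tensor.values.copy()
        v[5:] = v[:5] + 11.0  # subject s1 = shifted copy of s0
        t = random_tensor.copy_with(values=v)
        out = normalize_subject(t)
        np.testing.assert_allclose(out.values[:5], out.values[5:], atol=1e-9)

    def test_seed12_preset_on_full_montage(self):
        from sgcsrm.features import BandFeatureTensor
        from sgcsrm.graph import seed62_layout

        names = seed62_layout().names
        rng = np.random.default_rng(8)
        t62 = BandFeatureTensor(
            rng.normal(size=(3, 62, 2, 4)), names, ("alpha", "beta"),
            np.array(["s"] * 3), np.array([0, 1, 2]),
        )
        out = select_channels(t62, "seed12")
        assert out.channel_names == SEED12_CHANNELS
        for k, name in enumerate(SEED12_CHANNELS):
            np.testing.assert_array_equal(
                out.values[:, k], t62.values[:, names.index(name)]
            )

    def test_select_channels_preset_and_errors(self, small_dataset):
        tensor, _, _ = small_dataset
        out = select_channels(tensor, "seed12")
        assert out.channel_names == SEED12_CHANNELS
        ident = select_channels(tensor, tensor.channel_names)
        np.testing.assert_array_equal(ident.values, tensor.values)
        with pytest.raises(KeyError, match="XX"):
            select_channels(tensor, ("XX",))

    def test_select_bands_presets(self, random_tensor):
        single = select_bands(random_tensor, ("beta",))
        assert single.values.shape[2] == 1
        with pytest.raises(KeyError, match="gamma"):
            select_bands(random_tensor, ("gamma",))
        assert BAND_PRESETS["four"] == ("theta", "alpha", "beta", "gamma")

    def test_channel_band_selection_commutes(self, random_tensor):
        a = select_bands(select_channels(random_tensor, ("c3", "c1")), ("beta", "theta"))
        b = select_channels(select_bands(random_tensor, ("beta", "theta")), ("c3", "c1"))
        np.testing.assert_array_equal(a.values, b.values)
        assert a.channel_names == b.channel_names and a.band_names == b.band_names
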