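import numpy as np
import pytest
import scipy.fft

from mdfpnet.audio_io import Waveform
from mdfpnet.features import (
    BandedSpectrogram,
    FeatureConfig,
    STFTConfig,
    apply_filterbank,
    dct_cepstra,
    extract_feature_set,
    hz_to_mel,
    make_filterbank,
    mel_to_hz,
    power_to_db,
    stft_power,
    to_branch_input,
)


class TestSTFT:
    def test_standard_clip_shape(self, standard_clip):
        P = stft_power(standard_clip)
        assert P.values.shape == (59, 513)
        assert np.all(P.values >= 0)

    def test_zero_input_gives_zero_matrix(self):
        P = stft_power(Waveform(np.zeros(30_000), 10_000))
        assert np.all(P.values == 0)

    def test_impulse_flat_spectrum_uncentered_rect(self):
        x = np.zeros(2048)
        x[0] = 1.0
        cfg = STFTConfig(window="boxcar", centered=False)
        P = stft_power(Waveform(x, 10_000), cfg)
        # |DFT of a unit impulse| is 1 in every bin
        np.testing.assert_allclose(P.values[0], 1.0, atol=1e-12)

    def test_uncentered_short_clip_errors(self):
        cfg = STFTConfig(centered=False)
        with pytest.raises(ValueError):
            stft_power(Waveform(np.zeros(500), 10_000), cfg)

    def test_frame_count_formula(self, rng):
        for n in (30_000, 29_696, 10_240):
            P = stft_power(Waveform(rng.normal(size=n), 10_000))
            assert P.n_frames == 1 + n // 512


def _triangle_scalar(k, o, c, h):
    """Independent per-element triangular filter value."""
    if o <= k <= c:
        return (k - o) / (c - o)
    if c <= k <= h:
        return (h - k) / (h - c)
    return 0.0


class TestFilterBank:
    def test_paper_default_shapes(self):
        for scale in ("mel", "linear"):
            B = make_filterbank(513, 128, 0.0, 5000.0, scale, 10_000)
            assert B.weights.shape == (513, 128)

    def test_each_filter_peaks_at_exactly_one(self):
        B = make_filterbank(513, 128, 0.0, 5000.0, "linear", 10_000)
        np.testing.assert_array_equal(B.weights.max(axis=0), 1.0)
        Bm = make_filterbank(513, 128, 0.0, 5000.0, "mel", 10_000)
        np.testing.assert_array_equal(Bm.weights.max(axis=0), 1.0)

    @pytest.mark.parametrize("scale", ["mel", "linear"])
    def test_elementwise_against_scalar_oracle(self, scale):
        B = make_filterbank(129, 20, 0.0, 4000.0, scale, 8000)
        df = 8000 / (2 * (129 - 1))
        for m in range(20):
            o, c, h = B.lo_hz[m] / df, B.center_hz[m] / df, B.hi_hz[m] / df
            expected = np.array([_triangle_scalar(k, o, c, h) for k in range(129)])
            np.testing.assert_allclose(B.weights[:, m], expected, atol=1e-12)

    def test_breakpoints_monotone_and_shared(self):
        B = make_filterbank(513, 64, 0.0, 5000.0, "mel", 10_000)
        assert np.all(B.lo_hz < B.center_hz)
        assert np.all(B.center_hz < B.hi_hz)
        np.testing.assert_array_equal(B.lo_hz[1:], B.center_hz[:-1])
        np.testing.assert_array_equal(B.hi_hz[:-1], B.center_hz[1:])

    def test_too_many_filters_errors(self):
        with pytest.raises(ValueError, match="filter"):
            make_filterbank(33, 64, 0.0, 4000.0, "linear", 8000)

    def test_invalid_range_errors(self):
        with pytest.raises(ValueError):
            make_filterbank(513, 16, 3000.0, 1000.0, "mel", 10_000)
        with pytest.raises(ValueError):
            make_filterbank(513, 16, 0.0, 9000.0, "mel", 10_000)

    def test_mel_scale_round_trip(self):
        f = np.array([0.0, 440.0, 1000.0, 4999.0])
        np.testing.assert_allclose(mel_to_hz(hz_to_mel(f)), f, rtol=1e-12)


class TestApplyFilterbank:
    def test_paper_shape_contract(self, standard_clip):
        P = stft_power(standard_clip)
        B = make_filterbank(513, 128, 0.0, 5000.0, "mel", 10_000)
        X = apply_filterbank(P, B)
        assert X.values.shape == (59, 128)
        assert X.scale == "power"

    def test_zero_in_zero_out(self):
        P = stft_power(Waveform(np.zeros(30_000), 10_000))
        B = make_filterbank(513, 8, 0.0, 5000.0, "linear", 10_000)
        assert np.all(apply_filterbank(P, B).values == 0)

    def test_all_ones_filter_gives_row_sums(self, standard_clip):
        from mdfpnet.features import FilterBank

        P = stft_power(standard_clip)
        B = FilterBank(
            weights=np.ones((513, 1)),
            lo_hz=np.array([0.0]),
            center_hz=np.array([2500.0]),
            hi_hz=np.array([5000.0]),
            scale="linear",
        )
        X = apply_filterbank(P, B)
        np.testing.assert_allclose(X.values[:, 0], P.values.sum(axis=1), rtol=1e-12)

    def test_linearity(self, rng):
        from mdfpnet.features import PowerSpectrogram

        B = make_filterbank(65, 8, 0.0, 4000.0, "mel", 8000)
        v1, v2 = rng.random((10, 65)), rng.random((10, 65))
        freqs = np.fft.rfftfreq(128, 1 / 8000)
        times = np.arange(10.0)
        mk = lambda v: PowerSpectrogram(v, times, freqs)
        lhs = apply_filterbank(mk(2.0 * v1 + 3.0 * v2), B).values
        rhs = 2.0 * apply_filterbank(mk(v1), B).values + 3.0 * apply_filterbank(mk(v2), B).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_total_band_power_bounded_by_spectrogram_power(self, standard_clip):
        # filters never exceed 1, so summed band power cannot exceed total power
        P = stft_power(standard_clip)
        B = make_filterbank(513, 128, 0.0, 5000.0, "mel", 10_000)
        assert apply_filterbank(P, B).values.sum() <= P.values.sum() + 1e-9

    def test_shape_mismatch_errors(self, standard_clip):
        P = stft_power(standard_clip)
        B = make_filterbank(129, 8, 0.0, 4000.0, "mel", 8000)
        with pytest.raises(ValueError):
            apply_filterbank(P, B)


class TestPowerToDb:
    def test_reference_values(self):
        X = BandedSpectrogram(np.array([[1.0, 100.0, 0.0]]), "power")
        out = power_to_db(X, 1e-10)
        np.testing.assert_allclose(out.values, [[0.0, 20.0, -100.0]])
        assert out.scale == "db"

    def test_bad_floor(self):
        X = BandedSpectrogram(np.ones((2, 2)), "power")
        with pytest.raises(ValueError):
            power_to_db(X, 0.0)


class TestCepstra:
    def test_brute_force_triple_loop_oracle(self, rng):
        X = rng.normal(size=(5, 8))
        ours = dct_cepstra(BandedSpectrogram(X, "db"), 8).values
        M = 8
        expected = np.zeros((5, 8))
        for t in range(5):
            for c in range(8):
                for m in range(1, M + 1):
                    expected[t, c] += X[t, m - 1] * np.cos(c * np.pi * (m - 0.5) / M)
        assert np.abs(ours - expected).max() < 1e-9

    def test_matches_scipy_dct(self, rng):
        X = rng.normal(size=(7, 16))
        ours = dct_cepstra(BandedSpectrogram(X, "db"), 16).values
        ref = scipy.fft.dct(X, type=2, axis=1) / 2.0
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_constant_row_collapses_to_c0(self):
        X = BandedSpectrogram(np.full((3, 32), 7.5), "db")
        out = dct_cepstra(X, 32).values
        np.testing.assert_allclose(out[:, 0], 32 * 7.5, rtol=1e-12)
        assert np.abs(out[:, 1:]).max() < 1e-9

    def test_default_output_shape(self, standard_clip):
        F = extract_feature_set(standard_clip)
        assert F.mfcc.values.shape == (59, 32)

    def test_too_many_coefficients(self):
        X = BandedSpectrogram(np.ones((2, 8)), "db")
        with pytest.raises(ValueError):
            dct_cepstra(X, 9)


class TestFeatureSet:
    def test_four_feature_shapes(self, standard_clip):
        F = extract_feature_set(standard_clip)
        assert F.mel.values.shape == (59, 128)
        assert F.mfcc.values.shape == (59, 32)
        assert F.lfcc.values.shape == (59, 32)
        assert F.mean_mfcc.shape == (128,)

    def test_time_reversal_mirrors_mel_frames(self, rng):
        # exact when the taper is symmetric and the length is hop-aligned
        n = 512 * 58
        x = 0.1 * rng.normal(size=n)
        cfg = FeatureConfig(stft=STFTConfig(periodic=False))
        F = extract_feature_set(Waveform(x, 10_000), cfg)
        Fr = extract_feature_set(Waveform(x[::-1].copy(), 10_000), cfg)
        a, b = F.mel.values, Fr.mel.values[::-1]
        assert np.abs(a - b).max() <= 1e-6 * np.abs(a).max()

    def test_pure_tone_lands_in_matching_band(self):
        t = np.arange(30_000) / 10_000
        F = extract_feature_set(Waveform(0.5 * np.sin(2 * np.pi * 2000 * t), 10_000))
        B = make_filterbank(513, 128, 0.0, 5000.0, "mel", 10_000)
        bands = F.mel.values.argmax(axis=1)
        assert np.all(bands == bands[0])
        assert abs(B.center_hz[bands[0]] - 2000.0) <= B.hi_hz[bands[0]] - B.lo_hz[bands[0]]

    def test_pipeline_determinism(self, standard_clip):
        F1 = extract_feature_set(standard_clip)
        F2 = extract_feature_set(standard_clip)
        np.testing.assert_array_equal(F1.mel.values, F2.mel.values)
        np.testing.assert_array_equal(F1.mean_mfcc, F2.mean_mfcc)


class TestBranchInput:
    def test_constant_input_maps_to_zeros(self):
        out = to_branch_input(np.full((59, 128), 3.3), (128, 345))
        assert out.shape == (3, 128, 345)
        assert np.all(out == 0)

    def test_resize_to_paper_branch_shape(self, rng):
        out = to_branch_input(rng.normal(size=(59, 128)), (128, 345))
        assert out.shape == (3, 128, 345)
        np.testing.assert_array_equal(out[0], out[1])
        np.testing.assert_array_equal(out[0], out[2])
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_identity_resize_keeps_scaled_values(self, rng):
        F = rng.normal(size=(59, 128))
        out = to_branch_input(F, (128, 59))
        scaled = (F.T - F.min()) / (F.max() - F.min())
        np.testing.assert_allclose(out[0], scaled, rtol=1e-12)

    def test_non_finite_rejected(self):
        F = np.ones((4, 4))
        F[2, 2] = np.nan
        with pytest.raises(ValueError):
            to_branch_input(F, (4, 4))
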