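import numpy as np
import pytest

from emg2prosody.emgfeat import (
    FrameSpec,
    assemble_features,
    dwt_db2,
    extract_all,
    feature_dimension,
    frame_signal,
    mfcc_features,
    pairwise_features,
    spectral_features,
    time_domain_features,
    wavelet_features,
)

FS = 2222.0


def band_noise(rng, n, fs=FS):
    from scipy import signal as sps

    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


class TestFrameSignal:
    def test_f0_spec_arithmetic(self):
        frames = frame_signal(np.zeros(2222), FS, FrameSpec(0.040, 0.020))
        assert frames.shape == (49, 89)

    def test_intensity_spec_arithmetic(self):
        frames = frame_signal(np.zeros(2222), FS, FrameSpec(0.150, 0.030))
        assert frames.shape == (29, 333)

    def test_frames_tile_on_step_grid(self):
        x = np.arange(2222.0)
        spec = FrameSpec(0.040, 0.020)
        frames = frame_signal(x, FS, spec)
        for k in (0, 10, 48):
            start = int(round(k * spec.step * FS))
            assert frames[k, 0] == x[start]

    def test_too_short_empty(self):
        assert frame_signal(np.zeros(10), FS, FrameSpec(0.040, 0.020)).shape[0] == 0

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FrameSpec(0.02, 0.04)


class TestTimeDomain:
    def test_constant_frame(self):
        out = time_domain_features(np.full(89, 3.0))
        assert out["wl"] == 0.0
        assert out["zc"] == 0.0
        assert out["ssc"] == 0.0
        assert out["var"] == 0.0
        assert out["rms"] == pytest.approx(3.0)
        assert out["mav"] == pytest.approx(3.0)

    def test_zero_crossings_match_brute_force(self):
        t = np.arange(89) / FS
        x = np.sin(2 * np.pi * 50.0 * t + 0.3)
        eps = 0.01 * np.sqrt(np.mean(x**2))
        brute = sum(
            1
            for i in range(x.size - 1)
            if x[i] * x[i + 1] < 0 and abs(x[i + 1] - x[i]) > eps
        )
        assert time_domain_features(x)["zc"] == brute
        assert brute == 4  # ~2 periods of 50 Hz within 40 ms

    def test_homogeneity(self, rng):
        x = band_noise(rng, 89)
        f1 = time_domain_features(x)
        f2 = time_domain_features(5.0 * x)
        for key, power in (("mav", 1), ("rms", 1), ("wl", 1), ("var", 2)):
            assert f2[key] == pytest.approx(5.0**power * f1[key], rel=1e-9)
        # dead-band scales with RMS, so counts are scale-invariant
        assert f2["zc"] == f1["zc"]
        assert f2["ssc"] == f1["ssc"]

    def test_batch_matches_single(self, rng):
        frames = band_noise(rng, 89 * 3).reshape(3, 89)
        batch = time_domain_features(frames)
        for i in range(3):
            single = time_domain_features(frames[i])
            for k in batch:
                assert batch[k][i] == pytest.approx(single[k])


class TestSpectral:
    def test_narrowband_tone(self):
        t = np.arange(333) / FS
        x = np.sin(2 * np.pi * 100.0 * t)
        out = spectral_features(x, FS)
        df = FS / 333
        for key in ("meanfreq", "medianfreq", "peakfreq"):
            assert abs(out[key] - 100.0) <= 2 * df
        assert out["cfv"] < (2 * df) ** 2 + 25.0

    def test_white_noise_mean_freq(self, rng):
        frames = rng.standard_normal((100, 333))
        out = spectral_features(frames, FS)
        assert np.mean(out["meanfreq"]) == pytest.approx(FS / 4, rel=0.05)

    def test_scaling(self, rng):
        x = band_noise(rng, 333)
        f1 = spectral_features(x, FS)
        f2 = spectral_features(3.0 * x, FS)
        for key in ("meanpd", "sm1", "sm2", "sm3", "pdwl"):
            assert f2[key] == pytest.approx(9.0 * f1[key], rel=1e-9)
        for key in ("meanfreq", "medianfreq", "peakfreq", "cfv"):
            assert f2[key] == pytest.approx(f1[key], rel=1e-9)

    def test_zero_frame_fallback(self):
        out = spectral_features(np.zeros(64), FS)
        assert out["meanfreq"] == 0.0
        assert out["medianfreq"] == 0.0
        assert out["peakfreq"] == 0.0
        assert np.isfinite(list(out.values())).all()


class TestMfcc:
    def test_output_length(self, rng):
        assert mfcc_features(band_noise(rng, 89), FS).shape == (24,)

    def test_gain_moves_only_c0(self, rng):
        x = band_noise(rng, 89)
        c1 = mfcc_features(x, FS)
        c2 = mfcc_features(4.0 * x, FS)
        assert abs(c2[0] - c1[0]) > 1e-6
        assert np.allclose(c1[1:], c2[1:], atol=1e-9)

    def test_tone_vs_noise_differ(self, rng):
        t = np.arange(89) / FS
        tone = np.sin(2 * np.pi * 100.0 * t)
        noise = rng.standard_normal(89)
        c_tone = mfcc_features(tone, FS)
        c_noise = mfcc_features(noise, FS)
        assert abs(c_tone[1] - c_noise[1]) > 1.0

    def test_zero_frame_finite(self):
        assert np.isfinite(mfcc_features(np.zeros(89), FS)).all()


class TestWavelet:
    def test_zero_frame(self):
        out = wavelet_features(np.zeros(96))
        assert all(v == 0.0 for v in out.values())
        assert len(out) == 12

    def test_scaling(self, rng):
        x = band_noise(rng, 96)
        f1 = wavelet_features(x)
        f2 = wavelet_features(2.0 * x)
        for lev in (1, 2, 3, 4):
            assert f2[f"dwtmax_l{lev}"] == pytest.approx(
                2.0 * f1[f"dwtmax_l{lev}"], rel=1e-9
            )
            assert f2[f"dwtvar_l{lev}"] == pytest.approx(
                4.0 * f1[f"dwtvar_l{lev}"], rel=1e-9
            )

    def test_energy_conservation(self, rng):
        # orthogonal periodized transform: detail + approximation energy
        # equals frame energy (frame length divisible by 2^levels)
        x = rng.standard_normal(96)
        details, approx, padded = dwt_db2(x, levels=4)
        assert not padded
        total = sum(float(np.sum(d**2)) for d in details) + float(np.sum(approx**2))
        assert total == pytest.approx(float(np.sum(x**2)), abs=1e-8)

    def test_short_frame_padded_flag(self):
        details, approx, padded = dwt_db2(np.ones(89), levels=4)
        assert padded
        assert all(np.isfinite(d).all() for d in details)


class TestPairwise:
    def _stack(self, rng, n_ch=3, n_frames=20, flen=89):
        return rng.standard_normal((n_ch, n_frames, flen))

    def test_self_pair_is_one(self, rng):
        fbc = self._stack(rng)
        out = pairwise_features(fbc, FS)
        pairs = out["_pairs"]
        for p, (i, j) in enumerate(pairs):
            if i == j:
                assert np.allclose(out["cross_correlation"][p], 1.0, atol=1e-9)
                assert np.allclose(out["coherence"][p], 1.0, atol=1e-9)

    def test_independent_noise_low_coherence(self, rng):
        fbc = self._stack(rng, n_ch=2, n_frames=100)
        out = pairwise_features(fbc, FS)
        pairs = out["_pairs"]
        p01 = pairs.index((0, 1))
        assert out["coherence"][p01].mean() < 0.35

    def test_shifted_copy_high_xcorr(self, rng):
        x = band_noise(rng, 89 * 10).reshape(10, 89)
        shifted = np.roll(x, 5, axis=1)
        fbc = np.stack([x, shifted])
        out = pairwise_features(fbc, FS)
        p01 = out["_pairs"].index((0, 1))
        # circular shift leaves small edge effects on the linear estimate
        assert np.mean(out["cross_correlation"][p01]) > 0.9
        assert np.all(out["cross_correlation"][p01] > 0.8)

    def test_zero_variance_channel_flagged_zero(self, rng):
        fbc = self._stack(rng, n_ch=2, n_frames=5)
        fbc[1] = 0.0
        out = pairwise_features(fbc, FS)
        p01 = out["_pairs"].index((0, 1))
        assert np.all(out["coherence"][p01] == 0.0)
        assert np.all(np.isfinite(out["cross_correlation"][p01]))


class TestAssemble:
    def test_dimension_closed_form_hand_count_2ch(self):
        # per channel: 6 time + 9 spectral + 24 mfcc + 12 wavelet = 51
        # pairs of 2 channels incl. self: 3; three pair families
        assert feature_dimension(2) == 51 * 2 + 3 * 3
        assert feature_dimension(8) == 51 * 8 + 3 * 36

    def test_extract_all_dimension_and_names(self, rng):
        channels = [band_noise(rng, 2222) for _ in range(2)]
        fm = extract_all(channels, FS, FrameSpec(0.040, 0.020))
        assert fm.n_features == feature_dimension(2)
        assert len(set(fm.feature_names)) == fm.n_features
        # symmetric pair families only contain i <= j
        for name in fm.feature_names:
            if "/ch" in name and "-ch" in name:
                left, right = name.split("/")[1].split("-")
                assert int(left[2:]) <= int(right[2:])

    def test_column_order_stable(self, rng):
        channels = [band_noise(rng, 2222) for _ in range(2)]
        fm1 = extract_all(channels, FS, FrameSpec(0.040, 0.020))
        fm2 = extract_all(channels, FS, FrameSpec(0.040, 0.020))
        assert fm1.feature_names == fm2.feature_names
        assert np.array_equal(fm1.values, fm2.values)

    def test_frame_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_features(
                np.arange(3) * 0.02,
                [(["a"], np.zeros((3, 1))), (["b"], np.zeros((2, 1)))],
            )

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            assemble_features(
                np.arange(2) * 0.02,
                [(["a"], np.zeros((2, 1))), (["a"], np.zeros((2, 1)))],
            )

    def test_rows_finite_on_fuzz(self, rng):
        channels = [band_noise(rng, 2222 * 3) for _ in range(2)]
        fm = extract_all(channels, FS, FrameSpec(0.040, 0.020))
        assert np.isfinite(fm.values).all()

    def test_frame_times_match_target_grid(self, rng):
        from emg2prosody.acoustics import frame_targets
        from emg2prosody.signals import Contour

        channels = [band_noise(rng, 2222) for _ in range(2)]
        spec = FrameSpec(0.040, 0.020)
        fm = extract_all(channels, FS, spec)
        c = Contour(np.arange(100) * 0.01, np.ones(100), "Hz")
        targ = frame_targets(c, spec.frame_len, spec.step)
        n = min(len(fm.frame_times), len(targ))
        assert np.allclose(fm.frame_times[:n], targ.times[:n], atol=1e-9)
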