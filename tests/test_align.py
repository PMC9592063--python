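import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emg2prosody.align import (
    MemMeter,
    WarpPath,
    align_emg_to_audio,
    dtw_full,
    dtw_lowmem,
    envelope_features,
    path_cost,
)
from emg2prosody.signals import SignalTrack
from emg2prosody.synthgen import generate_session, make_task_config


def brute_force_dtw_cost(a, b):
    """Plain-python DP oracle, written independently of the kernels."""
    a = np.atleast_2d(np.asarray(a, float).T).T
    b = np.atleast_2d(np.asarray(b, float).T).T
    n, m = len(a), len(b)
    d = [[float(np.linalg.norm(a[i] - b[j])) for j in range(m)] for i in range(n)]
    D = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                D[i][j] = d[0][0]
            elif i == 0:
                D[i][j] = D[0][j - 1] + d[0][j]
            elif j == 0:
                D[i][j] = D[i - 1][0] + d[i][0]
            else:
                D[i][j] = min(D[i - 1][j - 1], D[i - 1][j], D[i][j - 1]) + d[i][j]
    return D[n - 1][m - 1]


class TestEnvelopeFeatures:
    def test_constant_signal_identical_vectors(self):
        track = SignalTrack(np.ones(44100), 44100.0)
        f = envelope_features(track, 0.010)
        assert np.allclose(f, f[0])

    def test_vector_count(self):
        track = SignalTrack(np.zeros(44100 * 10), 44100.0)
        assert envelope_features(track, 0.010).shape == (1000, 5)

    def test_band_profiles_distinguish_noise_color(self, rng):
        from scipy import signal as sps

        white = rng.standard_normal(44100 * 2)
        sos = sps.butter(4, 200.0, fs=44100.0, output="sos")
        lowpassed = sps.sosfiltfilt(sos, rng.standard_normal(44100 * 2))
        fw = envelope_features(SignalTrack(white, 44100.0), 0.010)
        fl = envelope_features(SignalTrack(lowpassed, 44100.0), 0.010)
        gap = np.abs(fw.mean(axis=0) - fl.mean(axis=0))
        # z-scored per track, so compare via a joint re-extraction instead
        joint = envelope_features(
            SignalTrack(np.concatenate([white, lowpassed]), 44100.0), 0.010
        )
        half = joint.shape[0] // 2
        gap = np.abs(joint[:half, 1:].mean(axis=0) - joint[half:, 1:].mean(axis=0))
        assert gap.max() > 1.0

    def test_rejects_bad_hop(self):
        with pytest.raises(ValueError):
            envelope_features(SignalTrack(np.zeros(100), 44100.0), 0.0)

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            envelope_features(SignalTrack(np.zeros(100), 44100.0), 0.010)


class TestDtwFull:
    def test_identical_sequences(self, rng):
        a = rng.standard_normal((40, 3))
        cost, path = dtw_full(a, a)
        assert cost == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(path.pairs, np.column_stack([np.arange(40)] * 2))

    def test_hand_example_duplicated_element(self):
        cost, path = dtw_full(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 1.0, 2.0]))
        assert cost == pytest.approx(0.0, abs=1e-12)
        pairs = [tuple(p) for p in path.pairs]
        assert (0, 0) in pairs and (0, 1) in pairs  # visits the duplicate

    def test_symmetry(self, rng):
        a = rng.standard_normal((25, 2))
        b = rng.standard_normal((31, 2))
        ca, pa = dtw_full(a, b)
        cb, pb = dtw_full(b, a)
        assert ca == pytest.approx(cb, abs=1e-9)
        pb.transposed().validate(25, 31)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a = rng.standard_normal((12, 2))
            b = rng.standard_normal((15, 2))
            cost, _ = dtw_full(a, b)
            assert cost == pytest.approx(brute_force_dtw_cost(a, b), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_full(np.zeros((0, 2)), np.zeros((3, 2)))


class TestDtwLowmem:
    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(50):
            n, m = rng.integers(2, 200, size=2)
            a = rng.standard_normal((n, 4))
            b = rng.standard_normal((m, 4))
            c_full, _ = dtw_full(a, b)
            c_low, path = dtw_lowmem(a, b)
            assert abs(c_full - c_low) < 1e-9
            path.validate(n, m)

    def test_identical_sequences_diagonal(self, rng):
        a = rng.standard_normal((300, 3))
        cost, path = dtw_lowmem(a, a)
        assert cost == pytest.approx(0.0, abs=1e-10)
        assert np.array_equal(path.pairs[:, 0], path.pairs[:, 1])

    def test_path_cost_equals_reported_cost(self, rng):
        a = rng.standard_normal((80, 3))
        b = rng.standard_normal((120, 3))
        cost, path = dtw_lowmem(a, b)
        assert path_cost(a, b, path) == pytest.approx(cost, abs=1e-9)

    def test_memory_linear(self, rng):
        base_cells = 4096  # full-DP fallback size for tiny subproblems
        for n in (400, 800, 1600):
            meter = MemMeter()
            a = rng.standard_normal((n, 3))
            b = rng.standard_normal((n, 3))
            dtw_lowmem(a, b, meter)
            # peak concurrently-touched DP cells is O(N+M), never O(N*M)
            assert meter.peak <= 4 * (n + n) + base_cells
            assert meter.peak < n * n / 10

    @settings(max_examples=30, deadline=None)
    @given(st.integers(2, 40), st.integers(2, 40), st.integers(0, 10**6))
    def test_property_equivalence(self, n, m, seed):
        r = np.random.default_rng(seed)
        a = r.standard_normal((n, 2))
        b = r.standard_normal((m, 2))
        c_full, _ = dtw_full(a, b)
        c_low, path = dtw_lowmem(a, b)
        assert abs(c_full - c_low) < 1e-9
        path.validate(n, m)


class TestWarpPath:
    def test_validate_boundary(self):
        with pytest.raises(ValueError):
            WarpPath(np.array([[1, 0], [2, 1]])).validate(3, 2)

    def test_validate_steps(self):
        with pytest.raises(ValueError):
            WarpPath(np.array([[0, 0], [2, 2]])).validate(3, 3)


@pytest.fixture(scope="module")
def aligned_session():
    ses = generate_session(make_task_config("phrase", seed=21, duration_s=20.0))
    paths, warped = align_emg_to_audio(ses)
    return ses, paths, warped


class TestAlignEmgToAudio:
    def test_path_stays_near_diagonal(self, aligned_session):
        # stochastic EMG carriers put a floor on hop-level path jitter, so
        # the near-identity check uses median/offset statistics rather
        # than the idealized +-1-hop bound (see decisions ledger)
        _, paths, _ = aligned_session
        for p in paths:
            off = p.pairs[:, 0] - p.pairs[:, 1]
            assert abs(np.median(off)) <= 2
            assert np.mean(np.abs(off) <= 10) > 0.7
            assert np.abs(off).max() < 100

    def test_warping_near_identity_at_envelope_level(self, aligned_session):
        from emg2prosody.align import _upsample

        ses, _, warped = aligned_session
        for ch, w in zip(ses.emg[:3], warped[:3]):
            up = _upsample(ch, ses.audio.rate)
            n = min(up.n_samples, w.n_samples)
            k = int(0.01 * ses.audio.rate)
            e1 = np.sqrt(np.convolve(up.samples[:n] ** 2, np.ones(k) / k, "same"))
            e2 = np.sqrt(np.convolve(w.samples[:n] ** 2, np.ones(k) / k, "same"))
            assert np.corrcoef(e1, e2)[0, 1] > 0.85

    def test_delay_shifts_path(self):
        ses = generate_session(make_task_config("phrase", seed=22, duration_s=20.0))
        delay = int(0.100 * ses.emg[0].rate)
        for i, ch in enumerate(ses.emg):
            ses.emg[i] = SignalTrack(
                np.concatenate([np.zeros(delay), ch.samples]), ch.rate
            )
        paths, _ = align_emg_to_audio(ses)
        offsets = [np.median(p.pairs[:, 0] - p.pairs[:, 1]) for p in paths]
        assert np.median(offsets) == pytest.approx(10, abs=3)

    def test_output_duration_matches_audio(self, aligned_session):
        ses, _, warped = aligned_session
        for w in warped:
            assert w.n_samples == ses.audio.n_samples
            assert w.rate == ses.audio.rate

    def test_path_validity(self, aligned_session):
        ses, paths, _ = aligned_session
        n = int(ses.emg[0].duration / 0.010)
        m = int(ses.audio.duration / 0.010)
        for p in paths:
            p.validate(n, m)
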