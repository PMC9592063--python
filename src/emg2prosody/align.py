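"""EMG-to-audio time alignment via exact dynamic time warping.

Each EMG channel is upsampled to the audio rate, summarized as per-hop
envelope features, aligned to the matching audio features with DTW, and
resampled along the warp path onto the audio timeline.  Two DTW routines are
provided: a quadratic-memory full-DP oracle and an exact linear-memory
divide-and-conquer variant that returns the identical optimal cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from . import _dtwkernels as _k
from .signals import SignalTrack
from .synthgen import SynthSession

__all__ = [
    "WarpPath",
    "MemMeter",
    "envelope_features",
    "dtw_full",
    "dtw_lowmem",
    "align_emg_to_audio",
]

_BAND_EDGES_HZ = (0.0, 100.0, 300.0, 1000.0)  # last band extends to Nyquist
_EPS = 1e-12


@dataclass
class WarpPath:
    """Monotone step path through the (index_a, index_b) grid."""

    pairs: np.ndarray  # (L, 2) int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2 or not len(self.pairs):
            raise ValueError("path must be a nonempty (L, 2) index array")

    def validate(self, n: int, m: int) -> None:
        p = self.pairs
        if tuple(p[0]) != (0, 0) or tuple(p[-1]) != (n - 1, m - 1):
            raise ValueError("path must run corner to corner")
        steps = np.diff(p, axis=0)
        ok = ((steps >= 0) & (steps <= 1)).all() and (steps.sum(axis=1) >= 1).all()
        if not ok:
            raise ValueError("path steps must be in {(1,0),(0,1),(1,1)}")

    def transposed(self) -> "WarpPath":
        return WarpPath(self.pairs[:, ::-1].copy())

    def __len__(self) -> int:
        return len(self.pairs)


class MemMeter:
    """Counts DP cells concurrently allocated, to assert O(N+M) behaviour."""

    def __init__(self) -> None:
        self.current = 0
        self.peak = 0

    def alloc(self, n: int) -> None:
        self.current += n
        self.peak = max(self.peak, self.current)

    def free(self, n: int) -> None:
        self.current -= n


def _as_matrix(seq) -> np.ndarray:
    arr = np.asarray(seq, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("sequences must be nonempty 1-D or (n, d) arrays")
    return np.ascontiguousarray(arr)


def path_cost(a, b, path: WarpPath) -> float:
    a, b = _as_matrix(a), _as_matrix(b)
    ia, ib = path.pairs[:, 0], path.pairs[:, 1]
    return float(np.sqrt(((a[ia] - b[ib]) ** 2).sum(axis=1)).sum())


def dtw_full(a, b) -> tuple[float, WarpPath]:
    """Exact DTW with a full DP table (quadratic memory); the oracle."""
    a, b = _as_matrix(a), _as_matrix(b)
    cost, steps = _k.full_dp(a, b)
    i, j = a.shape[0] - 1, b.shape[0] - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        st = steps[i, j]
        if st == 2:
            i, j = i - 1, j - 1
        elif st == 1:
            i -= 1
        else:
            j -= 1
        rev.append((i, j))
    path = WarpPath(np.asarray(rev[::-1]))
    path.validate(a.shape[0], b.shape[0])
    return float(cost), path


def _forward(a, b, meter: MemMeter | None) -> np.ndarray:
    m = b.shape[0]
    row0 = np.empty(m)
    row1 = np.empty(m)
    if meter is not None:
        meter.alloc(2 * m)
    out = _k.forward_row(a, b, row0, row1).copy()
    if meter is not None:
        meter.free(2 * m)
    return out


_BASE_CELLS = 4096  # below this, fall back to the full table


def _lowmem_recurse(a, b, i0, j0, out: list, meter: MemMeter | None) -> None:
    n, m = a.shape[0], b.shape[0]
    if n * m <= _BASE_CELLS or n <= 2:
        if meter is not None:
            meter.alloc(n * m)
        _, path = dtw_full(a, b)
        if meter is not None:
            meter.free(n * m)
        for (pi, pj) in path.pairs:
            out.append((i0 + pi, j0 + pj))
        return
    mid = n // 2
    f = _forward(a[: mid + 1], b, meter)
    g = _forward(a[mid:][::-1], b[::-1], meter)[::-1]
    d_mid = np.sqrt(((a[mid][None, :] - b) ** 2).sum(axis=1))
    total = f + g - d_mid
    j_star = int(np.argmin(total))
    left: list = []
    _lowmem_recurse(a[: mid + 1], b[: j_star + 1], i0, j0, left, meter)
    right: list = []
    _lowmem_recurse(
        a[mid:], b[j_star:], i0 + mid, j0 + j_star, right, meter
    )
    out.extend(left)
    out.extend(right[1:])  # (mid, j_star) is shared


def dtw_lowmem(a, b, meter: MemMeter | None = None) -> tuple[float, WarpPath]:
    """Exact DTW in O(N+M) working memory via midpoint divide-and-conquer.

    The returned cost equals :func:`dtw_full` exactly; among equal-cost ties
    the path may differ.
    """
    a, b = _as_matrix(a), _as_matrix(b)
    pairs: list = []
    _lowmem_recurse(a, b, 0, 0, pairs, meter)
    path = WarpPath(np.asarray(pairs))
    path.validate(a.shape[0], b.shape[0])
    return path_cost(a, b, path), path


def envelope_features(track: SignalTrack, hop: float) -> np.ndarray:
    """Per-hop log-energy plus four log band energies, z-scored per track."""
    if hop <= 0:
        raise ValueError("hop must be positive")
    n_hop = int(round(hop * track.rate))
    n = int(np.floor(track.duration / hop))
    if n < 1 or n_hop < 2:
        raise ValueError("track shorter than one hop")
    x = track.samples[: n * n_hop].reshape(n, n_hop)
    feats = np.empty((n, 5))
    feats[:, 0] = np.log(np.mean(x * x, axis=1) + _EPS)
    spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_hop, 1.0 / track.rate)
    edges = list(_BAND_EDGES_HZ) + [track.rate / 2.0 + 1.0]
    for bi in range(4):
        sel = (freqs >= edges[bi]) & (freqs < edges[bi + 1])
        feats[:, 1 + bi] = np.log(spec[:, sel].sum(axis=1) + _EPS)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd < _EPS] = 1.0
    return (feats - mu) / sd


def _upsample(track: SignalTrack, fs_out: float) -> SignalTrack:
    # FFT resampling: the 2222 -> 44100 ratio reduces only to 22050/1111,
    # which makes polyphase filters prohibitively long
    n_out = int(round(track.duration * fs_out))
    y = sps.resample(track.samples, n_out)
    return SignalTrack(samples=y, rate=fs_out, units=track.units)


def _with_time_anchor(feats: np.ndarray, scale: int, alpha: float) -> np.ndarray:
    """Append a linear time-index column.

    Envelope features carry no alignment information inside steady spans
    (constant activation, pauses), where unanchored DTW wanders by hundreds
    of milliseconds.  A weak index component makes deviation from the
    diagonal cost a little everywhere, pinning uninformative spans while
    genuine offsets (which realign every transient) still win.
    """
    n = feats.shape[0]
    anchor = alpha * 2.0 * (np.arange(n) - n / 2.0) / scale
    return np.column_stack([feats, anchor])


def align_emg_to_audio(
    session: SynthSession,
    hop: float = 0.010,
    smooth_hops: int = 75,
    anchor_alpha: float = 8.0,
    mode: str = "joint",
) -> tuple[list[WarpPath], list[SignalTrack]]:
    """Align the EMG channels to the session audio.

    Channels are upsampled to the audio rate and summarized as per-hop
    envelope features.  In ``"joint"`` mode (default) one exact DTW path is
    computed between the channel-averaged EMG features and the audio
    features and applied to every channel: all sensors share one
    acquisition clock, and channels whose envelopes are driven by pitch
    rather than loudness carry no usable alignment signal of their own.
    ``"per_channel"`` computes 8 independent paths instead.

    The hop-level warp map is low-pass smoothed (physiological warps are
    smooth; the stochastic EMG carrier leaves jitter on the raw path) and
    each channel is resampled along it onto the audio timeline, with tied
    matches collapsed by averaging.
    """
    audio = session.audio
    feats_audio = envelope_features(audio, hop)
    n_b = feats_audio.shape[0]
    t_samples = np.arange(audio.n_samples) / audio.rate
    hop_centers_b = (np.arange(n_b) + 0.5) * hop

    ups = [_upsample(ch, audio.rate) for ch in session.emg]
    feats_emg = [envelope_features(u, hop) for u in ups]

    def _warp_map(path: WarpPath) -> np.ndarray:
        # audio hop j -> mean matched EMG hop index
        sums = np.zeros(n_b)
        counts = np.zeros(n_b)
        np.add.at(sums, path.pairs[:, 1], path.pairs[:, 0])
        np.add.at(counts, path.pairs[:, 1], 1.0)
        m = sums / np.maximum(counts, 1.0)
        if smooth_hops > 1 and n_b > smooth_hops:
            m = ndimage.uniform_filter1d(m, smooth_hops)
            m = np.maximum.accumulate(m)
        return m

    def _anchored(f: np.ndarray) -> np.ndarray:
        scale = max(n_b, max(g.shape[0] for g in feats_emg))
        return _with_time_anchor(f, scale, anchor_alpha)

    fa = _anchored(feats_audio)
    if mode == "joint":
        n_min = min(f.shape[0] for f in feats_emg)
        stacked = np.mean([f[:n_min] for f in feats_emg], axis=0)
        mu, sd = stacked.mean(axis=0), stacked.std(axis=0)
        sd[sd < _EPS] = 1.0
        _, path = dtw_lowmem(_anchored((stacked - mu) / sd), fa)
        paths = [path] * len(session.emg)
        maps = [_warp_map(path)] * len(session.emg)
    elif mode == "per_channel":
        paths = [dtw_lowmem(_anchored(f), fa)[1] for f in feats_emg]
        maps = [_warp_map(p) for p in paths]
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    warped: list[SignalTrack] = []
    for up, m in zip(ups, maps):
        warp_t = np.interp(t_samples, hop_centers_b, (m + 0.5) * hop)
        y = np.interp(warp_t, np.arange(up.n_samples) / up.rate, up.samples)
        warped.append(SignalTrack(samples=y, rate=audio.rate, units=up.units))
    return paths, warped
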