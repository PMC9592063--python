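"""Per-frame sEMG feature battery.

Twenty feature families per channel and frame: six time-domain statistics,
nine periodogram-derived spectral statistics, 24 mel-frequency cepstral
coefficients, 12 Daubechies-2 wavelet statistics (3 stats x 4 detail levels),
and three cross-channel families (coherence, beta-band coherence, peak
normalized cross-correlation) over unordered channel pairs.  Symmetric
duplicates (pair j < i) are never generated, and the realized cascaded
dimension is computed rather than assumed.

All routines are batch-oriented: ``frames`` arguments accept a single frame
or an (n_frames, frame_len) array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

__all__ = [
    "FrameSpec",
    "FeatureMatrix",
    "frame_signal",
    "time_domain_features",
    "spectral_features",
    "mfcc_features",
    "wavelet_features",
    "pairwise_features",
    "assemble_features",
    "extract_all",
    "feature_dimension",
]

# dead-band for zero-crossing / slope-sign-change counting, x frame RMS
_DEADBAND_RMS_FRACTION = 0.01
_LOG_FLOOR = 1e-12

F0_FRAMESPEC_DEFAULTS = (0.040, 0.020)
INTENSITY_FRAMESPEC_DEFAULTS = (0.150, 0.030)


@dataclass(frozen=True)
class FrameSpec:
    """Frame length and hop in seconds (40/20 ms f0 stream, 150/30 ms
    intensity stream)."""

    frame_len: float
    step: float

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.frame_len):
            raise ValueError("need 0 < step <= frame_len")

    def n_frames(self, duration: float) -> int:
        return int(np.floor((duration - self.frame_len) / self.step + 1e-9)) + 1

    def frame_times(self, duration: float) -> np.ndarray:
        return self.step * np.arange(max(self.n_frames(duration), 0))


@dataclass
class FeatureMatrix:
    frame_times: np.ndarray
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValueError("duplicated feature names")
        if self.values.shape != (len(self.frame_times), len(self.feature_names)):
            raise ValueError("values shape does not match times/names")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _batch(frames) -> tuple[np.ndarray, bool]:
    arr = np.asarray(frames, dtype=np.float64)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim != 2:
        raise ValueError("frames must be 1-D or 2-D")
    return arr, False


def frame_signal(samples, rate: float, spec: FrameSpec) -> np.ndarray:
    """Slice a signal into frames on the ``t = k * step`` grid.

    Frame k starts at sample ``round(k * step * rate)`` (per-frame rounding,
    so the grid does not drift), has ``round(frame_len * rate)`` samples, and
    a trailing partial frame is dropped.
    """
    samples = np.asarray(samples, dtype=np.float64)
    flen = int(round(spec.frame_len * rate))
    duration = samples.size / rate
    n = spec.n_frames(duration)
    if n < 1 or flen > samples.size:
        return np.zeros((0, max(flen, 1)))
    starts = np.round(np.arange(n) * spec.step * rate).astype(int)
    while n > 0 and starts[n - 1] + flen > samples.size:
        n -= 1
    starts = starts[:n]
    return samples[starts[:, None] + np.arange(flen)[None, :]]


# ---------------------------------------------------------------------------
# time domain


def time_domain_features(frames) -> dict[str, np.ndarray]:
    """MAV, RMS, variance, waveform length, zero crossings, slope sign
    changes (the latter two with a dead-band of 1% of frame RMS)."""
    x, single = _batch(frames)
    if x.shape[1] < 3:
        raise ValueError("frames must have at least 3 samples")
    rms = np.sqrt(np.mean(x * x, axis=1))
    eps = _DEADBAND_RMS_FRACTION * rms
    d = np.diff(x, axis=1)
    zc = np.sum(
        (x[:, :-1] * x[:, 1:] < 0) & (np.abs(d) > eps[:, None]), axis=1
    ).astype(float)
    d1 = x[:, 1:-1] - x[:, :-2]
    d2 = x[:, 1:-1] - x[:, 2:]
    ssc = np.sum(
        (d1 * d2 > 0)
        & (np.maximum(np.abs(d1), np.abs(d2)) > eps[:, None]),
        axis=1,
    ).astype(float)
    out = {
        "mav": np.mean(np.abs(x), axis=1),
        "rms": rms,
        "var": np.var(x, axis=1),
        "wl": np.sum(np.abs(d), axis=1),
        "zc": zc,
        "ssc": ssc,
    }
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


# ---------------------------------------------------------------------------
# spectral


def spectral_features(frames, fs: float) -> dict[str, np.ndarray]:
    """Statistics of the one-sided periodogram.

    mean/median/peak frequency, mean power density, central-frequency
    variance, unnormalized spectral moments k = 1..3, and the waveform length
    of the periodogram curve ("power density wavelength").
    """
    x, single = _batch(frames)
    if x.shape[1] < 16:
        raise ValueError("frames must have at least 16 samples")
    freqs, p = sps.periodogram(x, fs=fs, axis=1)
    total = p.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    mean_f = (p * freqs[None, :]).sum(axis=1) / safe
    cum = np.cumsum(p, axis=1)
    med_idx = np.argmax(cum >= (total / 2.0)[:, None], axis=1)
    median_f = freqs[med_idx]
    peak_f = freqs[np.argmax(p, axis=1)]
    cfv = (p * (freqs[None, :] - mean_f[:, None]) ** 2).sum(axis=1) / safe
    moments = {
        f"sm{k}": (p * freqs[None, :] ** k).sum(axis=1) for k in (1, 2, 3)
    }
    out = {
        "meanfreq": np.where(total > 0, mean_f, 0.0),
        "medianfreq": np.where(total > 0, median_f, 0.0),
        "peakfreq": np.where(total > 0, peak_f, 0.0),
        "meanpd": p.mean(axis=1),
        "cfv": np.where(total > 0, cfv, 0.0),
        **moments,
        "pdwl": np.sum(np.abs(np.diff(p, axis=1)), axis=1),
    }
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


# ---------------------------------------------------------------------------
# cepstral


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, fs: float) -> np.ndarray:
    edges_mel = np.linspace(0.0, _mel(fs / 2.0), n_filters + 2)
    edges_hz = _mel_inv(edges_mel)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    bank = np.zeros((n_filters, freqs.size))
    for j in range(n_filters):
        lo, mid, hi = edges_hz[j], edges_hz[j + 1], edges_hz[j + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        bank[j] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def mfcc_features(frames, fs: float, n_coeff: int = 24, n_filters: int = 26):
    """Mel-frequency cepstral coefficients (c0 retained).

    Triangular mel filterbank over [0, fs/2] applied to the magnitude
    spectrum, log with a floor guard, orthonormal DCT-II, first ``n_coeff``
    coefficients.
    """
    x, single = _batch(frames)
    if x.shape[1] < 32:
        raise ValueError("frames must have at least 32 samples")
    n_fft = int(2 ** np.ceil(np.log2(x.shape[1])))
    mag = np.abs(np.fft.rfft(x, n_fft, axis=1))
    bank = _mel_filterbank(n_filters, n_fft, fs)
    energies = mag @ bank.T
    log_e = np.log(np.maximum(energies, _LOG_FLOOR))
    coeffs = sfft.dct(log_e, type=2, norm="ortho", axis=1)[:, :n_coeff]
    return coeffs[0] if single else coeffs


# ---------------------------------------------------------------------------
# wavelet

_SQRT3 = np.sqrt(3.0)
_DB2_H = np.array([1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]) / (
    4.0 * np.sqrt(2.0)
)
_DB2_G = np.array([_DB2_H[3], -_DB2_H[2], _DB2_H[1], -_DB2_H[0]])


def _dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """One periodized db2 analysis step along axis 1 (batch x samples)."""
    padded = False
    if x.shape[1] % 2:
        x = np.concatenate([x, x[:, -1:]], axis=1)
        padded = True
    n = x.shape[1]
    ext = np.concatenate([x, x[:, :3]], axis=1)
    half = n // 2
    a = np.zeros((x.shape[0], half))
    d = np.zeros((x.shape[0], half))
    for m in range(4):
        seg = ext[:, m : m + n : 2][:, :half]
        a += _DB2_H[m] * seg
        d += _DB2_G[m] * seg
    return a, d, padded


def dwt_db2(frames, levels: int = 4):
    """Periodized db2 decomposition; returns (details [d1..dL], approx,
    padded_flag).  Odd lengths are extended by repeating the last sample."""
    x, single = _batch(frames)
    details = []
    padded = False
    for _ in range(levels):
        if x.shape[1] < 4:
            x = np.pad(x, ((0, 0), (0, 4 - x.shape[1])), mode="edge")
            padded = True
        x, d, p = _dwt_step(x)
        padded = padded or p
        details.append(d)
    if single:
        details = [d[0] for d in details]
        x = x[0]
    return details, x, padded


def wavelet_features(frames) -> dict[str, np.ndarray]:
    """max |coefficient|, mean and variance of each of 4 db2 detail levels."""
    x, single = _batch(frames)
    if x.shape[1] < 16:
        x = np.pad(x, ((0, 0), (0, 16 - x.shape[1])), mode="constant")
    details, _, _ = dwt_db2(x, levels=4)
    out = {}
    for lev, d in enumerate(details, start=1):
        out[f"dwtmax_l{lev}"] = np.max(np.abs(d), axis=1)
        out[f"dwtmean_l{lev}"] = np.mean(d, axis=1)
        out[f"dwtvar_l{lev}"] = np.var(d, axis=1)
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


# ---------------------------------------------------------------------------
# cross-channel

_COH_NPERSEG = 32
_COH_NOVERLAP = 16
_COH_BAND = (20.0, 450.0)
_BETA_BAND = (15.0, 30.0)


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    sel = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if sel.size == 0:  # degenerate resolution: fall back to the nearest bin
        sel = np.array([np.argmin(np.abs(freqs - 0.5 * (band[0] + band[1])))])
    return sel


def pairwise_features(
    frames_by_channel: np.ndarray,
    fs: float,
    chunk: int = 2048,
) -> dict[str, np.ndarray]:
    """Cross-channel families over unordered pairs i <= j (self-pairs kept).

    coherence: magnitude-squared coherence (Welch within frame, segment 32,
    overlap 16) averaged over 20-450 Hz; beta_coherence: same over 15-30 Hz;
    cross_correlation: max |normalized cross-correlation| over lags within
    +-frame_len/2.
    """
    fbc = np.asarray(frames_by_channel, dtype=np.float64)
    if fbc.ndim != 3:
        raise ValueError("expected (n_channels, n_frames, frame_len)")
    n_ch, n_frames, flen = fbc.shape
    nseg = (flen - _COH_NPERSEG) // _COH_NOVERLAP + 1
    win = sps.windows.hann(_COH_NPERSEG, sym=False)
    freqs_w = np.fft.rfftfreq(_COH_NPERSEG, 1.0 / fs)
    bins_main = _band_bins(freqs_w, _COH_BAND)
    bins_beta = _band_bins(freqs_w, _BETA_BAND)
    nfft_xc = int(2 ** np.ceil(np.log2(2 * flen)))
    max_lag = flen // 2
    lag_idx = np.concatenate(
        [np.arange(max_lag + 1), np.arange(nfft_xc - max_lag, nfft_xc)]
    )
    pairs = [(i, j) for i in range(n_ch) for j in range(i, n_ch)]
    out = {
        f"{fam}": np.zeros((len(pairs), n_frames))
        for fam in ("coherence", "beta_coherence", "cross_correlation")
    }
    for lo in range(0, n_frames, chunk):
        hi = min(lo + chunk, n_frames)
        blk = fbc[:, lo:hi, :]
        # Welch segments for coherence
        starts = np.arange(nseg) * _COH_NOVERLAP
        segs = blk[:, :, starts[:, None] + np.arange(_COH_NPERSEG)[None, :]]
        segs = (segs - segs.mean(axis=3, keepdims=True)) * win
        Z = np.fft.rfft(segs, axis=3)  # (ch, frame, seg, bin)
        auto = np.mean(np.abs(Z) ** 2, axis=2)  # (ch, frame, bin)
        # normalized cross-correlation spectra
        centered = blk - blk.mean(axis=2, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=2))
        X = np.fft.rfft(centered, nfft_xc, axis=2)
        for p, (i, j) in enumerate(pairs):
            cross = np.mean(Z[i] * np.conj(Z[j]), axis=1)  # (frame, bin)
            denom = auto[i] * auto[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                coh = np.abs(cross) ** 2 / denom
            coh = np.nan_to_num(coh, nan=0.0, posinf=0.0, neginf=0.0)
            out["coherence"][p, lo:hi] = coh[:, bins_main].mean(axis=1)
            out["beta_coherence"][p, lo:hi] = coh[:, bins_beta].mean(axis=1)
            cc = np.fft.irfft(X[i] * np.conj(X[j]), nfft_xc, axis=1)
            denom_cc = norms[i] * norms[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                ccn = np.abs(cc[:, lag_idx]) / denom_cc[:, None]
            ccn = np.nan_to_num(ccn, nan=0.0, posinf=0.0, neginf=0.0)
            out["cross_correlation"][p, lo:hi] = ccn.max(axis=1)
    out["_pairs"] = pairs  # type: ignore[assignment]
    return out


# ---------------------------------------------------------------------------
# assembly

_PER_CHANNEL_ORDER = (
    ("td", ("mav", "rms", "var", "wl", "zc", "ssc")),
    (
        "spec",
        (
            "meanfreq",
            "medianfreq",
            "peakfreq",
            "meanpd",
            "cfv",
            "sm1",
            "sm2",
            "sm3",
            "pdwl",
        ),
    ),
    ("mfcc", tuple(f"c{k:02d}" for k in range(24))),
    (
        "dwt",
        tuple(
            f"{stat}_l{lev}"
            for stat in ("dwtmax", "dwtmean", "dwtvar")
            for lev in (1, 2, 3, 4)
        ),
    ),
)
_PAIR_FAMILIES = ("coherence", "beta_coherence", "cross_correlation")


def feature_dimension(n_channels: int) -> int:
    """Closed-form cascaded dimension after symmetric-duplicate removal."""
    per_channel = sum(len(names) for _, names in _PER_CHANNEL_ORDER)
    n_pairs = n_channels * (n_channels + 1) // 2
    return per_channel * n_channels + len(_PAIR_FAMILIES) * n_pairs


def assemble_features(
    frame_times: np.ndarray,
    blocks: list[tuple[list[str], np.ndarray]],
) -> FeatureMatrix:
    """Cascade named feature blocks into one matrix (one row per frame)."""
    n = len(frame_times)
    names: list[str] = []
    cols: list[np.ndarray] = []
    for block_names, vals in blocks:
        vals = np.asarray(vals, dtype=np.float64)
        if vals.shape != (n, len(block_names)):
            raise ValueError("frame-count mismatch between feature blocks")
        names.extend(block_names)
        cols.append(vals)
    return FeatureMatrix(
        frame_times=np.asarray(frame_times, dtype=np.float64),
        feature_names=names,
        values=np.hstack(cols) if cols else np.zeros((n, 0)),
    )


def extract_all(
    channels: list[np.ndarray] | np.ndarray,
    rate: float,
    spec: FrameSpec,
) -> FeatureMatrix:
    """Full battery for a multi-channel signal under one frame spec."""
    framed = [frame_signal(ch, rate, spec) for ch in channels]
    n_frames = min(f.shape[0] for f in framed)
    framed = [f[:n_frames] for f in framed]
    times = spec.step * np.arange(n_frames)
    blocks: list[tuple[list[str], np.ndarray]] = []
    for c, frames in enumerate(framed, start=1):
        td = time_domain_features(frames)
        sf = spectral_features(frames, rate)
        mf = mfcc_features(frames, rate)
        wf = wavelet_features(frames)
        for fam, keys in _PER_CHANNEL_ORDER:
            if fam == "td":
                vals = np.column_stack([td[k] for k in keys])
            elif fam == "spec":
                vals = np.column_stack([sf[k] for k in keys])
            elif fam == "mfcc":
                vals = mf
            else:
                vals = np.column_stack([wf[k] for k in keys])
            blocks.append(([f"{fam}_{k}/ch{c}" for k in keys], vals))
    fbc = np.stack(framed, axis=0)
    pw = pairwise_features(fbc, rate)
    pairs = pw.pop("_pairs")
    for fam in _PAIR_FAMILIES:
        names = [f"{fam}/ch{i + 1}-ch{j + 1}" for (i, j) in pairs]
        blocks.append((names, pw[fam].T))
    return assemble_features(times, blocks)
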