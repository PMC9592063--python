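"""Acoustic target extraction: f0 and intensity contours.

The f0 tracker follows the classic normalized-autocorrelation design: per
frame, the autocorrelation of the Gaussian-windowed segment is divided by the
autocorrelation of the window itself, local maxima in the admissible lag range
become voiced candidates, and a dynamic-programming path finder picks the
least-cost track under octave / octave-jump / voiced-unvoiced costs.

The intensity contour is the squared, DC-removed signal convolved with a
unit-area Kaiser window whose sidelobes are below -190 dB, expressed in dB and
optionally shifted to dB SPL with a meter-based calibration offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import Contour, SignalTrack

__all__ = [
    "PitchParams",
    "CalibrationInfo",
    "extract_f0",
    "extract_intensity",
    "calibrate_spl",
    "uncalibrate_spl",
    "hz_to_semitones",
    "semitones_to_hz",
    "frame_targets",
]

# dB reference power: 10*log10(0.5 / _DB_REF) ~ 91 dB for a full-scale sine,
# i.e. the conventional 20 uPa hearing-threshold reference squared.
_DB_REF = 4e-10
_DB_FLOOR_GUARD = 1e-30  # power floor so silence maps to a finite dB value

# Kaiser shape parameter; sidelobes fall below -190 dB for beta >~ 20, we use
# the more conservative 20*pi/sqrt(2).
_KAISER_BETA = 20.0 * np.pi / np.sqrt(2.0)


@dataclass
class PitchParams:
    """Configuration of the autocorrelation pitch tracker.

    Path-cost defaults mirror the published defaults of the reference
    implementation (silence 0.03, voicing 0.45, octave 0.01, octave-jump
    0.35, voiced/unvoiced 0.14).
    """

    f_min: float = 65.0
    f_max: float = 475.0
    time_step: float | None = None  # defaults to 0.75 / f_min
    silence_threshold: float = 0.03
    voicing_threshold: float = 0.45
    octave_cost: float = 0.01
    octave_jump_cost: float = 0.35
    voiced_unvoiced_cost: float = 0.14
    max_candidates: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.time_step is None:
            self.time_step = 0.75 / self.f_min
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def window_duration(self) -> float:
        """Analysis frame length in seconds (three longest periods)."""
        return 3.0 / self.f_min


@dataclass
class CalibrationInfo:
    """SPL calibration: meter reading vs the uncalibrated contour level."""

    meter_reading: float  # dB SPL measured at the microphone
    measured_level: float  # uncalibrated dB of the same recording
    offset: float = field(init=False)

    def __post_init__(self) -> None:
        self.offset = float(self.meter_reading - self.measured_level)
        if not np.isfinite(self.offset):
            raise ValueError("calibration offset must be finite")


def _frame_grid(duration: float, window: float, step: float) -> tuple[int, float]:
    """Number of frames and the centre time of the first frame.

    Frames of length ``window`` at ``step`` spacing, centred as a block within
    ``duration`` (no drift: frame k is at ``t0 + k*step`` exactly).
    """
    n = int(np.floor((duration - window) / step + 1e-9)) + 1
    if n < 1:
        return 0, 0.0
    leftover = duration - (window + (n - 1) * step)
    return n, leftover / 2.0 + window / 2.0


def _gaussian_window(n: int) -> np.ndarray:
    # exp(-12 (t/T - 1/2)^2) rescaled to vanish at the edges
    t = (np.arange(n) + 0.5) / n
    w = np.exp(-12.0 * (t - 0.5) ** 2)
    edge = np.exp(-12.0 * 0.25)
    return (w - edge) / (1.0 - edge)


def _parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (i-1, i, i+1); returns (offset, value)."""
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom >= 0 or abs(denom) < 1e-300:
        return 0.0, float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return d, float(b - 0.25 * (a - c) * d)


def _frame_candidates(
    r: np.ndarray,
    lag_min: int,
    lag_max: int,
    fs: float,
    params: PitchParams,
    local_peak: float,
    global_peak: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Voiced candidates (freq, strength) plus the unvoiced candidate (f=0)."""
    lo = max(lag_min, 2)
    hi = min(lag_max, r.size - 2)
    freqs = [0.0]
    intensity = local_peak / global_peak if global_peak > 0 else 0.0
    strengths = [
        params.voicing_threshold
        + max(
            0.0,
            2.0
            - intensity * (1.0 + params.voicing_threshold) / params.silence_threshold,
        )
    ]
    if hi > lo:
        seg = r[lo - 1 : hi + 2]
        is_max = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]) & (seg[1:-1] > 0.0)
        for idx in np.nonzero(is_max)[0]:
            lag = lo + idx
            off, val = _parabolic_peak(r, lag)
            tau = (lag + off) / fs
            # 3% slack at the range edges absorbs interpolation rounding for
            # true f0 at exactly f_min/f_max; the path is clipped afterwards
            if not (1.0 / (1.03 * params.f_max) <= tau <= 1.03 / params.f_min):
                continue
            val = min(val, 1.0)
            strength = val - params.octave_cost * np.log2(params.f_min * tau)
            freqs.append(1.0 / tau)
            strengths.append(strength)
    f = np.asarray(freqs)
    s = np.asarray(strengths)
    if f.size > params.max_candidates:
        keep = np.argsort(s[1:])[::-1][: params.max_candidates - 1] + 1
        keep = np.concatenate([[0], np.sort(keep)])
        f, s = f[keep], s[keep]
    return f, s


def _viterbi_path(
    cand_freqs: list[np.ndarray],
    cand_strengths: list[np.ndarray],
    params: PitchParams,
) -> np.ndarray:
    """Least-cost (max total strength minus transition cost) frequency path."""
    n = len(cand_freqs)
    delta = cand_strengths[0].astype(np.float64).copy()
    back: list[np.ndarray] = []
    for k in range(1, n):
        f_prev = cand_freqs[k - 1]
        f_cur = cand_freqs[k]
        vprev = f_prev > 0
        vcur = f_cur > 0
        trans = np.zeros((f_prev.size, f_cur.size))
        both = np.outer(vprev, vcur)
        either = np.logical_xor.outer(vprev, vcur)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(
                np.log2(np.outer(f_prev, np.ones_like(f_cur)))
                - np.log2(np.outer(np.ones_like(f_prev), f_cur))
            )
        trans[both] = params.octave_jump_cost * ratio[both]
        trans[either] = params.voiced_unvoiced_cost
        score = delta[:, None] - trans + cand_strengths[k][None, :]
        back.append(np.argmax(score, axis=0))
        delta = np.max(score, axis=0)
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for k in range(n - 2, -1, -1):
        path[k] = back[k][path[k + 1]]
    return np.array([cand_freqs[k][path[k]] for k in range(n)])


def extract_f0(audio: SignalTrack, params: PitchParams | None = None) -> Contour:
    """Track the fundamental-frequency contour of ``audio``.

    Returns a contour in Hz on a uniform ``params.time_step`` grid; frames
    judged unvoiced by the path finder are undefined.
    """
    params = params or PitchParams()
    if audio.rate < 4.0 * params.f_max:
        raise ValueError("sampling rate must be at least 4 * f_max")
    n_win = int(round(params.window_duration * audio.rate))
    n_frames, t_first = _frame_grid(
        audio.duration, params.window_duration, params.time_step
    )
    if n_frames < 1:
        return Contour(np.zeros(0), np.zeros(0), unit="Hz", defined=np.zeros(0, bool))

    x = audio.samples - np.mean(audio.samples)
    global_peak = float(np.max(np.abs(x))) if x.size else 0.0
    times = t_first + params.time_step * np.arange(n_frames)
    if global_peak == 0.0:
        return Contour(times, np.full(n_frames, np.nan), unit="Hz")

    window = _gaussian_window(n_win)
    nfft = int(2 ** np.ceil(np.log2(2 * n_win)))
    rw = np.fft.irfft(np.abs(np.fft.rfft(window, nfft)) ** 2)
    rw = rw / rw[0]
    lag_min = int(np.floor(audio.rate / params.f_max))
    lag_max = int(np.ceil(audio.rate / params.f_min)) + 1
    max_lag = min(lag_max + 2, n_win - 1)

    cand_f: list[np.ndarray] = []
    cand_s: list[np.ndarray] = []
    centers = np.round(times * audio.rate).astype(int)
    starts = np.clip(centers - n_win // 2, 0, max(0, x.size - n_win))
    chunk = 1024
    for c0 in range(0, n_frames, chunk):
        idx = starts[c0 : c0 + chunk, None] + np.arange(n_win)[None, :]
        frames = x[idx]
        frames = frames - frames.mean(axis=1, keepdims=True)
        peaks = np.max(np.abs(frames), axis=1)
        fw = frames * window[None, :]
        spec = np.fft.rfft(fw, nfft, axis=1)
        r = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, : max_lag + 2]
        norm = r[:, :1].copy()
        norm[norm <= 0] = 1.0
        r = r / norm / rw[None, : max_lag + 2]
        for j in range(r.shape[0]):
            f, s = _frame_candidates(
                r[j], lag_min, lag_max, audio.rate, params, peaks[j], global_peak
            )
            cand_f.append(f)
            cand_s.append(s)

    path_f = _viterbi_path(cand_f, cand_s, params)
    values = np.where(
        path_f > 0, np.clip(path_f, params.f_min, params.f_max), np.nan
    )
    return Contour(times, values, unit="Hz")


def extract_intensity(
    audio: SignalTrack,
    f_min: float = 65.0,
    time_step: float | None = None,
) -> Contour:
    """Intensity contour in (uncalibrated) dB.

    The DC-removed signal is squared and convolved with a unit-area Kaiser
    window of duration ``3.2 / f_min``; the smoothed power is sampled on a
    uniform grid and converted to dB re the internal power reference.
    """
    if audio.n_samples == 0:
        raise ValueError("empty audio")
    win_dur = 3.2 / f_min
    if time_step is None:
        time_step = win_dur / 4.0
    n_win = int(round(win_dur * audio.rate))
    if n_win >= audio.n_samples:
        return Contour(np.zeros(0), np.zeros(0), unit="dB", defined=np.zeros(0, bool))
    w = sps.windows.kaiser(n_win, _KAISER_BETA)
    w = w / np.sum(w)
    x = audio.samples - np.mean(audio.samples)
    power = sps.fftconvolve(x * x, w, mode="same")
    n_frames, t_first = _frame_grid(audio.duration, win_dur, time_step)
    times = t_first + time_step * np.arange(n_frames)
    idx = np.clip(np.round(times * audio.rate).astype(int), 0, x.size - 1)
    p = np.maximum(power[idx], _DB_FLOOR_GUARD)
    values = 10.0 * np.log10(p / _DB_REF)
    return Contour(times, values, unit="dB")


def calibrate_spl(contour: Contour, cal: CalibrationInfo) -> Contour:
    """Shift an uncalibrated dB contour to dB SPL by the calibration offset."""
    if contour.unit != "dB":
        raise ValueError(f"expected a dB contour, got unit {contour.unit!r}")
    return contour.with_values(contour.values + cal.offset, unit="dB SPL")


def uncalibrate_spl(contour: Contour, cal: CalibrationInfo) -> Contour:
    """Inverse of :func:`calibrate_spl`."""
    if contour.unit != "dB SPL":
        raise ValueError(f"expected a dB SPL contour, got unit {contour.unit!r}")
    return contour.with_values(contour.values - cal.offset, unit="dB")


def hz_to_semitones(f, f_ref: float):
    """12 * log2(f / f_ref); strictly increasing bijection on (0, inf)."""
    f = np.asarray(f, dtype=np.float64)
    if f_ref <= 0:
        raise ValueError("f_ref must be positive")
    if np.any(f[np.isfinite(f)] <= 0):
        raise ValueError("frequencies must be positive")
    out = 12.0 * np.log2(f / f_ref)
    return float(out) if out.ndim == 0 else out


def semitones_to_hz(st, f_ref: float):
    """Exact inverse of :func:`hz_to_semitones`."""
    st = np.asarray(st, dtype=np.float64)
    if f_ref <= 0:
        raise ValueError("f_ref must be positive")
    out = f_ref * np.exp2(np.asarray(st) / 12.0)
    return float(out) if out.ndim == 0 else out


def frame_targets(
    contour: Contour,
    frame_len: float,
    step: float,
    min_coverage: float = 0.5,
) -> Contour:
    """Per-frame means of a contour on the frame grid ``t = k * step``.

    A frame is undefined when fewer than ``min_coverage`` of its expected
    samples carry a defined value.  Returned times are frame *starts*.
    """
    if frame_len < step:
        raise ValueError("frame_len must be >= step")
    if len(contour) == 0:
        return Contour(np.zeros(0), np.zeros(0), contour.unit, np.zeros(0, bool))
    dt = contour.step if len(contour) > 1 else frame_len
    duration = contour.times[-1] + dt
    n = int(np.floor((duration - frame_len) / step + 1e-9)) + 1
    if n < 1:
        return Contour(np.zeros(0), np.zeros(0), contour.unit, np.zeros(0, bool))
    expected = frame_len / dt
    times = step * np.arange(n)
    values = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for k in range(n):
        t0 = k * step
        sel = (contour.times >= t0 - 1e-9) & (contour.times < t0 + frame_len - 1e-9)
        good = sel & contour.defined
        if good.sum() >= min_coverage * expected and good.any():
            values[k] = float(np.mean(contour.values[good]))
            defined[k] = True
    return Contour(times, values, contour.unit, defined)
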