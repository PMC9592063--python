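"""Synthetic recording sessions: voiced audio plus coupled 8-channel sEMG.

Ground-truth f0 and intensity trajectories are built per task type from
piecewise segments; the audio is an impulse-excited two-pole resonator whose
instantaneous period tracks 1/f0, and each EMG channel is band-limited
Gaussian noise amplitude-modulated by a softplus-linked affine mix of
(f0 deviation in ST, intensity deviation, voicing).  Everything is a pure
function of the config, so identical configs reproduce identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import Contour, SignalTrack

__all__ = [
    "Segment",
    "SynthConfig",
    "SynthSession",
    "TASK_TYPES",
    "default_coupling_gains",
    "make_task_config",
    "glottal_source",
    "emg_from_activation",
    "generate_session",
]

TASK_TYPES = (
    "tone",
    "legato",
    "vcv",
    "phrase",
    "passage",
    "question",
    "monologue",
)

_TRUTH_DT = 0.005  # grid for ground-truth contours (s)
_RESONATOR_HZ = 500.0  # single-formant shaping of the pulse train
_RESONATOR_BW = 250.0
_F0_ABS_RANGE = (20.0, 1000.0)
_F0_TASK_RANGE = (65.0, 475.0)


@dataclass(frozen=True)
class Segment:
    """One piecewise-linear span of the prosody trajectories."""

    duration: float
    voiced: bool
    f0_start: float = np.nan  # Hz, ignored when unvoiced
    f0_end: float = np.nan
    int_start: float = 0.0  # dB relative to the session nominal level
    int_end: float = 0.0


@dataclass
class SynthConfig:
    seed: int
    task_type: str
    segments: list[Segment]
    n_channels: int = 8
    fs_emg: float = 2222.0
    fs_audio: float = 44100.0
    coupling_gains: np.ndarray | None = None  # (n_channels, 4)
    emg_noise_floor: float = 0.05
    audio_snr_db: float = 30.0
    calibration_offset_db: float | None = None  # None: drawn from the seed
    f0_wiggle_st: float = 0.5  # slow random f0 fluctuation, ST sd
    int_wiggle_db: float = 1.5  # slow random intensity fluctuation, dB sd

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task type {self.task_type!r}")
        if self.fs_emg >= self.fs_audio:
            raise ValueError("fs_emg must be below fs_audio")
        if self.n_channels < 1:
            raise ValueError("need at least one EMG channel")
        if self.duration_s <= 0:
            raise ValueError("total duration must be positive")
        for seg in self.segments:
            if seg.voiced and not (
                _F0_TASK_RANGE[0] <= seg.f0_start <= _F0_TASK_RANGE[1]
                and _F0_TASK_RANGE[0] <= seg.f0_end <= _F0_TASK_RANGE[1]
            ):
                raise ValueError("voiced segment f0 outside [65, 475] Hz")
        if self.coupling_gains is None:
            self.coupling_gains = default_coupling_gains(self.n_channels, self.seed)
        self.coupling_gains = np.asarray(self.coupling_gains, dtype=np.float64)
        if self.coupling_gains.shape != (self.n_channels, 4):
            raise ValueError("coupling_gains must have shape (n_channels, 4)")

    @property
    def duration_s(self) -> float:
        return float(sum(seg.duration for seg in self.segments))

    @property
    def voicing_fraction(self) -> float:
        voiced = sum(seg.duration for seg in self.segments if seg.voiced)
        return voiced / self.duration_s


@dataclass
class SynthSession:
    audio: SignalTrack
    emg: list[SignalTrack]
    truth_f0: Contour
    truth_intensity: Contour
    task_label: str
    calibration_offset_db: float
    coupling_gains: np.ndarray


def default_coupling_gains(n_channels: int, seed: int) -> np.ndarray:
    """Per-channel (bias, f0, intensity, voicing) gains.

    The first half of the channels (neck placements) couple mostly to f0,
    the second half (face placements) mostly to intensity; all carry a
    voicing bump.  Gains are drawn once from the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    gains = np.zeros((n_channels, 4))
    half = n_channels // 2
    for c in range(n_channels):
        bias = rng.uniform(-1.2, -0.6)
        if c < half:
            g_f0 = rng.uniform(1.2, 2.0)
            g_int = rng.uniform(0.1, 0.3)
        else:
            g_f0 = rng.uniform(0.05, 0.25)
            g_int = rng.uniform(1.0, 1.6)
        g_v = rng.uniform(0.6, 1.2)
        gains[c] = (bias, g_f0, g_int, g_v)
    return gains


def _smooth_noise(n: int, dt: float, cutoff_hz: float, rng: np.random.Generator):
    """Unit-variance low-pass noise for slow prosodic fluctuation."""
    x = rng.standard_normal(n)
    if n < 32:
        return np.zeros(n)
    sos = sps.butter(2, cutoff_hz, fs=1.0 / dt, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = np.std(y)
    return y / sd if sd > 0 else y


def sample_trajectories(config: SynthConfig) -> tuple[Contour, Contour]:
    """Ground-truth f0 (Hz, undefined when unvoiced) and intensity (dB)."""
    n = int(round(config.duration_s / _TRUTH_DT))
    times = np.arange(n) * _TRUTH_DT
    f0 = np.full(n, np.nan)
    inten = np.zeros(n)
    t0 = 0.0
    for seg in config.segments:
        sel = (times >= t0 - 1e-12) & (times < t0 + seg.duration - 1e-12)
        if np.any(sel):
            frac = (times[sel] - t0) / seg.duration
            inten[sel] = seg.int_start + (seg.int_end - seg.int_start) * frac
            if seg.voiced:
                # geometric interpolation: linear in log-frequency
                f0[sel] = seg.f0_start * (seg.f0_end / seg.f0_start) ** frac
        t0 += seg.duration
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xF1]))
    voiced = np.isfinite(f0)
    if config.f0_wiggle_st > 0:
        wig = config.f0_wiggle_st * _smooth_noise(n, _TRUTH_DT, 2.5, rng)
        f0 = np.where(voiced, f0 * 2.0 ** (wig / 12.0), np.nan)
        f0 = np.clip(f0, _F0_TASK_RANGE[0], _F0_TASK_RANGE[1])
    if config.int_wiggle_db > 0:
        inten = inten + config.int_wiggle_db * _smooth_noise(n, _TRUTH_DT, 2.5, rng)
    inten = np.where(voiced, inten, np.minimum(inten, -25.0))
    truth_f0 = Contour(times, f0, unit="Hz")
    truth_int = Contour(times, inten, unit="dB", defined=np.ones(n, bool))
    return truth_f0, truth_int


def glottal_source(f0_contour: Contour, fs_audio: float, seed: int) -> SignalTrack:
    """Pulse train through a two-pole resonator following the f0 contour.

    Phase is accumulated by integrating f0, so the instantaneous period
    tracks 1/f0 exactly; undefined spans produce silence plus a tiny noise
    floor.
    """
    vals = f0_contour.defined_values()
    if vals.size and (vals.min() < _F0_ABS_RANGE[0] or vals.max() > _F0_ABS_RANGE[1]):
        raise ValueError("f0 outside the admissible [20, 1000] Hz range")
    dur = f0_contour.times[-1] + f0_contour.step if len(f0_contour) else 0.0
    n = int(round(dur * fs_audio))
    t = np.arange(n) / fs_audio
    voiced = (
        np.interp(t, f0_contour.times, f0_contour.defined.astype(float)) > 0.5
        if len(f0_contour)
        else np.zeros(n, bool)
    )
    f0_filled = f0_contour.values.copy()
    if np.any(f0_contour.defined):
        d = f0_contour.defined
        f0_filled[~d] = np.interp(
            f0_contour.times[~d], f0_contour.times[d], f0_contour.values[d]
        )
        f_inst = np.interp(t, f0_contour.times, f0_filled)
    else:
        f_inst = np.zeros(n)
    phase = np.cumsum(f_inst / fs_audio)
    pulses = np.zeros(n)
    ticks = np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1
    pulses[ticks] = 1.0
    pulses[~voiced] = 0.0
    theta = 2.0 * np.pi * _RESONATOR_HZ / fs_audio
    r = np.exp(-np.pi * _RESONATOR_BW / fs_audio)
    wave = sps.lfilter([1.0], [1.0, -2.0 * r * np.cos(theta), r * r], pulses)
    peak = np.max(np.abs(wave)) if n else 0.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0]))
    if peak > 0:
        wave = wave / peak
        wave += 1e-4 * rng.standard_normal(n)
    return SignalTrack(samples=wave, rate=fs_audio)


def _bandpass_sos(fs: float) -> np.ndarray:
    return sps.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")


def emg_from_activation(
    activation: Contour,
    fs_emg: float,
    noise_floor: float,
    seed: int,
) -> SignalTrack:
    """Band-limited noise amplitude-modulated by a nonnegative envelope.

    Short-time RMS is monotone in the activation; ``noise_floor`` adds an
    activation-independent floor as a fraction of the envelope peak.
    """
    if np.any(activation.defined_values() < 0):
        raise ValueError("activation must be nonnegative")
    dur = activation.times[-1] + activation.step if len(activation) else 0.0
    n = int(round(dur * fs_emg))
    t = np.arange(n) / fs_emg
    env = np.interp(t, activation.times, np.nan_to_num(activation.values))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE6]))
    carrier = rng.standard_normal(n)
    floor_noise = rng.standard_normal(n)
    sos = _bandpass_sos(fs_emg)
    carrier = sps.sosfiltfilt(sos, carrier)
    floor_noise = sps.sosfiltfilt(sos, floor_noise)
    # normalize the band-passed carrier to unit variance so RMS ~ envelope
    for arr in (carrier, floor_noise):
        sd = np.std(arr)
        if sd > 0:
            arr /= sd
    out = env * carrier + noise_floor * (env.max() if n else 0.0) * floor_noise
    return SignalTrack(samples=out, rate=fs_emg)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_session(config: SynthConfig) -> SynthSession:
    """Render a full session (audio + EMG + truth contours) from a config."""
    truth_f0, truth_int = sample_trajectories(config)
    seed = int(config.seed)

    # ---- audio: source scaled to the intensity trajectory, plus noise
    source = glottal_source(truth_f0, config.fs_audio, seed)
    n_a = source.n_samples
    t_a = np.arange(n_a) / config.fs_audio
    amp = 10.0 ** (np.interp(t_a, truth_int.times, truth_int.values) / 20.0)
    voiced_a = np.interp(t_a, truth_f0.times, truth_f0.defined.astype(float)) > 0.5
    audio = source.samples * amp * 0.2
    sig_pow = np.mean(audio[voiced_a] ** 2) if voiced_a.any() else np.mean(audio**2)
    noise_pow = sig_pow * 10.0 ** (-config.audio_snr_db / 10.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAD]))
    audio = audio + np.sqrt(noise_pow) * rng.standard_normal(n_a)
    audio_track = SignalTrack(samples=audio, rate=config.fs_audio)

    # ---- per-channel activation envelopes on the truth grid
    # deviations are taken against fixed speaker-level references (150 Hz,
    # 0 dB nominal) so absolute pitch/level remains encoded across sessions;
    # half-octave / 10-dB units keep the three terms commensurate
    d = truth_f0.defined
    f0_st = np.zeros(len(truth_f0))
    if d.any():
        f0_st[d] = 2.0 * np.log2(truth_f0.values[d] / 150.0)
    int_dev = truth_int.values / 10.0
    voicing = d.astype(float)
    emg_tracks: list[SignalTrack] = []
    for c in range(config.n_channels):
        b, gf, gi, gv = config.coupling_gains[c]
        act = _softplus(b + gf * f0_st + gi * int_dev * voicing + gv * voicing)
        act_contour = Contour(
            truth_f0.times, act, unit="au", defined=np.ones(act.size, bool)
        )
        emg_tracks.append(
            emg_from_activation(
                act_contour, config.fs_emg, config.emg_noise_floor, seed * 1009 + c
            )
        )

    if config.calibration_offset_db is not None:
        cal_offset = float(config.calibration_offset_db)
    else:
        cal_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA]))
        cal_offset = float(cal_rng.uniform(5.0, 20.0))
    return SynthSession(
        audio=audio_track,
        emg=emg_tracks,
        truth_f0=truth_f0,
        truth_intensity=truth_int,
        task_label=config.task_type,
        calibration_offset_db=cal_offset,
        coupling_gains=config.coupling_gains.copy(),
    )


# ---------------------------------------------------------------------------
# task-specific trajectory construction


def _rand_f0(rng: np.random.Generator, lo: float = 90.0, hi: float = 320.0) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def make_task_config(
    task_type: str,
    seed: int,
    duration_s: float | None = None,
    **overrides,
) -> SynthConfig:
    """Draw a task-appropriate segment list and wrap it in a config.

    Durations approximate the relative proportions of the acquisition
    protocol (passages longest, legatos shortest).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7A]))
    base_dur = {
        "tone": 4.0,
        "legato": 4.0,
        "vcv": 4.0,
        "phrase": 6.0,
        "passage": 16.0,
        "question": 5.0,
        "monologue": 10.0,
    }
    if task_type not in base_dur:
        raise ValueError(f"unknown task type {task_type!r}")
    total = duration_s if duration_s is not None else base_dur[task_type]
    segs: list[Segment] = []

    def voiced(dur, f0a, f0b, ia, ib):
        segs.append(Segment(dur, True, f0a, f0b, ia, ib))

    def pause(dur):
        segs.append(Segment(dur, False, int_start=-30.0, int_end=-30.0))

    if task_type == "tone":
        f0 = _rand_f0(rng)
        level = rng.uniform(-6, 6)
        pause(0.3)
        voiced(total - 0.6, f0, f0, level, level)
        pause(0.3)
    elif task_type == "legato":
        f0a = _rand_f0(rng, 90, 250)
        f0b = float(np.clip(f0a * 2.0 ** (rng.uniform(-7, 7) / 12.0), 80, 400))
        pause(0.3)
        voiced(total - 0.6, f0a, f0b, rng.uniform(-4, 4), rng.uniform(-4, 4))
        pause(0.3)
    elif task_type == "vcv":
        f0 = _rand_f0(rng)
        stress = rng.integers(0, 2)
        pause(0.25)
        for i in range(2):
            lvl = 5.0 if i == stress else -2.0
            voiced((total - 0.75) / 2, f0, f0 * 1.02, lvl, lvl)
            if i == 0:
                pause(0.25)
        pause(0.25)
    else:  # running-speech-like tasks: alternating voiced spans and pauses
        rising_end = task_type == "question"
        t_used = 0.3
        pause(0.3)
        while t_used < total - 0.8:
            dur_v = float(rng.uniform(0.6, 1.8))
            dur_p = float(rng.uniform(0.15, 0.45))
            f0a = _rand_f0(rng, 95, 280)
            f0b = float(np.clip(f0a * 2.0 ** (rng.uniform(-5, 5) / 12.0), 80, 400))
            lvl_a = rng.uniform(-8, 8)
            lvl_b = rng.uniform(-8, 8)
            voiced(dur_v, f0a, f0b, lvl_a, lvl_b)
            pause(dur_p)
            t_used += dur_v + dur_p
        if rising_end and segs[-2].voiced:
            last = segs[-2]
            segs[-2] = Segment(
                last.duration,
                True,
                last.f0_start,
                float(np.clip(last.f0_start * 2 ** (5 / 12.0), 80, 440)),
                last.int_start,
                last.int_end,
            )
    return SynthConfig(seed=int(seed), task_type=task_type, segments=segs, **overrides)
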