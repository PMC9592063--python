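"""File I/O: WAV audio, delimited contours, columnar EMG with metadata sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signals import Contour, SignalTrack

__all__ = [
    "read_wav",
    "write_wav",
    "read_contour",
    "write_contour",
    "read_emg",
    "write_emg",
]


def write_wav(path: str | Path, track: SignalTrack) -> None:
    """Write a track as float32 PCM WAV."""
    wavfile.write(str(path), int(round(track.rate)), track.samples.astype(np.float32))


def read_wav(path: str | Path) -> SignalTrack:
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    return SignalTrack(samples=np.asarray(data, dtype=np.float64), rate=float(rate))


def write_contour(path: str | Path, contour: Contour) -> None:
    """Three-column TSV (time_s, value, defined_flag) with a unit header line."""
    with open(path, "w") as fh:
        fh.write(f"# unit: {contour.unit}\n")
        fh.write("time_s\tvalue\tdefined\n")
        for t, v, d in zip(contour.times, contour.values, contour.defined):
            sval = f"{v:.10g}" if d else "nan"
            fh.write(f"{t:.9f}\t{sval}\t{int(d)}\n")


def read_contour(path: str | Path) -> Contour:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# unit:"):
            raise ValueError(f"{path}: missing unit header")
        unit = header.split(":", 1)[1].strip()
        df = pd.read_csv(fh, sep="\t")
    return Contour(
        times=df["time_s"].to_numpy(),
        values=df["value"].to_numpy(),
        unit=unit,
        defined=df["defined"].to_numpy().astype(bool),
    )


def write_emg(
    path_csv: str | Path,
    tracks: list[SignalTrack],
    meta: dict | None = None,
) -> None:
    """Write multi-channel EMG as CSV plus a ``.json`` metadata sidecar.

    The sidecar records the sampling rate, channel names and any extra
    metadata (task label, calibration offset, ...).
    """
    path_csv = Path(path_csv)
    rates = {t.rate for t in tracks}
    if len(rates) != 1:
        raise ValueError("all EMG channels must share one sampling rate")
    n = min(t.n_samples for t in tracks)
    names = [f"ch{i + 1}" for i in range(len(tracks))]
    arr = np.column_stack([t.samples[:n] for t in tracks])
    pd.DataFrame(arr, columns=names).to_csv(path_csv, index=False, float_format="%.8g")
    sidecar = {
        "rate_hz": float(tracks[0].rate),
        "channels": names,
        "n_samples": int(n),
    }
    sidecar.update(meta or {})
    with open(path_csv.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_emg(path_csv: str | Path) -> tuple[list[SignalTrack], dict]:
    path_csv = Path(path_csv)
    with open(path_csv.with_suffix(".json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path_csv)
    rate = float(meta["rate_hz"])
    tracks = [
        SignalTrack(samples=df[c].to_numpy(), rate=rate, units="au")
        for c in meta["channels"]
    ]
    return tracks, meta
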