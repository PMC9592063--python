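"""Core carrier types: uniformly sampled signal tracks and scalar contours.

A :class:`SignalTrack` holds one channel of uniformly sampled data (audio or
one sEMG electrode pair).  A :class:`Contour` holds a regularly spaced scalar
time series (f0 or intensity) in which individual samples may be *undefined*
(e.g. f0 during unvoiced spans), tracked through an explicit mask rather than
NaN arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalTrack", "Contour"]


@dataclass
class SignalTrack:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Sample values, float.
    rate : float
        Sampling rate in Hz, > 0.
    units : str
        Free-form unit tag ("au", "mV", ...).
    """

    samples: np.ndarray
    rate: float
    units: str = "au"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("SignalTrack requires a 1-D sample array")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"invalid sampling rate {self.rate!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Track duration in seconds (n / rate)."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class Contour:
    """Regularly spaced scalar time series with an undefined-sample mask.

    ``times`` must be strictly increasing with a constant step.  ``defined``
    marks samples carrying a value; where it is False the stored value is
    ignored (and normalised to NaN for safety).
    """

    times: np.ndarray
    values: np.ndarray
    unit: str
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times/values must be matching 1-D arrays")
        if self.defined is None:
            self.defined = np.isfinite(self.values)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.defined.shape != self.values.shape:
            raise ValueError("defined mask shape mismatch")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("times must have a constant step")
        vals = self.values.copy()
        vals[~self.defined] = np.nan
        self.values = vals

    @property
    def step(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]

    def defined_times(self) -> np.ndarray:
        return self.times[self.defined]

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Contour":
        """Copy of this contour carrying new values on the same grid/mask."""
        return Contour(
            times=self.times.copy(),
            values=np.asarray(values, dtype=np.float64),
            unit=self.unit if unit is None else unit,
            defined=self.defined.copy(),
        )

    def __len__(self) -> int:
        return self.times.size
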