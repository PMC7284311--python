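"""Regularly sampled time series container used throughout the package.

All behavioral and inertial signals (eye position at camera rate, IMU
channels, piezo sensor voltage) are represented as :class:`UniformTrace`
objects: a start time, a sampling rate, and a value array whose first axis
is time.  Missing samples (dropped camera frames, low-confidence pupil
fits, out-of-span resampling targets) are flagged as NaN and are excluded
from statistics rather than interpolated across.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UniformTrace"]


@dataclass
class UniformTrace:
    """A regularly sampled scalar or vector time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample, in seconds.
    rate : float
        Sampling rate in Hz; must be positive.
    values : ndarray
        Sample values, shape ``(n,)`` for a scalar channel or ``(n, k)``
        for a k-channel trace.  NaN marks a missing sample.
    """

    t0: float
    rate: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D (scalar) or 2-D (vector)")

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Time spanned from the first to the last sample, in seconds."""
        return max(self.n - 1, 0) * self.dt

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(self.n) / self.rate

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of samples with no missing (NaN) component."""
        if self.values.ndim == 1:
            return np.isfinite(self.values)
        return np.all(np.isfinite(self.values), axis=1)

    def channel(self, i: int) -> "UniformTrace":
        """Extract one channel of a vector trace as a scalar trace."""
        if self.values.ndim != 2:
            raise ValueError("channel() requires a vector trace")
        return UniformTrace(self.t0, self.rate, self.values[:, i].copy())

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t``."""
        return int(round((t - self.t0) * self.rate))

    def copy_with(self, values: np.ndarray) -> "UniformTrace":
        """A new trace on the same time base with different values."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.n:
            raise ValueError("replacement values must preserve sample count")
        return UniformTrace(self.t0, self.rate, values)
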