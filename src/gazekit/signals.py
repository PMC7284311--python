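"""Preprocessing primitives for eye, IMU and sensor traces.

Camera-rate eye positions are smoothed with the fixed 3-point Gaussian
kernel (0.072, 0.855, 0.072) before differentiation; IMU channels are
resampled onto the camera time base by linear interpolation; head tilt is
recovered from the accelerometer's gravity direction; yaw position is the
drift-corrected integral of the gyroscope yaw rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate as _integrate
from scipy import signal as _signal

from .trace import UniformTrace

__all__ = [
    "ImuRecord",
    "EYE_SMOOTHING_KERNEL",
    "IMU_DELAY_S",
    "smooth_eye_trace",
    "velocity",
    "resample_linear",
    "pitch_roll_from_accel",
    "estimate_gyro_drift",
    "integrate_yaw",
    "zero_phase_butterworth",
    "autocorrelation",
]

#: Fixed 3-point Gaussian smoothing kernel applied to raw eye positions.
EYE_SMOOTHING_KERNEL = np.array([0.072, 0.855, 0.072])

#: Constant IMU sensor latency subtracted from IMU timestamps before
#: alignment with the eye cameras.
IMU_DELAY_S = 0.005


@dataclass
class ImuRecord:
    """Head-mounted IMU recording: 3-axis accelerometer (units of g) and
    3-axis gyroscope (deg/s), both at ``rate`` Hz (default 190)."""

    accel: UniformTrace  # (n, 3) in g, head frame: X forward, Y left, Z up
    gyro: UniformTrace  # (n, 3) in deg/s about the same axes

    def __post_init__(self) -> None:
        if self.accel.rate != self.gyro.rate:
            raise ValueError("accelerometer and gyroscope rates must match")
        if self.accel.values.shape != self.gyro.values.shape:
            raise ValueError("accelerometer and gyroscope shapes must match")

    @property
    def rate(self) -> float:
        return self.accel.rate

    def yaw_rate(self) -> UniformTrace:
        """Gyroscope channel about the dorsal (yaw) axis."""
        return self.gyro.channel(2)


def smooth_eye_trace(x: UniformTrace, mode: str = "replicate") -> UniformTrace:
    """Convolve with the fixed 3-point Gaussian kernel.

    ``mode='replicate'`` (default) pads by repeating the edge samples;
    ``mode='valid'`` flags the two edge samples missing instead.  NaN
    samples contaminate their neighbors, as with any convolution.
    """
    if x.n < 3:
        raise ValueError("smoothing requires at least 3 samples")
    v = x.values
    if v.ndim != 1:
        raise ValueError("smooth_eye_trace expects a scalar trace")
    if mode == "replicate":
        padded = np.pad(v, 1, mode="edge")
        out = np.convolve(padded, EYE_SMOOTHING_KERNEL, mode="valid")
    elif mode == "valid":
        out = np.full_like(v, np.nan)
        out[1:-1] = np.convolve(v, EYE_SMOOTHING_KERNEL, mode="valid")
    else:
        raise ValueError(f"unknown edge mode {mode!r}")
    return x.copy_with(out)


def velocity(x: UniformTrace) -> UniformTrace:
    """Time derivative in units of the input per second.

    Central differences in the interior, one-sided at the ends.
    """
    if x.n < 2:
        raise ValueError("velocity requires at least 2 samples")
    return x.copy_with(np.gradient(x.values, x.dt, axis=0))


def resample_linear(
    source_times: np.ndarray,
    source_values: np.ndarray,
    target_times: np.ndarray,
    max_gap_s: float = 0.1,
) -> np.ndarray:
    """Linear interpolation of a (possibly irregular) series onto new times.

    Targets outside the source span, or falling inside a gap between
    consecutive valid source samples longer than ``max_gap_s``, come back
    NaN rather than being bridged.
    """
    t = np.asarray(source_times, dtype=float)
    v = np.asarray(source_values, dtype=float)
    tt = np.asarray(target_times, dtype=float)
    if t.ndim != 1 or t.size != v.shape[0]:
        raise ValueError("source_times must be 1-D and match source_values")
    if np.any(np.diff(t) <= 0):
        raise ValueError("source timestamps must be strictly increasing")
    single = v.ndim == 1
    vv = v[:, None] if single else v
    out = np.full((tt.size, vv.shape[1]), np.nan)
    for k in range(vv.shape[1]):
        ok = np.isfinite(vv[:, k])
        if ok.sum() < 2:
            continue
        ts, vs = t[ok], vv[ok, k]
        inside = (tt >= ts[0]) & (tt <= ts[-1])
        idx = np.searchsorted(ts, tt[inside], side="right") - 1
        idx = np.clip(idx, 0, ts.size - 2)
        gap = ts[idx + 1] - ts[idx]
        col = np.interp(tt[inside], ts, vs)
        col[gap > max_gap_s] = np.nan
        out[inside, k] = col
    return out[:, 0] if single else out


def resample_trace(
    x: UniformTrace, target: UniformTrace, max_gap_s: float = 0.1
) -> UniformTrace:
    """Resample ``x`` onto the time base of ``target``."""
    vals = resample_linear(x.times(), x.values, target.times(), max_gap_s)
    return UniformTrace(target.t0, target.rate, vals)


def pitch_roll_from_accel(
    imu: ImuRecord, lowpass_hz: float | None = None
) -> UniformTrace:
    """Head pitch and roll (degrees) from the accelerometer's gravity
    direction.

    At rest the accelerometer reads the upward unit vector expressed in
    the head frame; pitch is recovered as atan2 of the forward against
    the dorsal component and roll as the arcsine of the leftward
    component, matching the roll-after-pitch Euler convention of the
    gaze model.  Samples whose acceleration norm falls outside
    [0.3, 3] g (free fall, impacts) are flagged missing.
    """
    a = imu.accel.values.copy()
    if lowpass_hz is not None:
        nyq = imu.rate / 2
        if not 0 < lowpass_hz < nyq:
            raise ValueError("lowpass cutoff must be within (0, Nyquist)")
        sos = _signal.butter(2, lowpass_hz, btype="low", fs=imu.rate, output="sos")
        a = _signal.sosfiltfilt(sos, a, axis=0)
    nrm = np.linalg.norm(a, axis=1)
    bad = ~np.isfinite(nrm) | (nrm < 0.3) | (nrm > 3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = a / nrm[:, None]
        pitch = np.rad2deg(np.arctan2(u[:, 0], u[:, 2]))
        roll = np.rad2deg(np.arcsin(np.clip(u[:, 1], -1.0, 1.0)))
    out = np.column_stack([pitch, roll])
    out[bad] = np.nan
    return UniformTrace(imu.accel.t0, imu.rate, out)


def estimate_gyro_drift(yaw_rate: UniformTrace, segment: tuple[float, float]) -> float:
    """Constant gyroscope bias (deg/s) from a stationary calibration
    segment.

    ``segment`` gives (start, end) times in seconds and must cover at
    least 10 s.  The segment is required explicitly: averaging over a
    whole session would absorb any net head rotation into the bias.
    """
    t = yaw_rate.times()
    v = yaw_rate.values
    lo, hi = segment
    m = (t >= lo) & (t <= hi) & np.isfinite(v)
    if m.sum() < 10 * yaw_rate.rate:
        raise ValueError("drift estimation requires >= 10 s of stationary data")
    return float(np.mean(v[m]))


def integrate_yaw(yaw_rate: UniformTrace, drift: float = 0.0) -> UniformTrace:
    """Angular yaw position (degrees) as the trapezoidal integral of the
    drift-corrected yaw rate, starting at 0."""
    if not np.isfinite(drift):
        raise ValueError("drift must be finite")
    v = yaw_rate.values - drift
    pos = _integrate.cumulative_trapezoid(v, dx=yaw_rate.dt, initial=0.0)
    return yaw_rate.copy_with(pos)


def zero_phase_butterworth(
    x: UniformTrace,
    kind: str,
    cutoff_hz: float | tuple[float, float],
    order: int = 2,
) -> UniformTrace:
    """Forward-backward (zero phase lag) Butterworth filter.

    ``kind`` is ``'highpass'`` with a scalar cutoff or ``'bandpass'``
    with a (low, high) pair; cutoffs must lie strictly inside
    (0, Nyquist).
    """
    nyq = x.rate / 2.0
    if kind == "highpass":
        if not np.isscalar(cutoff_hz):
            raise ValueError("highpass takes a scalar cutoff")
        if not 0 < cutoff_hz < nyq:
            raise ValueError("cutoff must be within (0, Nyquist)")
        wn: float | list[float] = cutoff_hz
    elif kind == "bandpass":
        lo, hi = cutoff_hz  # type: ignore[misc]
        if not (0 < lo < hi < nyq):
            raise ValueError("bandpass cutoffs must satisfy 0 < lo < hi < Nyquist")
        wn = [lo, hi]
    else:
        raise ValueError(f"kind must be 'highpass' or 'bandpass', got {kind!r}")
    sos = _signal.butter(order, wn, btype=kind, fs=x.rate, output="sos")
    return x.copy_with(_signal.sosfiltfilt(sos, x.values, axis=0))


def autocorrelation(x: UniformTrace, max_lag_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation for lags in [-max_lag_s, +max_lag_s].

    Returns (lags_s, values) with the zero-lag value equal to 1.  The
    estimate is the biased sample autocovariance divided by the variance,
    symmetric in lag by construction.
    """
    v = x.values
    if v.ndim != 1:
        raise ValueError("autocorrelation expects a scalar trace")
    v = v[np.isfinite(v)]
    n = v.size
    max_lag = int(round(max_lag_s * x.rate))
    if max_lag >= n:
        raise ValueError("max_lag must be shorter than the record")
    v = v - v.mean()
    var = np.dot(v, v)
    if var <= 0:
        raise ValueError("autocorrelation undefined for zero-variance input")
    full = _signal.correlate(v, v, mode="full", method="fft") / var
    mid = n - 1
    vals = full[mid - max_lag : mid + max_lag + 1]
    lags = np.arange(-max_lag, max_lag + 1) / x.rate
    return lags, vals
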