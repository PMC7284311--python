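"""End-to-end session analyses built from the module primitives.

These helpers wire the preprocessing, saccade and model layers together
the way a full recording is analyzed: smooth and differentiate the eye
traces, derive CW-positive head yaw velocity from the gyroscope (with the
drift estimated on a stationary calibration segment), detect and pair
saccades, and compute stabilization and tilt-regression summaries on the
inter-saccade samples of the analysis window.
"""

from __future__ import annotations

import numpy as np

from . import saccades as _sac
from . import signals as _sig
from . import stabilization as _stab
from . import tiltmodel as _tilt
from .signals import ImuRecord
from .trace import UniformTrace

__all__ = [
    "head_yaw_velocity_cw",
    "detect_and_pair",
    "stabilization_analysis",
    "tilt_regression_analysis",
]


def head_yaw_velocity_cw(imu: ImuRecord, drift_dps: float) -> UniformTrace:
    """Drift-corrected head yaw velocity in the CW-positive convention.

    The gyroscope dorsal-axis channel is right-handed (CCW positive);
    negating the drift-corrected channel yields the clockwise-positive
    yaw velocity used alongside the eye traces.
    """
    z = imu.yaw_rate()
    return z.copy_with(-(z.values - drift_dps))


def detect_and_pair(
    eyes: dict[str, UniformTrace],
    threshold: float = _sac.SACCADE_SPEED_THRESHOLD,
) -> tuple[dict[str, list[_sac.SaccadeEvent]], list[_sac.BinocularSaccade]]:
    """Smooth, differentiate, detect, size and binocularly pair saccades.

    ``eyes`` maps 'left_h', 'left_v', 'right_h', 'right_v' to camera-rate
    position traces.  Events are sized on the smoothed traces.  Returns
    per-eye event lists and the paired binocular saccades.
    """
    events: dict[str, list[_sac.SaccadeEvent]] = {}
    for eye in ("left", "right"):
        h = _sig.smooth_eye_trace(eyes[f"{eye}_h"])
        v = _sig.smooth_eye_trace(eyes[f"{eye}_v"])
        vh = _sig.velocity(h)
        vv = _sig.velocity(v)
        evs = _sac.detect_saccades(vh, vv, threshold=threshold, eye=eye)
        for ev in evs:
            _sac.saccade_size(h, ev, v=v)
        events[eye] = evs
    pairs = _sac.pair_binocular(events["left"], events["right"], frame_rate=eyes["left_h"].rate)
    return events, pairs


def _fixation_sample_mask(
    t: np.ndarray, segments: list[tuple[float, float]]
) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for s, e in segments:
        mask |= (t >= s) & (t <= e)
    return mask


def stabilization_analysis(
    eyes: dict[str, UniformTrace],
    imu: ImuRecord,
    calibration_segment: tuple[float, float],
    analysis_start_s: float = 0.0,
    threshold: float = _sac.SACCADE_SPEED_THRESHOLD,
) -> dict:
    """Fixation-phase gaze stabilization summary of one session.

    Estimates the gyro drift on the stationary calibration segment,
    detects and pairs saccades, removes their windows, and fits eye
    velocity (binocular mean of the horizontal components) against the
    drift-corrected CW-positive head yaw velocity resampled onto the
    camera time base.  Returns the gain, the MAD, the drift and the
    paired events.
    """
    events, pairs = detect_and_pair(eyes, threshold=threshold)
    drift = _sig.estimate_gyro_drift(imu.yaw_rate(), calibration_segment)
    yaw_cw = head_yaw_velocity_cw(imu, drift)
    base = eyes["left_h"]
    head_vel = _sig.resample_linear(yaw_cw.times(), yaw_cw.values, base.times())
    eye_vels = []
    for eye in ("left", "right"):
        h = _sig.smooth_eye_trace(eyes[f"{eye}_h"])
        eye_vels.append(_sig.velocity(h).values)
    eye_vel = 0.5 * (eye_vels[0] + eye_vels[1])
    t = base.times()
    span = (max(analysis_start_s, t[0]), t[-1])
    # pad each saccade window by the support of the velocity estimate
    # (one frame of central differencing plus one of the smoothing kernel)
    segments = _stab.fixation_segments(pairs, span, pad_s=2.0 / base.rate)
    mask = _fixation_sample_mask(t, segments) & np.isfinite(head_vel) & np.isfinite(eye_vel)
    summary = _stab.stabilization_summary(eye_vel[mask], head_vel[mask])
    return {
        "gain": summary.gain,
        "mad": summary.mad,
        "n_samples": summary.n_samples,
        "drift_dps": drift,
        "events": events,
        "pairs": pairs,
        "segments": segments,
    }


def tilt_regression_analysis(
    eyes: dict[str, UniformTrace],
    imu: ImuRecord,
    axis: str = "v",
    folds: int = 5,
    seed: int = 0,
    analysis_start_s: float = 0.0,
    regressor_factory=None,
) -> dict[str, _tilt.TiltFitResult]:
    """Cross-validated tilt-to-eye-position regression for both eyes.

    Head pitch and roll are recovered from the accelerometer, lag
    features built at the eye sample times within the analysis window,
    and one independent model fit per eye on the requested axis ('h' or
    'v').  Returns a mapping eye -> fit result.
    """
    if axis not in ("h", "v"):
        raise ValueError("axis must be 'h' or 'v'")
    tilt = _sig.pitch_roll_from_accel(imu)
    pitch = tilt.channel(0)
    roll = tilt.channel(1)
    out = {}
    for eye in ("left", "right"):
        trace = eyes[f"{eye}_{axis}"]
        t = trace.times()
        keep = t >= analysis_start_s
        feats = _tilt.build_lag_features(pitch, roll, t[keep])
        y = trace.values[keep][feats.row_index]
        out[eye] = _tilt.fit_cv_predict(
            feats, y, folds=folds, seed=seed, regressor_factory=regressor_factory
        )
    return out
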