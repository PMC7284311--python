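"""Attempted head rotation analysis for head-restrained recordings.

A piezo sensor coupled to the head post reports attempted yaw rotations
(compression = CW, tension = CCW) while the head cannot actually move.
The signal is band-pass filtered at 1-50 Hz (zero phase), normalized by
the noise SD measured without an animal attached, and sampled at 9
equally spaced lags within +/-50 ms of each saccade peak.  Saccade
direction is decoded from these windows with a linear support vector
machine; saccade size is regressed with automatic-relevance-determination
Bayesian linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ARDRegression
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .saccades import SaccadeEvent
from .signals import zero_phase_butterworth
from .stabilization import roc_auc
from .trace import UniformTrace

__all__ = [
    "SENSOR_WINDOW_LAGS_S",
    "SensorWindow",
    "NoiseModel",
    "preprocess_sensor",
    "estimate_noise",
    "extract_windows",
    "saccade_sensor_magnitude",
    "classify_direction_cv",
    "ard_size_regression",
]

#: 9 equally spaced lags spanning -50 ms to +50 ms around the saccade peak.
SENSOR_WINDOW_LAGS_S = np.linspace(-0.05, 0.05, 9)


@dataclass
class SensorWindow:
    """Sensor samples around one saccade, plus event metadata."""

    values: np.ndarray  # 9 sensor values at the standard lags
    direction: str  # 'CW' or 'CCW'
    size: float | None  # signed saccade size, deg (None if unsized)
    mouse_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (9,):
            raise ValueError("a sensor window holds exactly 9 lag values")


@dataclass
class NoiseModel:
    """Sensor noise level from a recording without an animal attached."""

    noise_sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise ValueError("noise_sd must be positive")


def preprocess_sensor(x: UniformTrace) -> UniformTrace:
    """Zero-phase 2nd-order Butterworth band-pass, 1-50 Hz."""
    if x.rate <= 100:
        raise ValueError("sensor rate must exceed 100 Hz for the 1-50 Hz band")
    return zero_phase_butterworth(x, "bandpass", (1.0, 50.0), order=2)


def estimate_noise(no_animal: UniformTrace) -> NoiseModel:
    """Noise SD of the band-passed sensor signal with no animal attached."""
    filtered = preprocess_sensor(no_animal)
    v = filtered.values[np.isfinite(filtered.values)]
    return NoiseModel(noise_sd=float(np.std(v)))


def extract_windows(
    sensor: UniformTrace, events: list[SaccadeEvent], mouse_id: str = ""
) -> list[SensorWindow]:
    """Sample the (already filtered) sensor at the 9 standard lags around
    each saccade peak; events without the full window are skipped."""
    t = sensor.times()
    out = []
    for ev in events:
        q = ev.peak_time + SENSOR_WINDOW_LAGS_S
        if q[0] < t[0] or q[-1] > t[-1]:
            continue
        vals = np.interp(q, t, sensor.values)
        out.append(
            SensorWindow(values=vals, direction=ev.direction, size=ev.size_h, mouse_id=mouse_id)
        )
    return out


def saccade_sensor_magnitude(
    sensor: UniformTrace, events: list[SaccadeEvent], noise: NoiseModel
) -> tuple[np.ndarray, float]:
    """Per-saccade sensor magnitude in noise-SD units.

    The magnitude is the maximum absolute sensor value within +/-50 ms of
    the peak, divided by the noise SD.  Returns the per-event magnitudes
    and the fraction exceeding 3 SD.
    """
    if noise.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    t = sensor.times()
    half = 0.05
    mags = []
    for ev in events:
        m = (t >= ev.peak_time - half) & (t <= ev.peak_time + half)
        if not np.any(m):
            continue
        mags.append(np.nanmax(np.abs(sensor.values[m])) / noise.noise_sd)
    mags_arr = np.asarray(mags)
    if mags_arr.size == 0:
        raise ValueError("no events within the sensor record")
    return mags_arr, float(np.mean(mags_arr >= 3.0))


def _design(windows: list[SensorWindow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([w.values for w in windows])
    y = np.array([1 if w.direction == "CW" else 0 for w in windows])
    mice = np.array([w.mouse_id for w in windows])
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("degenerate design: a lag feature has zero variance")
    return X, y, mice


def _svm_auc(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, y_te: np.ndarray, split: str
) -> np.ndarray:
    if len(np.unique(y_tr)) < 2:
        raise ValueError(f"training split {split!r} contains a single class")
    scaler = StandardScaler().fit(X_tr)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(scaler.transform(X_tr), y_tr)
    return clf.decision_function(scaler.transform(X_te))


def classify_direction_cv(
    windows: list[SensorWindow],
    scheme: str = "per_mouse",
    folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Saccade-direction decoding AUC from sensor windows.

    ``scheme='per_mouse'``: within each mouse, stratified ``folds``-fold
    cross-validation; the AUC is computed on the pooled held-out SVM
    decision values.  ``scheme='leave_one_mouse_out'``: for each mouse,
    train on all other mice and report the AUC on the held-out mouse.
    Returns a mapping from mouse id to AUC.
    """
    X, y, mice = _design(windows)
    uniq = sorted(str(m) for m in set(mice))
    out: dict[str, float] = {}
    if scheme == "per_mouse":
        for m in uniq:
            sel = mice == m
            Xm, ym = X[sel], y[sel]
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            dec = np.empty(ym.size)
            for k, (tr, te) in enumerate(cv.split(Xm, ym)):
                dec[te] = _svm_auc(Xm[tr], ym[tr], Xm[te], ym[te], f"{m}/fold{k}")
            out[m] = float(roc_auc(dec, ym))
    elif scheme == "leave_one_mouse_out":
        if len(uniq) < 2:
            raise ValueError("leave_one_mouse_out requires at least 2 mice")
        for m in uniq:
            te = mice == m
            dec = _svm_auc(X[~te], y[~te], X[te], y[te], f"holdout={m}")
            out[m] = float(roc_auc(dec, y[te]))
    else:
        raise ValueError("scheme must be 'per_mouse' or 'leave_one_mouse_out'")
    return out


def ard_size_regression(
    windows: list[SensorWindow],
    scheme: str = "per_mouse",
    folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Cross-validated R^2 of saccade size (signed, deg) predicted from
    sensor windows with ARD Bayesian linear regression.

    The linear weights and offset carry per-weight relevance
    (hierarchical shrinkage) priors with broad gamma hyperpriors.
    Schemes mirror :func:`classify_direction_cv`.  Returns a mapping from
    mouse id to held-out R^2.
    """
    usable = [w for w in windows if w.size is not None]
    if len(usable) < 30:
        raise ValueError("need at least 30 sized windows")
    X, _, mice = _design(usable)
    sizes = np.array([w.size for w in usable], dtype=float)
    if np.std(sizes) == 0:
        raise ValueError("R^2 undefined: all saccade sizes are equal")

    def fit_predict(tr: np.ndarray, te: np.ndarray) -> np.ndarray:
        scaler = StandardScaler().fit(X[tr])
        model = ARDRegression()
        model.fit(scaler.transform(X[tr]), sizes[tr])
        return model.predict(scaler.transform(X[te]))

    uniq = sorted(str(m) for m in set(mice))
    out: dict[str, float] = {}
    if scheme == "per_mouse":
        for m in uniq:
            sel = np.nonzero(mice == m)[0]
            cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
            pred = np.empty(sel.size)
            for tr, te in cv.split(sel):
                pred[te] = fit_predict(sel[tr], sel[te])
            ym = sizes[sel]
            out[m] = float(1.0 - np.sum((ym - pred) ** 2) / np.sum((ym - ym.mean()) ** 2))
    elif scheme == "leave_one_mouse_out":
        if len(uniq) < 2:
            raise ValueError("leave_one_mouse_out requires at least 2 mice")
        for m in uniq:
            te = np.nonzero(mice == m)[0]
            tr = np.nonzero(mice != m)[0]
            pred = fit_predict(tr, te)
            ym = sizes[te]
            out[m] = float(1.0 - np.sum((ym - pred) ** 2) / np.sum((ym - ym.mean()) ** 2))
    else:
        raise ValueError("scheme must be 'per_mouse' or 'leave_one_mouse_out'")
    return out
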