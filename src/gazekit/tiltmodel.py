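"""Prediction of eye position from lagged head tilt.

The otolith-driven component of eye position is modeled as a smooth
nonlinear function of the recent history of head pitch and roll: for each
eye sample, pitch and roll are linearly interpolated at lags
-100, -75, -50, -25 and 0 ms, giving a 10-dimensional feature vector.
The reference regressor is a multilayer perceptron with one hidden layer
of 100 rectified-linear units trained with a stochastic gradient solver
with adaptive momentum estimation; performance is the held-out
coefficient of determination R^2 = 1 - rss/tss under 5-fold
cross-validation with contiguous temporal folds (a sequential split of
the recording, which avoids leakage through the autocorrelated signals).

The observed eye trace decomposes exactly into the cross-validated
prediction (the tilt-driven component) plus the residual; interocular
correlations of the two parts separate convergent tilt-compensating
movements (negative horizontal correlation) from conjugate
saccade-and-fixate movements (positive residual correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .trace import UniformTrace

__all__ = [
    "TILT_LAGS_MS",
    "TiltFeatureMatrix",
    "TiltFitResult",
    "build_lag_features",
    "fit_cv_predict",
    "interocular_correlation",
    "decompose_components",
]

#: Time lags (ms) at which pitch and roll are sampled for each eye sample.
TILT_LAGS_MS = (-100.0, -75.0, -50.0, -25.0, 0.0)


@dataclass
class TiltFeatureMatrix:
    """Lagged pitch/roll design matrix aligned to eye sample times.

    ``X`` has one row per retained eye sample and 10 columns: pitch at
    the five lags followed by roll at the five lags.  ``row_times`` are
    the retained eye timestamps; ``row_index`` maps rows back into the
    original eye sample array (rows with any missing lag were dropped).
    """

    X: np.ndarray
    row_times: np.ndarray
    row_index: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class TiltFitResult:
    """Cross-validated tilt-to-eye regression result for one eye axis."""

    y: np.ndarray  # observed eye position on retained rows
    prediction: np.ndarray  # held-out prediction per row
    residual: np.ndarray  # y - prediction, exactly
    fold_id: np.ndarray  # fold assignment per row
    r2: float  # 1 - rss/tss on concatenated held-out predictions
    rss: float
    tss: float
    row_times: np.ndarray


def build_lag_features(
    pitch: UniformTrace, roll: UniformTrace, eye_times: np.ndarray
) -> TiltFeatureMatrix:
    """Interpolate pitch and roll at the standard lags for each eye time.

    Eye samples whose full 100 ms feature window does not lie inside the
    valid span of both tilt traces are dropped (and recorded via
    ``row_index``).
    """
    eye_times = np.asarray(eye_times, dtype=float)
    cols = []
    valid = np.ones(eye_times.size, dtype=bool)
    for trace in (pitch, roll):
        t = trace.times()
        v = trace.values
        ok = np.isfinite(v)
        if ok.sum() < 2:
            raise ValueError("tilt trace has too few valid samples")
        ts, vs = t[ok], v[ok]
        for lag_ms in TILT_LAGS_MS:
            q = eye_times + lag_ms / 1000.0
            inside = (q >= ts[0]) & (q <= ts[-1])
            col = np.full(eye_times.size, np.nan)
            col[inside] = np.interp(q[inside], ts, vs)
            valid &= inside
            cols.append(col)
    if not np.any(valid):
        raise ValueError("no eye samples overlap the tilt record")
    X = np.column_stack(cols)[valid]
    idx = np.nonzero(valid)[0]
    return TiltFeatureMatrix(X=X, row_times=eye_times[valid], row_index=idx)


def _contiguous_folds(n: int, folds: int) -> np.ndarray:
    edges = np.linspace(0, n, folds + 1).astype(int)
    fid = np.empty(n, dtype=int)
    for k in range(folds):
        fid[edges[k] : edges[k + 1]] = k
    return fid


def default_regressor(seed: int, max_iter: int = 300) -> MLPRegressor:
    """The reference architecture: one hidden layer of 100 ReLU units,
    adam solver, early stopping on a held-out 10% of the training data."""
    return MLPRegressor(
        hidden_layer_sizes=(100,),
        activation="relu",
        solver="adam",
        max_iter=max_iter,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=10,
        random_state=seed,
    )


def fit_cv_predict(
    features: TiltFeatureMatrix,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    regressor_factory=None,
    fold_mode: str = "contiguous",
    guard_s: float = 0.1,
) -> TiltFitResult:
    """Cross-validated prediction of one eye axis from tilt features.

    Folds are contiguous temporal blocks by default (``fold_mode=
    'interleaved'`` assigns rows round-robin instead).  Each fold is
    predicted by a model trained on the remaining rows, with feature
    standardization fit on the training rows only; for contiguous folds,
    training rows within ``guard_s`` of the test block are dropped so no
    training sample overlaps a test sample's feature window.  R^2 is
    computed once on the concatenated held-out predictions.
    """
    X = features.X
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("y must have one value per feature row")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite on retained rows")
    if X.shape[0] < 10 * X.shape[1]:
        raise ValueError("need at least 10x more rows than features")
    if fold_mode == "contiguous":
        fid = _contiguous_folds(X.shape[0], folds)
    elif fold_mode == "interleaved":
        fid = np.arange(X.shape[0]) % folds
    else:
        raise ValueError("fold_mode must be 'contiguous' or 'interleaved'")
    if regressor_factory is None:
        regressor_factory = default_regressor
    pred = np.empty_like(y)
    t = features.row_times
    for k in range(folds):
        test = fid == k
        train = ~test
        if fold_mode == "contiguous" and guard_s > 0:
            lo, hi = t[test].min(), t[test].max()
            train &= (t < lo - guard_s) | (t > hi + guard_s)
        scaler = StandardScaler().fit(X[train])
        model = regressor_factory(seed)
        model.fit(scaler.transform(X[train]), y[train])
        pred[test] = model.predict(scaler.transform(X[test]))
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return TiltFitResult(
        y=y,
        prediction=pred,
        residual=y - pred,
        fold_id=fid,
        r2=1.0 - rss / tss,
        rss=rss,
        tss=tss,
        row_times=features.row_times,
    )


def interocular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between sample-aligned series of the two eyes,
    over jointly valid samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be sample-aligned")
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        raise ValueError("need at least 3 paired valid samples")
    if np.std(a[m]) == 0 or np.std(b[m]) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(_stats.pearsonr(a[m], b[m])[0])


def decompose_components(
    fits_left: dict[str, TiltFitResult], fits_right: dict[str, TiltFitResult]
) -> dict[str, dict[str, float]]:
    """Interocular correlations of the tilt-predicted and residual
    components, per axis.

    ``fits_left`` and ``fits_right`` map axis names (e.g. 'h', 'v') to
    per-eye fits sharing row timestamps.  Verifies the exact
    decomposition observed = prediction + residual before correlating.
    """
    axes = sorted(fits_left)
    if sorted(fits_right) != axes:
        raise ValueError("eyes must provide fits for the same axes")
    out: dict[str, dict[str, float]] = {"prediction_r": {}, "residual_r": {}}
    for ax in axes:
        fl, fr = fits_left[ax], fits_right[ax]
        if fl.row_times.shape != fr.row_times.shape or not np.allclose(
            fl.row_times, fr.row_times
        ):
            raise ValueError(f"axis {ax!r}: fits do not share timestamps")
        for f in (fl, fr):
            if not np.array_equal(f.residual, f.y - f.prediction):
                raise AssertionError("prediction + residual must equal observed")
        out["prediction_r"][ax] = interocular_correlation(fl.prediction, fr.prediction)
        out["residual_r"][ax] = interocular_correlation(fl.residual, fr.residual)
    return out
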