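"""Quantification of gaze stabilization between gaze shifts.

During fixation phases (inter-saccade intervals) the angular
vestibulo-ocular reflex counter-rotates the eyes against head yaw.  Two
measures quantify how complete that compensation is, both computed on
angular velocities rather than positions:

* MAD, the mean absolute deviation ``mean |eye_vel + head_vel|`` from the
  complete-compensation line of slope -1;
* gain, the negative slope of the ordinary least-squares fit of eye
  velocity on head velocity over the raw (unbinned) samples; 1 means
  full compensation.

Also provided: binocular velocity-difference statistics split by head
rotation direction, gaze-shift rate, a recording-level label permutation
test on event-aligned traces, and a rank-based ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .saccades import BinocularSaccade

__all__ = [
    "StabilizationResult",
    "VelDiffStats",
    "fixation_segments",
    "mad_from_full_compensation",
    "stabilization_gain",
    "stabilization_summary",
    "velocity_difference_stats",
    "gaze_shift_rate",
    "permutation_test_L1",
    "roc_auc",
]


@dataclass
class StabilizationResult:
    """Fixation-phase compensation summary."""

    mad: float  # deg/s, mean |eye_vel + head_vel|
    gain: float  # dimensionless, 1 = complete compensation
    n_samples: int


@dataclass
class VelDiffStats:
    """Statistics of the right-minus-left horizontal eye velocity
    difference during upright head posture, for one rotation sign."""

    rotation_sign: str  # 'CW' or 'CCW'
    median: float  # deg/s
    median_abs_deviation: float  # deg/s, median |x - median(x)|, unscaled
    skewness: float  # adjusted Fisher-Pearson sample skewness
    n_samples: int


def fixation_segments(
    pairs: list[BinocularSaccade], span: tuple[float, float], pad_s: float = 0.0
) -> list[tuple[float, float]]:
    """Inter-saccade intervals: the complement within ``span`` of the
    union of saccade [start, end] windows (union over the two eyes).

    Pairs without computed bounds contribute a window around their peaks
    spanning both peak times.  ``pad_s`` widens each exclusion on both
    sides (e.g. by the support of a velocity estimator).  Overlapping or
    abutting exclusions merge; zero-length intervals are dropped.
    """
    lo, hi = span
    windows = []
    for p in pairs:
        starts = [b for b in (p.left.start_time, p.right.start_time) if b is not None]
        ends = [b for b in (p.left.end_time, p.right.end_time) if b is not None]
        s = (min(starts) if starts else min(p.left.peak_time, p.right.peak_time)) - pad_s
        e = (max(ends) if ends else max(p.left.peak_time, p.right.peak_time)) + pad_s
        windows.append((max(s, lo), min(e, hi)))
    windows = sorted(w for w in windows if w[1] > lo and w[0] < hi)
    merged: list[tuple[float, float]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    out = []
    cursor = lo
    for s, e in merged:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if hi > cursor:
        out.append((cursor, hi))
    return out


def _paired_finite(eye_vel: np.ndarray, head_vel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eye_vel = np.asarray(eye_vel, dtype=float)
    head_vel = np.asarray(head_vel, dtype=float)
    if eye_vel.shape != head_vel.shape:
        raise ValueError("eye and head velocity arrays must be aligned")
    m = np.isfinite(eye_vel) & np.isfinite(head_vel)
    return eye_vel[m], head_vel[m]


def mad_from_full_compensation(eye_vel: np.ndarray, head_vel: np.ndarray) -> float:
    """Mean absolute deviation from complete compensation, deg/s."""
    e, h = _paired_finite(eye_vel, head_vel)
    if e.size < 100:
        raise ValueError("MAD requires at least 100 paired samples")
    return float(np.mean(np.abs(e + h)))


def stabilization_gain(eye_vel: np.ndarray, head_vel: np.ndarray) -> float:
    """Negative least-squares slope of eye velocity on head velocity,
    fit on the individual samples."""
    e, h = _paired_finite(eye_vel, head_vel)
    if e.size < 2 or np.var(h) == 0:
        raise ValueError("gain requires head-velocity variance > 0")
    slope = _stats.linregress(h, e).slope
    return float(-slope)


def stabilization_summary(eye_vel: np.ndarray, head_vel: np.ndarray) -> StabilizationResult:
    """MAD and gain over the same fixation-phase samples."""
    e, h = _paired_finite(eye_vel, head_vel)
    return StabilizationResult(
        mad=mad_from_full_compensation(e, h),
        gain=stabilization_gain(e, h),
        n_samples=int(e.size),
    )


def _skewness(x: np.ndarray) -> float:
    if np.std(x) == 0:
        warnings.warn("zero-variance sample; skewness reported as 0", stacklevel=3)
        return 0.0
    return float(_stats.skew(x, bias=False))


def velocity_difference_stats(
    v_right: np.ndarray,
    v_left: np.ndarray,
    pitch: np.ndarray,
    roll: np.ndarray,
    head_yaw_vel: np.ndarray,
    tilt_limit_deg: float = 10.0,
) -> dict[str, VelDiffStats]:
    """Right-minus-left horizontal eye velocity statistics per rotation
    sign during near-upright posture.

    Samples are retained only while both |pitch| and |roll| are below
    ``tilt_limit_deg`` and then split by the sign of head yaw velocity
    (CW positive under the reporting convention).  For each sign the
    median, unscaled median absolute deviation, and adjusted
    Fisher-Pearson skewness of (v_right - v_left) are returned.
    """
    arrs = [np.asarray(a, dtype=float) for a in (v_right, v_left, pitch, roll, head_yaw_vel)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("all traces must be sample-aligned")
    vr, vl, p, r, yv = arrs
    ok = (
        np.isfinite(vr)
        & np.isfinite(vl)
        & np.isfinite(p)
        & np.isfinite(r)
        & np.isfinite(yv)
        & (np.abs(p) < tilt_limit_deg)
        & (np.abs(r) < tilt_limit_deg)
    )
    if not np.any(ok):
        raise ValueError("no samples with near-upright head posture")
    out = {}
    for name, mask in (("CW", yv > 0), ("CCW", yv < 0)):
        d = (vr - vl)[ok & mask]
        if d.size == 0:
            continue
        med = float(np.median(d))
        out[name] = VelDiffStats(
            rotation_sign=name,
            median=med,
            median_abs_deviation=float(np.median(np.abs(d - med))),
            skewness=_skewness(d),
            n_samples=int(d.size),
        )
    return out


def gaze_shift_rate(events, duration_s: float) -> float:
    """Gaze shifts per second over a recording of known duration."""
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    return len(events) / duration_s


def permutation_test_L1(
    traces_a: list[np.ndarray],
    traces_b: list[np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Recording-level label permutation test on event-aligned traces.

    The statistic is the L1 norm between the two condition means of the
    per-recording average traces.  Labels are shuffled across all
    recordings ``n_perm`` times; the p-value is the fraction of
    permutations with a statistic at least as large as observed, with
    the observed labeling included in numerator and denominator
    ((k+1)/(n+1)), so p is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(traces_a) < 2 or len(traces_b) < 2:
        raise ValueError("need at least 2 recordings per condition")
    A = np.asarray(traces_a, dtype=float)
    B = np.asarray(traces_b, dtype=float)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("traces must share the same length")
    na = A.shape[0]
    pool = np.concatenate([A, B], axis=0)

    def stat(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.sum(np.abs(x.mean(axis=0) - y.mean(axis=0))))

    observed = stat(A, B)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        idx = rng.permutation(pool.shape[0])
        if stat(pool[idx[:na]], pool[idx[na:]]) >= observed:
            k += 1
    return observed, (k + 1) / (n_perm + 1)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based area under the ROC curve (ties share ranks).

    Equivalent to the Mann-Whitney U statistic normalized by the number
    of positive-negative pairs; all-equal scores give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes present")
    ranks = _stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
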