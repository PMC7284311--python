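"""Saccade detection, sizing, binocular pairing and gaze-shift components.

Saccades are rapid eye movements whose speed (combining the horizontal
and vertical components) exceeds 350 deg/s.  Detection keeps
supra-threshold local speed maxima and, within any 50 ms window (the
typical mouse saccade duration), only the larger peak.  Events detected
in both eyes within two camera frame intervals are paired; the reported
sign convention labels positive horizontal velocity at the peak as CW
(clockwise viewed from above) and negative as CCW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .trace import UniformTrace

__all__ = [
    "SaccadeEvent",
    "BinocularSaccade",
    "SACCADE_SPEED_THRESHOLD",
    "detect_saccades",
    "saccade_size",
    "pair_binocular",
    "same_sign_fraction",
    "event_triggered_average",
    "gaze_shift_components",
]

#: Eye speed threshold for saccade detection, deg/s.
SACCADE_SPEED_THRESHOLD = 350.0


@dataclass
class SaccadeEvent:
    """One detected saccade in one eye."""

    peak_time: float  # s
    peak_speed: float  # deg/s, >= detection threshold
    peak_vh: float  # horizontal velocity at the peak, deg/s (signed)
    eye: str = ""  # optional label, e.g. 'left'
    start_time: float | None = None  # filled by saccade_size
    end_time: float | None = None
    size_h: float | None = None  # signed horizontal amplitude, deg

    @property
    def direction(self) -> str:
        """'CW' when the horizontal peak velocity is positive under the
        CW-positive sign convention, else 'CCW'."""
        return "CW" if self.peak_vh >= 0 else "CCW"


@dataclass
class BinocularSaccade:
    """A saccade detected in both eyes within the pairing window."""

    left: SaccadeEvent
    right: SaccadeEvent
    dt: float = field(init=False)  # right peak time minus left, s
    same_sign: bool = field(init=False)

    def __post_init__(self) -> None:
        self.dt = self.right.peak_time - self.left.peak_time
        self.same_sign = np.sign(self.left.peak_vh) == np.sign(self.right.peak_vh)


def detect_saccades(
    vh: UniformTrace,
    vv: UniformTrace,
    threshold: float = SACCADE_SPEED_THRESHOLD,
    dedup_window_s: float = 0.05,
    eye: str = "",
) -> list[SaccadeEvent]:
    """Detect saccades from horizontal and vertical eye velocity traces.

    Speed is the Euclidean norm of the two velocity components.  Local
    speed maxima above ``threshold`` are candidates; within any
    ``dedup_window_s`` only the larger-magnitude peak is retained (ties
    keep the earlier peak).  Events come back time-ordered.
    """
    if vh.n != vv.n or vh.t0 != vv.t0 or vh.rate != vv.rate:
        raise ValueError("horizontal and vertical velocity traces must be aligned")
    speed = np.hypot(vh.values, vv.values)
    speed = np.where(np.isfinite(speed), speed, 0.0)
    peaks, _ = _signal.find_peaks(speed, height=threshold)
    if peaks.size == 0:
        return []
    # keep-the-larger deduplication: visit candidates from largest to
    # smallest (earlier first on ties) and suppress neighbors within the
    # window of an already retained peak
    order = sorted(range(peaks.size), key=lambda i: (-speed[peaks[i]], peaks[i]))
    window = int(round(dedup_window_s * vh.rate))
    kept: list[int] = []
    for i in order:
        p = peaks[i]
        if all(abs(p - q) > window for q in kept):
            kept.append(p)
    kept.sort()
    t = vh.times()
    return [
        SaccadeEvent(
            peak_time=float(t[p]),
            peak_speed=float(speed[p]),
            peak_vh=float(vh.values[p]),
            eye=eye,
        )
        for p in kept
    ]


def saccade_size(
    h: UniformTrace,
    event: SaccadeEvent,
    v: UniformTrace | None = None,
    oversample_ms: float = 5.0,
    stop_speed: float = 50.0,
    cap_ms: float = 35.0,
    margin_ms: float = 100.0,
) -> float | None:
    """Signed horizontal saccade amplitude; updates the event in place.

    The position trace is oversampled at ``oversample_ms`` resolution on
    +/-``margin_ms`` around the peak; scanning outward from the peak, the
    start and end are the first samples at which eye speed drops below
    ``stop_speed`` deg/s, capped at +/-``cap_ms``.  The size is the
    horizontal position difference between end and start.  Events without
    the full margin inside the trace are left unsized (returns None).
    """
    margin = margin_ms / 1000.0
    t_lo, t_hi = event.peak_time - margin, event.peak_time + margin
    span_lo, span_hi = h.t0, h.t0 + (h.n - 1) * h.dt
    if t_lo < span_lo or t_hi > span_hi:
        return None
    step = oversample_ms / 1000.0
    k = int(round(margin / step))
    tt = event.peak_time + np.arange(-k, k + 1) * step
    th = h.times()
    hh = np.interp(tt, th, h.values)
    comps = [np.gradient(hh, step)]
    if v is not None:
        comps.append(np.gradient(np.interp(tt, v.times(), v.values), step))
    speed = np.hypot(*comps) if len(comps) == 2 else np.abs(comps[0])
    cap = int(round(cap_ms / 1000.0 / step))
    # outward scan from the peak (index k)
    end = k + cap
    for i in range(k + 1, k + cap + 1):
        if speed[i] < stop_speed:
            end = i
            break
    start = k - cap
    for i in range(k - 1, k - cap - 1, -1):
        if speed[i] < stop_speed:
            start = i
            break
    event.start_time = float(tt[start])
    event.end_time = float(tt[end])
    event.size_h = float(hh[end] - hh[start])
    return event.size_h


def pair_binocular(
    left: list[SaccadeEvent],
    right: list[SaccadeEvent],
    frame_rate: float = 60.0,
) -> list[BinocularSaccade]:
    """Greedy nearest-in-time binocular pairing within two frame intervals.

    Candidate (left, right) pairs closer in time than ``2 / frame_rate``
    are matched nearest-first; each event is used at most once.
    """
    window = 2.0 / frame_rate
    cands = [
        (abs(r.peak_time - l.peak_time), i, j)
        for i, l in enumerate(left)
        for j, r in enumerate(right)
        if abs(r.peak_time - l.peak_time) < window
    ]
    cands.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        pairs.append(BinocularSaccade(left[i], right[j]))
    pairs.sort(key=lambda p: p.left.peak_time)
    return pairs


def same_sign_fraction(pairs: list[BinocularSaccade]) -> float:
    """Fraction of binocular saccades in which both eyes moved in the
    same rotational direction (conjugate saccades)."""
    if not pairs:
        raise ValueError("same_sign_fraction requires at least one pair")
    return sum(p.same_sign for p in pairs) / len(pairs)


def event_triggered_average(
    x: UniformTrace,
    events: list[SaccadeEvent],
    window_s: float,
    group_by_direction: bool = True,
) -> dict[str, dict[str, np.ndarray | int]]:
    """Event-aligned mean +/- SEM profiles of a trace.

    Extracts ``x`` on +/-``window_s`` around each event peak; events too
    close to the record edges, or with any missing sample in the window,
    are excluded.  Profiles are grouped by saccade direction (CW/CCW)
    unless ``group_by_direction`` is False, in which case a single
    ``'all'`` group is returned.  Each group maps to ``lags`` (s),
    ``mean``, ``sem`` and the event count ``n``.
    """
    k = int(round(window_s * x.rate))
    groups: dict[str, list[np.ndarray]] = {}
    for ev in events:
        c = x.index_at(ev.peak_time)
        if c - k < 0 or c + k >= x.n:
            continue
        seg = x.values[c - k : c + k + 1]
        if not np.all(np.isfinite(seg)):
            continue
        key = ev.direction if group_by_direction else "all"
        groups.setdefault(key, []).append(seg)
    if not groups:
        raise ValueError("no usable events with full windows")
    lags = np.arange(-k, k + 1) / x.rate
    out = {}
    for key, segs in groups.items():
        arr = np.asarray(segs)
        n = arr.shape[0]
        sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
        out[key] = {"lags": lags, "mean": arr.mean(axis=0), "sem": sem, "n": n}
    return out


def gaze_shift_components(
    h_left: UniformTrace,
    h_right: UniformTrace,
    yaw_pos: UniformTrace,
    pairs: list[BinocularSaccade],
    eye_mode: str = "mean",
) -> list[dict[str, float]]:
    """Eye-alone, head-alone and combined gaze displacement per saccade.

    Over each saccade's [start, end] window (union of the two eyes'
    bounds), the eye contribution is the horizontal eye displacement
    (binocular mean by default, or ``'left'``/``'right'``), the head
    contribution is the integrated yaw displacement, and the combined
    gaze shift their sum.  Pairs whose bounds were not computed are
    skipped.
    """
    if eye_mode not in ("mean", "left", "right"):
        raise ValueError("eye_mode must be 'mean', 'left' or 'right'")
    t_yaw = yaw_pos.times()
    out = []
    for p in pairs:
        bounds = [p.left.start_time, p.left.end_time, p.right.start_time, p.right.end_time]
        if any(b is None for b in bounds):
            continue
        t0 = min(p.left.start_time, p.right.start_time)  # type: ignore[arg-type]
        t1 = max(p.left.end_time, p.right.end_time)  # type: ignore[arg-type]
        d_l = float(
            np.interp(t1, h_left.times(), h_left.values)
            - np.interp(t0, h_left.times(), h_left.values)
        )
        d_r = float(
            np.interp(t1, h_right.times(), h_right.values)
            - np.interp(t0, h_right.times(), h_right.values)
        )
        eye = {"mean": 0.5 * (d_l + d_r), "left": d_l, "right": d_r}[eye_mode]
        head = float(np.interp(t1, t_yaw, yaw_pos.values) - np.interp(t0, t_yaw, yaw_pos.values))
        out.append(
            {
                "peak_time": p.left.peak_time,
                "eye_alone": eye,
                "head_alone": head,
                "combined": eye + head,
            }
        )
    return out
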