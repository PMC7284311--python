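"""Saccade detection, sizing, binocular pairing and gaze-shift components."""

from __future__ import annotations

import numpy as np
import pytest

from gazekit.pipeline import detect_and_pair, head_yaw_velocity_cw
from gazekit.saccades import (
    SaccadeEvent,
    detect_saccades,
    event_triggered_average,
    gaze_shift_components,
    pair_binocular,
    saccade_size,
    same_sign_fraction,
)
from gazekit.signals import estimate_gyro_drift, integrate_yaw, resample_trace, smooth_eye_trace, velocity
from gazekit.synthetic import SimConfig, simulate_session
from gazekit.trace import UniformTrace


def tr(values, rate=60.0):
    return UniformTrace(0.0, rate, np.asarray(values, dtype=float))


def gauss_step(t, center, size, sigma=0.006):
    from scipy.special import erf

    return 0.5 * size * (1.0 + erf((t - center) / (sigma * np.sqrt(2.0))))


def step_velocities(center=1.0, size=20.0, rate=60.0, dur=2.0):
    t = np.arange(int(dur * rate)) / rate
    h = gauss_step(t, center, size)
    vh = velocity(tr(h, rate))
    vv = velocity(tr(np.zeros_like(h), rate))
    return t, h, vh, vv


class TestDetect:
    def test_subthreshold_empty(self):
        t = np.arange(300) / 60.0
        vh = tr(100.0 * np.sin(2 * np.pi * t))
        vv = tr(np.zeros_like(t))
        assert detect_saccades(vh, vv) == []

    def test_single_event_at_peak(self):
        t, h, vh, vv = step_velocities()
        events = detect_saccades(vh, vv)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(1.0, abs=1.5 / 60.0)
        assert events[0].peak_speed > 350.0

    def test_dedup_keeps_larger(self):
        rate = 1000.0
        t = np.arange(int(0.4 * rate)) / rate
        v = 400.0 * np.exp(-0.5 * ((t - 0.1) / 0.004) ** 2) + 500.0 * np.exp(
            -0.5 * ((t - 0.13) / 0.004) ** 2
        )
        events = detect_saccades(tr(v, rate), tr(np.zeros_like(v), rate))
        assert len(events) == 1
        assert events[0].peak_speed == pytest.approx(500.0, rel=0.01)

    def test_dedup_window_exclusivity(self, session600):
        events, _ = detect_and_pair(session600.eyes)
        for evs in events.values():
            times = np.array([e.peak_time for e in evs])
            assert np.all(np.diff(times) > 0.05)

    def test_noise_invariance(self):
        t, h, vh, vv = step_velocities()
        events = detect_saccades(vh, vv)
        rng = np.random.default_rng(0)
        # sub-threshold velocity noise does not change the detection
        noisy = tr(vh.values + rng.uniform(-20, 20, vh.n))
        events2 = detect_saccades(noisy, vv)
        assert len(events2) == len(events)
        assert events2[0].peak_time == events[0].peak_time

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            detect_saccades(tr(np.zeros(10)), tr(np.zeros(11)))

    def test_recall_precision_on_defaults(self, session600):
        events, _ = detect_and_pair(session600.eyes)
        truth = session600.truth.event_times
        det = np.array([e.peak_time for e in events["left"]])
        tol = 1.5 / 60.0
        matched = sum(np.any(np.abs(det - tk) < tol) for tk in truth)
        recall = matched / truth.size
        precision = sum(np.any(np.abs(truth - td) < tol) for td in det) / det.size
        assert recall >= 0.95 and precision >= 0.95


class TestPairing:
    def ev(self, t, vh=500.0, eye=""):
        return SaccadeEvent(peak_time=t, peak_speed=abs(vh), peak_vh=vh, eye=eye)

    def test_close_events_pair(self):
        pairs = pair_binocular([self.ev(1.0)], [self.ev(1.010)])
        assert len(pairs) == 1
        assert pairs[0].dt == pytest.approx(0.010)

    def test_distant_events_do_not_pair(self):
        assert pair_binocular([self.ev(1.0)], [self.ev(1.040)]) == []

    def test_empty_lists(self):
        assert pair_binocular([], [self.ev(1.0)]) == []

    def test_each_event_used_once(self):
        left = [self.ev(1.0), self.ev(1.02)]
        right = [self.ev(1.005)]
        pairs = pair_binocular(left, right)
        assert len(pairs) == 1
        assert pairs[0].left.peak_time == 1.0

    def test_same_sign_fraction_trivial(self):
        p1 = pair_binocular([self.ev(1.0, 500)], [self.ev(1.0, 400)])
        p2 = pair_binocular([self.ev(2.0, 500)], [self.ev(2.0, -400)])
        assert same_sign_fraction(p1) == 1.0
        assert same_sign_fraction(p1 * 3 + p2) == pytest.approx(0.75)

    def test_same_sign_empty_rejected(self):
        with pytest.raises(ValueError):
            same_sign_fraction([])

    def test_conjugacy_recovery(self, session600):
        _, pairs = detect_and_pair(session600.eyes)
        truth = session600.truth
        p_true = float(np.mean(truth.dir_left == truth.dir_right))
        n = len(pairs)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert same_sign_fraction(pairs) == pytest.approx(p_true, abs=4 * se + 0.01)


class TestSizing:
    def test_smooth_step_size(self):
        t, h, vh, vv = step_velocities(size=15.0)
        ht = smooth_eye_trace(tr(h))
        ev = detect_saccades(velocity(ht), vv)[0]
        size = saccade_size(ht, ev)
        assert size == pytest.approx(15.0, abs=1.0)
        assert ev.start_time <= ev.peak_time <= ev.end_time

    def test_cap_at_35ms(self):
        rate = 60.0
        t = np.arange(int(4 * rate)) / rate
        h = 200.0 * (t - 2.0)  # constant 200 deg/s, always above stop speed
        ev = SaccadeEvent(peak_time=2.0, peak_speed=400.0, peak_vh=400.0)
        saccade_size(tr(h), ev)
        assert ev.start_time == pytest.approx(2.0 - 0.035, abs=1e-9)
        assert ev.end_time == pytest.approx(2.0 + 0.035, abs=1e-9)

    def test_flat_trace_zero(self):
        h = tr(np.zeros(240))
        ev = SaccadeEvent(peak_time=2.0, peak_speed=400.0, peak_vh=400.0)
        assert saccade_size(h, ev) == pytest.approx(0.0)

    def test_insufficient_margin_flagged(self):
        h = tr(np.zeros(240))
        ev = SaccadeEvent(peak_time=0.01, peak_speed=400.0, peak_vh=400.0)
        assert saccade_size(h, ev) is None
        assert ev.size_h is None

    def test_sizes_match_truth_on_quiet_session(self):
        """Sizing accuracy isolated from the slow phase: a session with
        slow head yaw so the window drift is negligible."""
        cfg = SimConfig(
            seed=9, duration_s=200.0, yaw_vel_sd_dps=5.0,
            head_turn_per_saccade_deg=0.0, eye_noise_sd_deg=0.1,
        )
        sess = simulate_session(cfg)
        events, _ = detect_and_pair(sess.eyes)
        truth = sess.truth
        errs = []
        for ev in events["left"]:
            k = int(np.argmin(np.abs(truth.event_times - ev.peak_time)))
            if abs(truth.event_times[k] - ev.peak_time) < 1.5 / 60 and ev.size_h is not None:
                errs.append(abs(ev.size_h - truth.size_left[k]))
        assert len(errs) > 100
        assert np.median(errs) < 1.0


class TestEventTriggeredAverage:
    def test_identical_profiles(self):
        rate = 60.0
        t = np.arange(int(20 * rate)) / rate
        x = np.zeros_like(t)
        events = []
        for c in (3.0, 7.0, 11.0, 15.0):
            x += np.exp(-0.5 * ((t - c) / 0.05) ** 2)
            events.append(SaccadeEvent(peak_time=c, peak_speed=400.0, peak_vh=400.0))
        out = event_triggered_average(tr(x, rate), events, 0.5)
        assert out["CW"]["n"] == 4
        assert np.allclose(out["CW"]["sem"], 0.0, atol=1e-9)
        assert out["CW"]["mean"].max() == pytest.approx(1.0, abs=1e-6)

    def test_sem_scales_with_noise(self):
        rng = np.random.default_rng(0)
        rate = 60.0
        t = np.arange(int(200 * rate)) / rate
        eps = 0.5
        x = rng.normal(0, eps, t.size)
        events = [
            SaccadeEvent(peak_time=c, peak_speed=400.0, peak_vh=400.0)
            for c in np.arange(2.0, 198.0, 2.0)
        ]
        out = event_triggered_average(tr(x, rate), events, 0.25)
        n = out["CW"]["n"]
        assert np.mean(out["CW"]["sem"]) == pytest.approx(eps / np.sqrt(n), rel=0.15)

    def test_edge_events_excluded(self):
        x = tr(np.zeros(600))
        events = [
            SaccadeEvent(peak_time=0.1, peak_speed=400.0, peak_vh=400.0),
            SaccadeEvent(peak_time=5.0, peak_speed=400.0, peak_vh=400.0),
        ]
        out = event_triggered_average(x, events, 0.5)
        assert out["CW"]["n"] == 1


class TestGazeShiftComponents:
    def test_additivity_and_recovery(self, session600):
        sess = session600
        events, pairs = detect_and_pair(sess.eyes)
        drift = estimate_gyro_drift(sess.imu.yaw_rate(), (0.0, 20.0))
        yaw_cw = head_yaw_velocity_cw(sess.imu, drift)
        yaw_pos = integrate_yaw(yaw_cw, 0.0)
        comps = gaze_shift_components(
            sess.eyes["left_h"], sess.eyes["right_h"], yaw_pos, pairs
        )
        assert len(comps) > 100
        for c in comps[:50]:
            assert c["combined"] == pytest.approx(
                c["eye_alone"] + c["head_alone"], abs=1e-9
            )

    def test_head_stationary(self):
        rate = 60.0
        t = np.arange(int(4 * rate)) / rate
        h = gauss_step(t, 2.0, 20.0)
        ht = smooth_eye_trace(tr(h))
        vh = velocity(ht)
        ev_l = detect_saccades(vh, velocity(tr(np.zeros_like(h))), eye="left")
        ev_r = detect_saccades(vh, velocity(tr(np.zeros_like(h))), eye="right")
        for e in ev_l + ev_r:
            saccade_size(ht, e)
        pairs = pair_binocular(ev_l, ev_r)
        yaw_pos = tr(np.zeros_like(h))
        comps = gaze_shift_components(ht, ht, yaw_pos, pairs)
        assert len(comps) == 1
        assert comps[0]["head_alone"] == pytest.approx(0.0, abs=1e-9)
        assert comps[0]["combined"] == pytest.approx(comps[0]["eye_alone"])


class TestAsymmetry:
    def test_temporal_bias_shifts_eye_positions_apart(self):
        """Larger temporal-ward (divergent) saccades shift the equilibrium
        eye positions outward; the resting positions, not the realized step
        sizes, carry the signature because recentering feedback rebalances
        the steps."""
        div = {}
        for asym in (1.0, 1.4):
            cfg = SimConfig(seed=4, duration_s=300.0, nasal_temporal_asymmetry=asym)
            sess = simulate_session(cfg)
            div[asym] = float(
                sess.eyes["left_h"].values.mean() - sess.eyes["right_h"].values.mean()
            )
        assert abs(div[1.0]) < 5.0
        assert div[1.4] > div[1.0] + 5.0
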