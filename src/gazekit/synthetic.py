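"""Forward model of freely-moving and head-restrained recording sessions.

The generator produces binocular eye traces, IMU traces and (for
head-restrained sessions) a piezo sensor trace with the statistical
structure the analysis assumes, together with exact ground truth:

* head pitch and roll follow bounded Ornstein-Uhlenbeck excursions;
  the accelerometer reads the rotated gravity direction plus noise;
* head yaw velocity is a smooth mean-reverting process plus brief
  saccade-locked head turns; the gyroscope adds a constant drift and
  white noise;
* each eye's position is, exactly, the sum of three bookkept parts:
  a tilt-driven component (a memoryless compensatory map of pitch/roll
  through the gaze geometry), a conjugate component (slow-phase
  counter-rotation at the aVOR gain, interrupted by rapid saccadic
  steps), and white observation noise;
* saccades arrive as a renewal process; the two eyes step in the same
  rotational direction with probability ``p_conj``; step directions are
  softly biased toward recentering the eye in the orbit; sizes carry an
  optional temporal-to-nasal asymmetry factor.

Horizontal angular signals in the generated data follow the
reporting sign convention: clockwise viewed from above is positive,
for eye positions and for derived head yaw alike.  The gyroscope z
channel is physical (right-handed about the dorsal axis, so CCW
positive); analysis code negates it when deriving CW-positive yaw.

Default parameter values are the study conditions: aVOR gain 0.53,
gyroscope drift -1.60 deg/s, saccade rate 1.5/s (within the observed 1-2
shifts per second), conjugacy probability 0.94.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf, expit

from .geometry import EyeAxisPlacement
from .signals import ImuRecord
from .trace import UniformTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticSession",
    "RectangleTrajectory",
    "simulate_session",
    "simulate_sensor_session",
    "simulate_stationary_gyro",
    "rectangle_position",
    "simulate_task_trials",
]


@dataclass
class SimConfig:
    """Full parameterization of a synthetic session.

    All angular quantities are degrees; rates are Hz; times are seconds.
    """

    seed: int
    duration_s: float = 600.0
    camera_rate: float = 60.0
    imu_rate: float = 190.0

    #: stationary prefix with no head motion, used for gyro drift
    #: calibration; motion ramps up over ``onset_ramp_s`` after it
    calibration_s: float = 20.0
    onset_ramp_s: float = 5.0

    # head tilt process (Ornstein-Uhlenbeck)
    pitch_sd_deg: float = 15.0
    pitch_tau_s: float = 2.0
    roll_sd_deg: float = 12.0
    roll_tau_s: float = 2.0

    # tilt -> eye coupling: compensatory orbit angles scaled by
    # ``tilt_compensation`` and softly saturated at ``tilt_saturation_deg``
    tilt_compensation: float = 0.8
    tilt_saturation_deg: float = 30.0

    # conjugate slow phase
    avor_gain: float = 0.53
    yaw_vel_sd_dps: float = 40.0
    yaw_vel_tau_s: float = 0.5
    #: head inertia bounds angular acceleration: the yaw-velocity process
    #: is low-pass filtered at this corner (Hz) and rescaled to its SD
    yaw_vel_bandwidth_hz: float = 3.0

    # saccades
    saccade_rate_hz: float = 1.5
    saccade_refractory_s: float = 0.25
    saccade_min_deg: float = 15.0
    saccade_size_shape: float = 2.0
    saccade_size_scale_deg: float = 2.5
    nasal_temporal_asymmetry: float = 1.0
    p_conj: float = 0.94
    recenter_softness_deg: float = 15.0
    recenter_size_gain: float = 0.7
    profile_sigma_s: float = 0.006
    head_turn_per_saccade_deg: float = 10.0
    head_turn_sigma_s: float = 0.12

    # sensors
    gyro_drift_dps: float = -1.60
    gyro_noise_sd_dps: float = 1.0
    accel_noise_sd_g: float = 0.005
    eye_noise_sd_deg: float = 0.3

    # head-restrained piezo sensor
    sensor_rate: float = 190.0
    sensor_noise_sd: float = 1.0
    sensor_gain_per_deg: float = 0.5
    sensor_pulse_sigma_s: float = 0.03
    attempt_rate_hz: float = 0.3

    #: optional per-axis target for the fraction of eye-position variance
    #: carried by the tilt component, e.g. {"h": 0.62, "v": 0.86}; the
    #: conjugate-plus-noise residual of that axis is rescaled to hit it
    tilt_variance_fraction: dict | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for name in ("camera_rate", "imu_rate", "sensor_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.avor_gain <= 1.5:
            raise ValueError("avor_gain must be in [0, 1.5]")
        if not 0 <= self.p_conj <= 1:
            raise ValueError("p_conj must be in [0, 1]")
        if self.tilt_variance_fraction is not None:
            for ax, f in self.tilt_variance_fraction.items():
                if ax not in ("h", "v") or not 0 < f < 1:
                    raise ValueError("tilt_variance_fraction maps 'h'/'v' to (0,1)")

    @property
    def analysis_start_s(self) -> float:
        """Start of the usable analysis window (after calibration and
        motion onset ramp)."""
        return self.calibration_s + self.onset_ramp_s


@dataclass
class GroundTruth:
    """Exact bookkeeping of the generated session."""

    event_times: np.ndarray  # saccade centers, s
    dir_left: np.ndarray  # +1 = CW, -1 = CCW
    dir_right: np.ndarray
    size_left: np.ndarray  # signed step, deg (CW positive)
    size_right: np.ndarray
    components: dict  # eye -> axis -> dict(tilt, conjugate, noise) arrays
    drift_dps: float
    variance_fraction: dict  # eye -> axis -> achieved tilt fraction
    analysis_start_s: float

    def observed(self, eye: str, axis: str) -> np.ndarray:
        c = self.components[eye][axis]
        return c["tilt"] + c["conjugate"] + c["noise"]


@dataclass
class SyntheticSession:
    """Generated session: per-eye camera-rate traces, IMU record and
    ground truth."""

    eyes: dict  # keys 'left_h', 'left_v', 'right_h', 'right_v' -> UniformTrace
    imu: ImuRecord
    truth: GroundTruth
    config: SimConfig
    sensor: UniformTrace | None = None


def _ou(rng: np.random.Generator, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (exact discretization)."""
    a = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i - 1]
    return x


def _onset_envelope(t: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """0 during calibration, smooth cosine ramp to 1 over the onset."""
    env = np.clip((t - cfg.calibration_s) / max(cfg.onset_ramp_s, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * env))


def _gauss_step(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Unit smooth step (Gaussian CDF) centered at ``center``."""
    return 0.5 * (1.0 + erf((t - center) / (sigma * math.sqrt(2.0))))


def _gauss_pulse(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _event_times(rng: np.random.Generator, cfg: SimConfig, t_lo: float, t_hi: float) -> np.ndarray:
    """Renewal process: refractory period plus exponential gaps, with the
    mean gap equal to 1/rate.  A rate of zero yields no events."""
    if cfg.saccade_rate_hz <= 0:
        return np.asarray([])
    mean_gap = 1.0 / cfg.saccade_rate_hz
    if mean_gap <= cfg.saccade_refractory_s:
        raise ValueError("saccade rate too high for the refractory period")
    exp_mean = mean_gap - cfg.saccade_refractory_s
    times = []
    t = t_lo + rng.exponential(exp_mean)
    while t < t_hi:
        times.append(t)
        t += cfg.saccade_refractory_s + rng.exponential(exp_mean)
    return np.asarray(times)


def _compensatory_orbit(
    pitch_deg: np.ndarray,
    roll_deg: np.ndarray,
    placement: EyeAxisPlacement,
    compensation: float,
    saturation_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Orbit angles that (fully, before scaling) restore the resting gaze
    direction up to a rotation about the vertical axis.

    For head tilt (pitch, roll) the target gaze keeps the resting
    elevation and follows the head's horizontal heading; solving
    placement^T tilt^T Rz(heading) u_rest for the local gaze direction
    yields the compensatory eye-in-orbit angles, which are then scaled by
    ``compensation`` and passed through a tanh saturation.  Returns
    (eyeh, eyev) in degrees, with eyeh in the CW-positive convention.
    """
    th = np.deg2rad(pitch_deg)
    ph = np.deg2rad(roll_deg)
    az = math.radians(placement.azimuth)
    el = math.radians(placement.elevation)
    # resting eye axis in the head frame
    ux = math.cos(el) * math.cos(az)
    uy = math.cos(el) * math.sin(az)
    uz = math.sin(el)
    # heading: azimuth of the tilted head's forward axis
    psi = np.arctan2(-np.sin(ph) * np.sin(th), np.cos(th))
    cpsi, spsi = np.cos(psi), np.sin(psi)
    gx = cpsi * ux - spsi * uy
    gy = spsi * ux + cpsi * uy
    gz = np.full_like(gx, uz)
    # head-in-space transpose: Rx(-roll) then Ry(+pitch)
    cph, sph = np.cos(ph), np.sin(ph)
    hy = cph * gy + sph * gz
    hz = -sph * gy + cph * gz
    cth, sth = np.cos(th), np.sin(th)
    hx = cth * gx + sth * hz
    hz = -sth * gx + cth * hz
    # placement transpose: Rz(-az) then Ry(+el)
    ca, sa = math.cos(az), math.sin(az)
    px = ca * hx + sa * hy
    py = -sa * hx + ca * hy
    ce, se = math.cos(el), math.sin(el)
    wx = ce * px + se * hz
    wz = -se * px + ce * hz
    eyev = np.rad2deg(np.arcsin(np.clip(wz, -1.0, 1.0)))
    eyeh_rh = np.rad2deg(np.arctan2(py, wx))
    s = saturation_deg
    eyev = s * np.tanh(compensation * eyev / s)
    eyeh_cw = -s * np.tanh(compensation * eyeh_rh / s)
    return eyeh_cw, eyev


def _residual_scale(tilt: np.ndarray, resid: np.ndarray, target_f: float) -> float:
    """Scale factor s for the residual so that the best-achievable R^2 of
    the tilt component, 1 - var(s*resid)/var(tilt + s*resid), equals
    ``target_f`` on this sample (covariance included)."""
    var_t = np.var(tilt)
    var_r = np.var(resid)
    cov = np.cov(tilt, resid)[0, 1]
    f = target_f
    # f * var_r * s^2 - 2 (1-f) cov s - (1-f) var_t = 0
    a, b, c = f * var_r, -2 * (1 - f) * cov, -(1 - f) * var_t
    disc = b * b - 4 * a * c
    if disc < 0 or a <= 0:
        raise ValueError("cannot reach the requested variance fraction")
    return (-b + math.sqrt(disc)) / (2 * a)


def _draw_saccade_train(
    rng: np.random.Generator,
    cfg: SimConfig,
    t_cam: np.ndarray,
    c_slow: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Event times, per-eye signed step sizes and the two eyes' cumulative
    saccadic step waveforms on the camera grid.

    Step directions are drawn with a soft recentering bias on the driving
    eye's current conjugate position; the other eye steps in the same
    direction with probability ``p_conj``.  The temporal-to-nasal
    asymmetry factor multiplies sizes of temporal-to-nasal movements
    (CW for the left eye, CCW for the right eye).
    """
    t_lo = cfg.analysis_start_s + 1.0
    t_hi = cfg.duration_s - 1.0
    ev = _event_times(rng, cfg, t_lo, t_hi)
    n = ev.size
    dir_l = np.empty(n)
    dir_r = np.empty(n)
    size_l = np.empty(n)
    size_r = np.empty(n)
    jumps_l = np.zeros_like(t_cam)
    jumps_r = np.zeros_like(t_cam)
    cum_l = 0.0
    cum_r = 0.0
    # slow-phase offset contributed by the saccade-locked head turns of
    # earlier events; the recentering must see the realized position, or
    # the uncorrected offsets accumulate into an unbounded random walk
    head_offset = 0.0
    per_turn = cfg.avor_gain * cfg.head_turn_per_saccade_deg
    sigma = cfg.profile_sigma_s
    halfwin = max(5 * sigma, 0.05)
    for k in range(n):
        tk = ev[k]
        i = np.searchsorted(t_cam, tk)
        drv_left = rng.random() < 0.5
        c_here = c_slow[min(i, c_slow.size - 1)] + head_offset
        c_l = c_here + cum_l
        c_r = c_here + cum_r
        c_drv = c_l if drv_left else c_r
        p_cw = expit(-c_drv / cfg.recenter_softness_deg)
        d_drv = 1.0 if rng.random() < p_cw else -1.0
        d_oth = d_drv if rng.random() < cfg.p_conj else -d_drv
        mag = cfg.saccade_min_deg + rng.gamma(cfg.saccade_size_shape, cfg.saccade_size_scale_deg)
        d_l, d_r = (d_drv, d_oth) if drv_left else (d_oth, d_drv)
        # steps toward an eye's own center scale with that eye's
        # eccentricity (recentering saccades), which keeps both the
        # eye-in-orbit positions and the vergence between the eyes within
        # their physiological range and mixing on a saccade timescale
        m_l = mag + (cfg.recenter_size_gain * abs(c_l) if d_l * c_l < 0 else 0.0)
        m_r = mag + (cfg.recenter_size_gain * abs(c_r) if d_r * c_r < 0 else 0.0)
        # temporal-to-nasal movements are larger by the asymmetry factor:
        # CW is temporal-to-nasal for the left eye, CCW for the right
        m_l *= cfg.nasal_temporal_asymmetry if d_l > 0 else 1.0
        m_r *= cfg.nasal_temporal_asymmetry if d_r < 0 else 1.0
        s_l, s_r = d_l * m_l, d_r * m_r
        lo = np.searchsorted(t_cam, tk - halfwin)
        hi = np.searchsorted(t_cam, tk + halfwin)
        step = _gauss_step(t_cam[lo:hi], tk, sigma)
        jumps_l[lo:hi] += s_l * step
        jumps_l[hi:] += s_l
        jumps_r[lo:hi] += s_r * step
        jumps_r[hi:] += s_r
        cum_l += s_l
        cum_r += s_r
        d_head = math.copysign(1.0, d_l + d_r) if d_l + d_r != 0 else d_l
        head_offset -= per_turn * d_head
        dir_l[k], dir_r[k] = d_l, d_r
        size_l[k], size_r[k] = s_l, s_r
    meta = {"n_events": n}
    return ev, dir_l, dir_r, size_l, size_r, {"left": jumps_l, "right": jumps_r, **meta}


def simulate_session(cfg: SimConfig) -> SyntheticSession:
    """Generate a complete freely-moving session.

    Deterministic given ``cfg.seed``; the observed eye trace of each
    eye/axis equals tilt + conjugate + noise exactly (see
    :class:`GroundTruth`).
    """
    rng = np.random.default_rng(cfg.seed)
    n_imu = int(round(cfg.duration_s * cfg.imu_rate)) + 1
    n_cam = int(round(cfg.duration_s * cfg.camera_rate)) + 1
    t_imu = np.arange(n_imu) / cfg.imu_rate
    t_cam = np.arange(n_cam) / cfg.camera_rate
    dt_imu = 1.0 / cfg.imu_rate
    env = _onset_envelope(t_imu, cfg)

    # --- head orientation ---------------------------------------------
    pitch = _ou(rng, n_imu, dt_imu, cfg.pitch_sd_deg, cfg.pitch_tau_s) * env
    roll = _ou(rng, n_imu, dt_imu, cfg.roll_sd_deg, cfg.roll_tau_s) * env
    yaw_vel_cw = _ou(rng, n_imu, dt_imu, cfg.yaw_vel_sd_dps, cfg.yaw_vel_tau_s)
    if cfg.yaw_vel_bandwidth_hz and cfg.yaw_vel_bandwidth_hz < cfg.imu_rate / 2:
        from scipy import signal as _scipy_signal

        sos = _scipy_signal.butter(
            2, cfg.yaw_vel_bandwidth_hz, btype="low", fs=cfg.imu_rate, output="sos"
        )
        yaw_vel_cw = _scipy_signal.sosfiltfilt(sos, yaw_vel_cw)
        sd = np.std(yaw_vel_cw)
        if sd > 0:
            yaw_vel_cw *= cfg.yaw_vel_sd_dps / sd
    yaw_vel_cw = yaw_vel_cw * env

    # conjugate slow phase needs the yaw position on the camera grid;
    # saccade-locked head turns are added after the event times are known,
    # so draw events against the slow phase from the background yaw first
    yaw_pos_bg = np.concatenate([[0.0], np.cumsum((yaw_vel_cw[1:] + yaw_vel_cw[:-1]) / 2) * dt_imu])
    c_slow_bg = -cfg.avor_gain * np.interp(t_cam, t_imu, yaw_pos_bg)
    ev, dir_l, dir_r, size_l, size_r, jumps = _draw_saccade_train(rng, cfg, t_cam, c_slow_bg)

    # saccade-locked head turns (same direction as the driving eye's step;
    # use the mean of the two eyes' directions as the head direction)
    if cfg.head_turn_per_saccade_deg > 0 and ev.size > 0:
        amp = cfg.head_turn_per_saccade_deg / (cfg.head_turn_sigma_s * math.sqrt(2 * math.pi))
        head_dir = np.where(dir_l + dir_r != 0, np.sign(dir_l + dir_r), dir_l)
        for tk, d in zip(ev, head_dir):
            lo = np.searchsorted(t_imu, tk - 5 * cfg.head_turn_sigma_s)
            hi = np.searchsorted(t_imu, tk + 5 * cfg.head_turn_sigma_s)
            yaw_vel_cw[lo:hi] += d * amp * _gauss_pulse(t_imu[lo:hi], tk, cfg.head_turn_sigma_s)
    yaw_pos = np.concatenate([[0.0], np.cumsum((yaw_vel_cw[1:] + yaw_vel_cw[:-1]) / 2) * dt_imu])
    c_slow = -cfg.avor_gain * np.interp(t_cam, t_imu, yaw_pos)

    # --- per-eye components on the camera grid ------------------------
    pitch_cam = np.interp(t_cam, t_imu, pitch)
    roll_cam = np.interp(t_cam, t_imu, roll)
    placements = {
        "left": EyeAxisPlacement.default("left"),
        "right": EyeAxisPlacement.default("right"),
    }
    a_start = cfg.analysis_start_s
    win = t_cam >= a_start
    components: dict = {}
    var_frac: dict = {}
    eyes: dict = {}
    h_scale = {"left": 1.0, "right": 1.0}
    for eye in ("left", "right"):
        th, tv = _compensatory_orbit(
            pitch_cam, roll_cam, placements[eye], cfg.tilt_compensation, cfg.tilt_saturation_deg
        )
        conj_h = c_slow + jumps[eye]
        noise_h = rng.normal(0.0, cfg.eye_noise_sd_deg, n_cam)
        conj_v = np.zeros(n_cam)
        noise_v = rng.normal(0.0, cfg.eye_noise_sd_deg, n_cam)
        scales = {"h": 1.0, "v": 1.0}
        if cfg.tilt_variance_fraction:
            if "h" in cfg.tilt_variance_fraction:
                scales["h"] = _residual_scale(
                    th[win], (conj_h + noise_h)[win], cfg.tilt_variance_fraction["h"]
                )
            if "v" in cfg.tilt_variance_fraction:
                scales["v"] = _residual_scale(
                    tv[win], (conj_v + noise_v)[win], cfg.tilt_variance_fraction["v"]
                )
        conj_h, noise_h = conj_h * scales["h"], noise_h * scales["h"]
        conj_v, noise_v = conj_v * scales["v"], noise_v * scales["v"]
        h_scale[eye] = scales["h"]
        components[eye] = {
            "h": {"tilt": th, "conjugate": conj_h, "noise": noise_h},
            "v": {"tilt": tv, "conjugate": conj_v, "noise": noise_v},
        }
        var_frac[eye] = {}
        for ax in ("h", "v"):
            c = components[eye][ax]
            obs = c["tilt"] + c["conjugate"] + c["noise"]
            resid = c["conjugate"] + c["noise"]
            v_obs = np.var(obs[win])
            # degenerate configs (all variance sources zero) have no
            # meaningful fraction; report 0 rather than dividing by zero
            var_frac[eye][ax] = float(1.0 - np.var(resid[win]) / v_obs) if v_obs > 0 else 0.0
            eyes[f"{eye}_{ax[0]}"] = UniformTrace(0.0, cfg.camera_rate, obs)

    # bookkept step sizes reflect any residual rescale of the h axis
    size_l_eff = size_l * h_scale["left"]
    size_r_eff = size_r * h_scale["right"]

    # --- IMU synthesis -------------------------------------------------
    thr = np.deg2rad(pitch)
    phr = np.deg2rad(roll)
    # gravity (upward unit vector) in the head frame for roll-after-pitch
    ax_ = np.sin(thr) * np.cos(phr)
    ay_ = np.sin(phr)
    az_ = np.cos(thr) * np.cos(phr)
    accel = np.column_stack([ax_, ay_, az_]) + rng.normal(0.0, cfg.accel_noise_sd_g, (n_imu, 3))
    gyro = np.empty((n_imu, 3))
    gyro[:, 0] = np.gradient(roll, dt_imu)
    gyro[:, 1] = np.gradient(pitch, dt_imu)
    gyro[:, 2] = -yaw_vel_cw + cfg.gyro_drift_dps
    gyro += rng.normal(0.0, cfg.gyro_noise_sd_dps, (n_imu, 3))
    imu = ImuRecord(
        accel=UniformTrace(0.0, cfg.imu_rate, accel),
        gyro=UniformTrace(0.0, cfg.imu_rate, gyro),
    )

    truth = GroundTruth(
        event_times=ev,
        dir_left=dir_l,
        dir_right=dir_r,
        size_left=size_l_eff,
        size_right=size_r_eff,
        components=components,
        drift_dps=cfg.gyro_drift_dps,
        variance_fraction=var_frac,
        analysis_start_s=a_start,
    )
    return SyntheticSession(eyes=eyes, imu=imu, truth=truth, config=cfg)


def simulate_sensor_session(cfg: SimConfig) -> SyntheticSession:
    """Head-restrained session: saccades without actual head motion and a
    piezo sensor reporting attempted yaw rotations.

    The sensor carries one band-limited pulse per saccade with sign equal
    to the saccade direction and amplitude proportional to its size, plus
    additional attempted-rotation pulses without saccades, plus white
    noise.  Ground-truth components for the eyes hold zero tilt and the
    saccadic steps as the conjugate part.
    """
    cfg_r = replace(
        cfg,
        pitch_sd_deg=0.0,
        roll_sd_deg=0.0,
        yaw_vel_sd_dps=0.0,
        head_turn_per_saccade_deg=0.0,
        avor_gain=0.0,
        tilt_variance_fraction=None,
    )
    rng = np.random.default_rng(cfg.seed)
    n_cam = int(round(cfg.duration_s * cfg.camera_rate)) + 1
    t_cam = np.arange(n_cam) / cfg.camera_rate
    c_zero = np.zeros(n_cam)
    ev, dir_l, dir_r, size_l, size_r, jumps = _draw_saccade_train(rng, cfg_r, t_cam, c_zero)

    eyes = {}
    components: dict = {}
    for eye, j in (("left", jumps["left"]), ("right", jumps["right"])):
        noise_h = rng.normal(0.0, cfg.eye_noise_sd_deg, n_cam)
        noise_v = rng.normal(0.0, cfg.eye_noise_sd_deg, n_cam)
        components[eye] = {
            "h": {"tilt": np.zeros(n_cam), "conjugate": j, "noise": noise_h},
            "v": {"tilt": np.zeros(n_cam), "conjugate": np.zeros(n_cam), "noise": noise_v},
        }
        eyes[f"{eye}_h"] = UniformTrace(0.0, cfg.camera_rate, j + noise_h)
        eyes[f"{eye}_v"] = UniformTrace(0.0, cfg.camera_rate, noise_v)

    n_sen = int(round(cfg.duration_s * cfg.sensor_rate)) + 1
    t_sen = np.arange(n_sen) / cfg.sensor_rate
    sensor = rng.normal(0.0, cfg.sensor_noise_sd, n_sen)
    mean_signed = 0.5 * (size_l + size_r)
    for tk, s in zip(ev, mean_signed):
        lo = np.searchsorted(t_sen, tk - 5 * cfg.sensor_pulse_sigma_s)
        hi = np.searchsorted(t_sen, tk + 5 * cfg.sensor_pulse_sigma_s)
        sensor[lo:hi] += cfg.sensor_gain_per_deg * s * _gauss_pulse(
            t_sen[lo:hi], tk, cfg.sensor_pulse_sigma_s
        )
    # attempted rotations that did not trigger a saccade
    n_extra = rng.poisson(cfg.attempt_rate_hz * cfg.duration_s)
    for _ in range(n_extra):
        tk = rng.uniform(0.0, cfg.duration_s)
        amp = rng.choice([-1.0, 1.0]) * cfg.sensor_gain_per_deg * (
            cfg.saccade_min_deg + rng.gamma(cfg.saccade_size_shape, cfg.saccade_size_scale_deg)
        )
        lo = np.searchsorted(t_sen, tk - 5 * cfg.sensor_pulse_sigma_s)
        hi = np.searchsorted(t_sen, tk + 5 * cfg.sensor_pulse_sigma_s)
        sensor[lo:hi] += amp * _gauss_pulse(t_sen[lo:hi], tk, cfg.sensor_pulse_sigma_s)

    accel = np.tile([0.0, 0.0, 1.0], (n_sen, 1))
    gyro = np.full((n_sen, 3), 0.0)
    gyro[:, 2] = cfg.gyro_drift_dps
    imu = ImuRecord(
        accel=UniformTrace(0.0, cfg.sensor_rate, accel),
        gyro=UniformTrace(0.0, cfg.sensor_rate, gyro),
    )
    truth = GroundTruth(
        event_times=ev,
        dir_left=dir_l,
        dir_right=dir_r,
        size_left=size_l,
        size_right=size_r,
        components=components,
        drift_dps=cfg.gyro_drift_dps,
        variance_fraction={e: {"h": 0.0, "v": 0.0} for e in ("left", "right")},
        analysis_start_s=cfg.analysis_start_s,
    )
    return SyntheticSession(
        eyes=eyes,
        imu=imu,
        truth=truth,
        config=cfg,
        sensor=UniformTrace(0.0, cfg.sensor_rate, sensor),
    )


def simulate_stationary_gyro(
    duration_s: float,
    bias_dps: float = -1.60,
    noise_sd_dps: float = 5.0,
    rate: float = 190.0,
    seed: int = 0,
) -> UniformTrace:
    """Stationary yaw-rate recording: a constant bias plus white noise."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate)) + 1
    return UniformTrace(0.0, rate, bias_dps + rng.normal(0.0, noise_sd_dps, n))


@dataclass
class RectangleTrajectory:
    """Accelerating touchscreen target: x(t) = x0 + d (v t + a t^2)."""

    x0: float = -2.0  # cm, +/-2
    d: int = 1  # direction, -1 or +1
    v: float = 2.0  # cm/s
    a: float = 5.0  # cm/s^2
    stop_distance: float = 6.0  # cm traveled before the target stops
    display_rate: float = 60.0  # Hz

    def __post_init__(self) -> None:
        if self.d not in (-1, 1):
            raise ValueError("d must be -1 or +1")
        if self.stop_distance <= 0:
            raise ValueError("stop_distance must be positive")

    @property
    def stop_time(self) -> float:
        """Time at which the cumulative displacement reaches the stop
        distance."""
        v, a, dst = self.v, self.a, self.stop_distance
        if a == 0:
            return dst / v
        return (-v + math.sqrt(v * v + 4 * a * dst)) / (2 * a)

    @property
    def final_x(self) -> float:
        return self.x0 + self.d * self.stop_distance


def rectangle_position(traj: RectangleTrajectory, t: float, quantize: bool = True) -> float:
    """Target center position at time ``t`` since motion onset, cm.

    Time is quantized to display frames by default; the target stops once
    its displacement reaches the stop distance.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if quantize:
        t = math.floor(t * traj.display_rate) / traj.display_rate
    t = min(t, traj.stop_time)
    return traj.x0 + traj.d * (traj.v * t + traj.a * t * t)


def simulate_task_trials(
    n_trials: int,
    touch_noise_cm: float = 1.0,
    seed: int = 0,
    rect_width_cm: float = 4.0,
    **traj_kwargs,
):
    """Trial table for the visual motion tracking task.

    The target appears at x0 = -2 or +2 cm and moves left or right, all
    four combinations with equal probability; the touch position is the
    final target center plus Gaussian noise.  Returns a pandas DataFrame
    with initial/final positions, touch position (raw and normalized by
    the final position and rectangle width) and the left/right movement
    label (+1 = rightward).
    """
    import pandas as pd

    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_trials):
        x0 = float(rng.choice([-2.0, 2.0]))
        d = int(rng.choice([-1, 1]))
        traj = RectangleTrajectory(x0=x0, d=d, **traj_kwargs)
        final = traj.final_x
        touch = final + rng.normal(0.0, touch_noise_cm)
        rows.append(
            {
                "x0_cm": x0,
                "d": d,
                "final_x_cm": final,
                "touch_x_cm": touch,
                "touch_norm": (touch - final) / rect_width_cm,
                "label_right": int(d > 0),
            }
        )
    return pd.DataFrame(rows)
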