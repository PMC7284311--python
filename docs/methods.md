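# Methods

Precise definitions of the estimators implemented in `gazekit`. All
angles are degrees, velocities deg/s, times seconds.

## Frames and sign conventions

- World and head frames are right-handed: X forward, Y left, Z up.
- Head orientation relative to gravity is `head_in_space = Rx(roll) ·
  Ry(−pitch)` with pitch nose-up positive and roll right-ear-down
  positive. Pitch/roll are estimated from the head-mounted
  accelerometer as `pitch = atan2(ax, az)`, `roll = asin(ay)` after
  normalizing each sample by its vector norm; samples whose norm is far
  from 1 g (linear-acceleration contamination) are flagged NaN.
- Eye-in-head orientation is `Rz(azimuth) · Ry(−elevation)` applied
  inside an eye-axis placement frame describing how each orbit sits in
  the skull; the default placement elevates the optical axis 30° above
  the horizon for a level head and the two eyes mirror each other about
  the sagittal plane.
- At every public interface, horizontal eye position and head yaw are
  clockwise-positive viewed from above. The gyroscope z channel is a
  physical right-handed yaw rate, so analyses negate it (after drift
  subtraction) to obtain the clockwise-positive head yaw velocity.

## Signal preprocessing

- Eye position traces (60 Hz) are smoothed with a 3-point Gaussian
  kernel (weights 0.072, 0.855, 0.072).
- Velocities are central differences (`numpy.gradient`) on the smoothed
  trace.
- Cross-rate alignment uses linear interpolation; gaps longer than
  100 ms are not bridged (NaN).
- Gyro drift is the mean yaw-rate over an explicit stationary segment of
  at least 10 s (typically the first 20 s calibration period); head yaw
  position is the cumulative trapezoidal integral of the drift-corrected
  rate.
- The piezo sensor is band-passed 1–50 Hz with a zero-phase 2nd-order
  Butterworth filter and expressed in units of the noise SD measured on
  a recording without an animal attached.

## Saccade detection, sizing and pairing

- A saccade is a local maximum of eye speed `sqrt(vh² + vv²)` exceeding
  350 deg/s. Detections within ±50 ms are deduplicated greedily by
  descending peak speed.
- Amplitude: the trace is linearly oversampled to 5-ms resolution around
  the peak; the event extends outward while speed exceeds 50 deg/s,
  capped at ±35 ms; the signed horizontal amplitude is the position
  difference across those bounds. Events without a full ±100 ms margin
  inside the trace are left unsized.
- Binocular pairing greedily matches nearest left/right peak times
  within 2 frames at 60 Hz (33.3 ms); each event is used at most once.
  Conjugacy is the fraction of pairs whose horizontal peak velocities
  share a sign.

## Gaze stabilization (fixation phases)

- Fixation segments are the complement of the union of paired-saccade
  windows, each window padded by 2 camera frames so the velocity
  estimator's support never touches a saccade.
- Head yaw velocity is resampled to the eye timebase; over fixation
  samples,
  - **gain** is the negative ordinary-least-squares slope of eye
    velocity on head yaw velocity (1 = complete compensation), and
  - **MAD** is `mean |eye velocity + head velocity|`, the mean absolute
    deviation from the complete-compensation line.
- Binocular velocity-difference statistics (right minus left) are
  computed during near-upright posture (|pitch|, |roll| < 10°), split by
  the sign of head yaw velocity: median, unscaled median absolute
  deviation, and adjusted Fisher–Pearson skewness.

## Tilt-to-eye regression

- Features: pitch and roll sampled at 5 lags (−100, −75, −50, −25,
  0 ms) relative to each eye sample — 10 features per sample. Samples
  whose full window leaves the valid tilt record are dropped.
- Regressor: a multilayer perceptron with one hidden layer of 100 ReLU
  units (adam, early stopping on 10% of the training split, fixed
  random state), with per-fold feature standardization.
- Cross-validation: 5 contiguous temporal folds. Training samples
  within 100 ms of a test block are excluded so no training sample's
  feature window overlaps a test sample's window. R² = 1 − RSS/TSS is
  computed once on the concatenated held-out predictions.
- Decomposition: observed = prediction + residual holds exactly
  (residual stored as `y − prediction`). The interocular Pearson
  correlation of the predicted components is negative for the
  horizontal axis (non-conjugate tilt compensation) while the residual
  components correlate positively (conjugate saccade-and-fixate).

## Head-restrained sensor decoding

- Each saccade contributes a 9-sample sensor window at lags −50…+50 ms
  around its peak.
- Direction decoding: linear SVM (C = 1) on standardized windows;
  stratified 5-fold CV within mouse (or leave-one-mouse-out), with the
  AUC computed from pooled held-out decision values via the rank-based
  (Mann–Whitney) estimator.
- Size regression: ARD (automatic relevance determination) Bayesian
  linear regression on the same windows; held-out R² per mouse.
- Sensor engagement: fraction of saccades whose peak absolute sensor
  value within ±50 ms exceeds 3 noise SDs.

## Statistics

- Circular mean = argument of the mean resultant vector; circular SD =
  `sqrt(−2 ln R̄)` in degrees.
- Recording-level permutation test: the statistic is the L1 distance
  between condition means of per-recording averaged traces; labels are
  permuted across recordings; p = (k + 1)/(n + 1) including the
  observed labeling, so p is never exactly 0.
- ROC AUC is the tie-aware rank estimator.

## Synthetic sessions

The generator produces, deterministically from a seed: pitch/roll as
Ornstein–Uhlenbeck processes; a band-limited (3 Hz) OU head yaw
velocity plus a discrete yaw turn accompanying each saccade; per-eye
tilt-compensating components through a saturating compensation map;
conjugate slow phases at aVOR gain `g` between saccades; saccadic steps
drawn at a Poisson rate with a refractory period, conjugate across eyes
with probability `p_conj`, with eccentricity-dependent recentering that
keeps per-eye position and vergence stationary; Gaussian observation
noise on eyes (60 Hz) and IMU (190 Hz); accelerometer = rotated gravity
plus noise; gyro z = physical yaw rate plus a constant drift.
Ground truth stores event times/directions/sizes and the exact
tilt/conjugate/noise decomposition of every trace (their sum is
bit-exactly the observed trace). An optional variance-fraction target
rescales the conjugate-plus-noise residual so the tilt component
explains a requested share of the variance of a chosen axis.

Head-restrained sessions keep the saccade machinery, freeze the head,
and add a piezo trace with one Gaussian pulse per saccade (sign =
direction, amplitude proportional to size), extra attempted-rotation
pulses, and white noise. A stationary-gyro simulator (bias + white
noise) and a touchscreen-task trial simulator (accelerating rectangle,
`x(t) = x0 + d(vt + at²)`, balanced start positions/directions, noisy
touch endpoints) complete the suite.
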