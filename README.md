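# gazekit

Analysis of eye–head coupling in freely moving and head-restrained mice.

Freely moving mice move their eyes in two largely independent ways:

1. **Tilt compensation (non-conjugate).** Driven by the otolith-ocular
   reflex, the two eyes rotate in *opposite* horizontal directions (and
   together vertically) to counter head pitch and roll, keeping each
   eye's optical axis at a stable elevation relative to the ground
   plane. These movements are predictable from head tilt alone.
2. **Saccade-and-fixate (conjugate).** Coupled to head yaw turns, both
   eyes make rapid same-direction saccades (speed > 350°/s) followed by
   fixation phases in which the angular vestibulo-ocular reflex (aVOR)
   counter-rotates the eyes against ongoing head rotation with a gain
   below one.

`gazekit` implements the full analysis chain for quantifying this
decomposition, plus a synthetic-session generator with exact ground
truth so every stage can be validated without any recordings.

## Modules

| Module | Contents |
| --- | --- |
| `gazekit.geometry` | Eye-in-head / head-in-space rotation composition, gaze elevation, eye-axis placement, circular statistics, spherical visual-field coverage and binocular contours |
| `gazekit.signals` | Eye-trace smoothing, velocities, resampling with gap handling, accelerometer → pitch/roll, gyro drift estimation, yaw integration, zero-phase Butterworth filters, autocorrelation |
| `gazekit.saccades` | Velocity-threshold detection with deduplication, amplitude sizing, binocular pairing, conjugacy, event-triggered averages, eye/head gaze-shift components |
| `gazekit.tiltmodel` | Lagged pitch/roll design matrices, cross-validated nonlinear regression (contiguous folds with a guard gap), interocular correlation of predicted and residual components |
| `gazekit.stabilization` | Fixation segmentation, stabilization gain and MAD, velocity-difference statistics, permutation tests, ROC AUC |
| `gazekit.restrained` | Piezo-sensor preprocessing, saccade-aligned sensor windows, SVM direction decoding, ARD size regression |
| `gazekit.synthetic` | Session, sensor-session, stationary-gyro, and touchscreen-task simulators with bit-reproducible ground truth |
| `gazekit.pipeline` | High-level session analyses combining the above |
| `gazekit.io` | CSV/JSON table formats used by the CLI |

## Worked example

Generate a 10-minute synthetic session and recover its built-in
stabilization gain and saccade conjugacy:

```python
from gazekit.pipeline import detect_and_pair, stabilization_analysis
from gazekit.saccades import same_sign_fraction
from gazekit.synthetic import SimConfig, simulate_session

cfg = SimConfig(seed=1, duration_s=600.0)   # defaults: aVOR gain 0.53,
sess = simulate_session(cfg)                # conjugacy 0.94, drift -1.60 deg/s

# saccade detection (350 deg/s threshold) and binocular pairing
events, pairs = detect_and_pair(sess.eyes)
print("same-direction fraction:", same_sign_fraction(pairs))   # ~0.94

# fixation-phase stabilization: drift calibration, saccade removal,
# least-squares fit of eye velocity on head yaw velocity
res = stabilization_analysis(
    sess.eyes, sess.imu,
    calibration_segment=(0.0, cfg.calibration_s),
    analysis_start_s=cfg.analysis_start_s,
)
print("gain:", res["gain"])                                     # ~0.53
print("MAD (deg/s):", res["mad"])
```

Predict eye position from lagged head tilt (−100…0 ms pitch/roll
features, neural-network regressor, 5 contiguous CV folds with a 100-ms
guard gap):

```python
from gazekit.pipeline import tilt_regression_analysis

fits = tilt_regression_analysis(
    sess.eyes, sess.imu, axis="v", analysis_start_s=cfg.analysis_start_s
)
print("held-out R^2:", fits["left"].r2, fits["right"].r2)
```

The same analyses are available from the command line:

```bash
gazekit simulate --config sim.yaml --out session/
gazekit detect-saccades --eyes session/eyes.csv --out events.csv
gazekit stabilize --eyes session/eyes.csv --imu session/imu.csv --out stab.json
gazekit fit-tilt --eyes session/eyes.csv --imu session/imu.csv --start 25 --out tilt.json
gazekit gaze-angles --eyes session/eyes.csv --imu session/imu.csv --out gaze.csv
gazekit visual-field --eyes session/eyes.csv --imu session/imu.csv --out vf.json
gazekit restrained --sensor sensor.csv --eyes eyes.csv --noise noise.csv --out res.json
```

`sim.yaml` holds `SimConfig` fields (a `seed` is mandatory), e.g.:

```yaml
seed: 1
duration_s: 600.0
avor_gain: 0.53
```

## Tests

```bash
python -m pytest
```

The suite (~2 minutes) covers unit behavior, seeded property-based
tests, end-to-end pipeline recovery on synthetic sessions, the CLI, and
the acceptance targets at their stated tolerances
(`tests/test_acceptance.py`).

## Conventions

- Right-handed frames, X forward / Y left / Z up; pitch is nose-up
  positive, roll is right-ear-down positive.
- Horizontal eye positions and head yaw are reported clockwise-positive
  as viewed from above (so a rightward rotation is positive); vertical
  eye positions are upward-positive.
- Eye cameras sample at 60 Hz, the head IMU and piezo sensor at 190 Hz.
- See `docs/methods.md` for the precise estimator definitions.
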