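"""Geometry: rotations, gaze elevation, circular stats, visual fields."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from gazekit.geometry import (
    EyeAxisPlacement,
    EyeOrbitAngles,
    GimbalLockError,
    HeadTilt,
    binocular_map_and_contours,
    circular_stats,
    compose_gaze_rotation,
    elevation_to_horizontal,
    eye_axis_angle,
    gaze_elevation_series,
    gaze_vector,
    rotation_about_principal_axis,
    visual_field_coverage,
)

angles = st.floats(-80.0, 80.0)
tilt_angles = st.floats(-60.0, 60.0)


def scipy_gaze(orbit, placement, tilt):
    """Independent oracle for the composed gaze rotation."""
    r_head = Rotation.from_euler("x", tilt.roll, degrees=True) * Rotation.from_euler(
        "y", -tilt.pitch, degrees=True
    )
    r_eh = Rotation.from_euler("z", placement.azimuth, degrees=True) * Rotation.from_euler(
        "y", -placement.elevation, degrees=True
    )
    r_eo = Rotation.from_euler("z", orbit.eyeh, degrees=True) * Rotation.from_euler(
        "y", -orbit.eyev, degrees=True
    )
    return (r_head * r_eh * r_eo).as_matrix()


class TestRotations:
    def test_zero_rotation_is_identity(self):
        assert np.allclose(rotation_about_principal_axis("pitch", 0.0), np.eye(3))

    def test_full_turn_is_identity(self):
        assert np.allclose(rotation_about_principal_axis("dorsal", 360.0), np.eye(3), atol=1e-9)

    def test_inverse_composition(self):
        r = rotation_about_principal_axis("roll", 30.0)
        rinv = rotation_about_principal_axis("roll", -30.0)
        assert np.allclose(r @ rinv, np.eye(3), atol=1e-12)

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            rotation_about_principal_axis("roll", np.nan)

    @settings(derandomize=True, max_examples=50)
    @given(eyeh=angles, eyev=angles, pitch=tilt_angles, roll=tilt_angles)
    def test_orthonormal_det_one(self, eyeh, eyev, pitch, roll):
        R = compose_gaze_rotation(
            EyeOrbitAngles(eyeh, eyev), EyeAxisPlacement.default("left"), HeadTilt(pitch, roll)
        )
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(R) - 1.0) < 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(eyeh=angles, eyev=angles, pitch=tilt_angles, roll=tilt_angles)
    def test_matches_scipy_oracle(self, eyeh, eyev, pitch, roll):
        orbit = EyeOrbitAngles(eyeh, eyev)
        placement = EyeAxisPlacement.alternate("right")
        tilt = HeadTilt(pitch, roll)
        R = compose_gaze_rotation(orbit, placement, tilt)
        assert np.allclose(R, scipy_gaze(orbit, placement, tilt), atol=1e-12)

    def test_identity_configuration(self):
        R = compose_gaze_rotation(
            EyeOrbitAngles(0, 0), EyeAxisPlacement(side="left", azimuth=0, elevation=0), HeadTilt(0, 0)
        )
        assert np.allclose(R, np.eye(3), atol=1e-12)

    def test_gimbal_guard(self):
        with pytest.raises(GimbalLockError):
            compose_gaze_rotation(
                EyeOrbitAngles(0, 0), EyeAxisPlacement.default("left"), HeadTilt(89.5, 0)
            )


class TestGazeVector:
    def test_identity_gives_base_vector(self):
        v = gaze_vector(np.eye(3))
        assert np.allclose(v, [1.0, 0.0, 0.0])

    def test_nose_up_90_points_up(self):
        R = compose_gaze_rotation(
            EyeOrbitAngles(0, 0), EyeAxisPlacement(side="left", azimuth=0, elevation=0), HeadTilt(88.9, 0)
        )
        v = gaze_vector(R)
        assert elevation_to_horizontal(v) == pytest.approx(88.9, abs=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            gaze_vector(np.eye(3) * 1.1)


class TestElevation:
    def test_horizontal_vector_zero(self):
        assert elevation_to_horizontal(np.array([1.0, 0.0, 0.0])) == pytest.approx(0.0)

    def test_vertical_up_90(self):
        assert elevation_to_horizontal(np.array([0.0, 0.0, 1.0])) == pytest.approx(90.0)

    def test_level_head_default_placement_30(self):
        R = compose_gaze_rotation(
            EyeOrbitAngles(0, 0), EyeAxisPlacement.default("left"), HeadTilt(0, 0)
        )
        assert elevation_to_horizontal(gaze_vector(R)) == pytest.approx(30.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            elevation_to_horizontal(np.zeros(3))

    @settings(derandomize=True, max_examples=50)
    @given(eyeh=angles, eyev=angles, pitch=tilt_angles, roll=tilt_angles, yaw=st.floats(-180, 180))
    def test_yaw_invariance(self, eyeh, eyev, pitch, roll, yaw):
        """Elevation is invariant to rotations about the vertical axis."""
        R = compose_gaze_rotation(
            EyeOrbitAngles(eyeh, eyev), EyeAxisPlacement.default("right"), HeadTilt(pitch, roll)
        )
        Rz = rotation_about_principal_axis("dorsal", yaw)
        a = elevation_to_horizontal(gaze_vector(R))
        b = elevation_to_horizontal(gaze_vector(Rz @ R))
        assert a == pytest.approx(b, abs=1e-9)


class TestEyeAxisAngle:
    def test_level_head_30(self):
        assert eye_axis_angle(EyeAxisPlacement.default("left"), HeadTilt(0, 0)) == pytest.approx(30.0)

    def test_zero_placement_zero(self):
        assert eye_axis_angle(
            EyeAxisPlacement(side="left", azimuth=0, elevation=0), HeadTilt(0, 0)
        ) == pytest.approx(0.0)

    def test_tilted_head_matches_bruteforce(self):
        placement = EyeAxisPlacement.default("left")
        tilt = HeadTilt(-40.0, 25.0)
        expected = np.degrees(
            np.arcsin(scipy_gaze(EyeOrbitAngles(0, 0), placement, tilt)[2, 0])
        )
        assert eye_axis_angle(placement, tilt) == pytest.approx(float(expected), abs=1e-9)


class TestGazeElevationSeries:
    def test_matches_per_frame_composition(self):
        rng = np.random.default_rng(0)
        n = 200
        eyeh = rng.uniform(-30, 30, n)
        eyev = rng.uniform(-30, 30, n)
        pitch = rng.uniform(-60, 60, n)
        roll = rng.uniform(-60, 60, n)
        placement = EyeAxisPlacement.default("left")
        got = gaze_elevation_series(eyeh, eyev, pitch, roll, placement)
        for i in range(0, n, 17):
            R = compose_gaze_rotation(
                EyeOrbitAngles(eyeh[i], eyev[i]), placement, HeadTilt(pitch[i], roll[i])
            )
            assert got[i] == pytest.approx(elevation_to_horizontal(gaze_vector(R)), abs=1e-9)

    def test_gimbal_samples_become_nan(self):
        placement = EyeAxisPlacement.default("left")
        out = gaze_elevation_series(
            np.zeros(2), np.zeros(2), np.array([0.0, 89.5]), np.zeros(2), placement
        )
        assert np.isfinite(out[0]) and np.isnan(out[1])


class TestCircularStats:
    def test_constant_angles(self):
        mean, sd = circular_stats([17.0] * 10)
        assert mean == pytest.approx(17.0)
        assert sd == pytest.approx(0.0, abs=1e-5)

    def test_wraparound_mean(self):
        mean, _ = circular_stats([359.0, 1.0])
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_wrapped_normal_recovery(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(30.0, 10.0, 10_000)
        mean, sd = circular_stats(draws)
        assert mean == pytest.approx(30.0, abs=0.5)
        assert sd == pytest.approx(10.0, abs=0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_stats([])


class TestTiltCompensationNarrowsGaze(object):
    def test_gaze_sd_below_axis_sd(self, session600):
        """With tilt compensation active, gaze elevation varies less than
        the eye-axis elevation over the same session."""
        from gazekit.signals import pitch_roll_from_accel, resample_linear

        sess = session600
        tilt = pitch_roll_from_accel(sess.imu)
        base = sess.eyes["left_h"]
        pr = resample_linear(tilt.times(), tilt.values, base.times())
        placement = EyeAxisPlacement.default("left")
        # stored horizontal positions are CW-positive; geometry is CCW
        gaze = gaze_elevation_series(
            -sess.eyes["left_h"].values, sess.eyes["left_v"].values, pr[:, 0], pr[:, 1], placement
        )
        axis = gaze_elevation_series(
            np.zeros(base.n), np.zeros(base.n), pr[:, 0], pr[:, 1], placement
        )
        ok = np.isfinite(gaze) & np.isfinite(axis)
        _, sd_gaze = circular_stats(gaze[ok])
        _, sd_axis = circular_stats(axis[ok])
        assert sd_gaze < sd_axis


def _level_gaze(side):
    R = compose_gaze_rotation(
        EyeOrbitAngles(0, 0), EyeAxisPlacement.default(side), HeadTilt(0, 0)
    )
    return gaze_vector(R)


class TestVisualField:
    def test_single_frame_half_sphere(self):
        vf = visual_field_coverage(np.array([[0.0, 0.0, 1.0]]), 4.0, point_radius_cm=1e9)
        frac = np.mean(vf.counts > 0)
        assert frac == pytest.approx(0.5, abs=0.05)
        assert vf.counts.min() >= 0 and vf.counts.max() <= 1

    def test_zenith_visible_to_both_eyes(self):
        for side in ("left", "right"):
            vf = visual_field_coverage(_level_gaze(side)[None, :], 10.0, point_radius_cm=1e9)
            zen_row = np.argmin(np.abs(vf.elevations - 90.0))
            assert np.all(vf.counts[zen_row] > 0)

    def test_two_frame_normalization(self):
        g = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        vf = visual_field_coverage(g, 10.0, point_radius_cm=1e9)
        zen_row = np.argmin(np.abs(vf.elevations - 90.0))
        assert np.allclose(vf.counts[zen_row], 0.5)

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(40, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        a = visual_field_coverage(g, 10.0)
        b = visual_field_coverage(g[::-1], 10.0)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            visual_field_coverage(np.empty((0, 3)), 4.0)

    def test_binocular_sum_and_contours(self):
        left = visual_field_coverage(_level_gaze("left")[None, :], 6.0, point_radius_cm=1e9)
        right = visual_field_coverage(_level_gaze("right")[None, :], 6.0, point_radius_cm=1e9)
        summed, contours = binocular_map_and_contours(left, right)
        assert summed.min() >= 0.0 and summed.max() <= 2.0
        # frontal overlap exists: some cells are seen by both eyes
        assert np.any(summed > 1.5)
        assert len(contours["left"]) >= 1 and len(contours["right"]) >= 1

    def test_empty_side_has_no_contour(self):
        left = visual_field_coverage(_level_gaze("left")[None, :], 10.0, point_radius_cm=1e9)
        zeros = visual_field_coverage(_level_gaze("right")[None, :], 10.0, point_radius_cm=1e9)
        zeros.counts[:] = 0.0
        summed, contours = binocular_map_and_contours(left, zeros)
        assert np.array_equal(summed, left.counts)
        assert contours["right"] == []
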