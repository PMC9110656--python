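"""Tests of orientation estimation, gravity removal and segmentation."""

import math

import numpy as np
import pandas as pd
import pytest

from aratscore import (
    IMURecording,
    SimulationConfig,
    estimate_orientation,
    remove_gravity,
    segment_tasks,
)
from aratscore.preprocessing import OrientationTrajectory
from aratscore.quaternions import integrate_gyro, quats_to_matrices
from aratscore.simulate import _render_sensor_frame, _task_kinematics

FS = 50.0
G = 9.81


def _static_recording(n=500, accel=(0.0, 0.0, G), gyro=(0.0, 0.0, 0.0)):
    return IMURecording(
        timestamps=np.arange(n) / FS,
        accel=np.tile(accel, (n, 1)),
        gyro=np.tile(gyro, (n, 1)),
    )


def _inclination_error_deg(quats: np.ndarray) -> np.ndarray:
    """Angle between the estimated sensor z-axis in the world frame and the
    true vertical, for a sensor whose true orientation is identity."""
    R = quats_to_matrices(quats)
    cosang = np.clip(R[:, 2, 2], -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


class TestEstimateOrientation:
    def test_static_identity(self):
        rec = _static_recording()
        ori = estimate_orientation(rec, correction_gain=0.02)
        assert np.all(_inclination_error_deg(ori.quats) < 1e-6)

    def test_pure_vertical_rotation_matches_closed_form(self):
        """Constant rotation about the world vertical integrates to the
        axis-angle quaternion exp(omega*t/2) within 0.5 degrees over 30 s."""
        omega = 0.8  # rad/s about z
        n = int(30 * FS)
        rec = _static_recording(n=n, gyro=(0.0, 0.0, omega))
        ori = estimate_orientation(rec, correction_gain=0.02)
        t = np.arange(n) / FS
        expected = np.column_stack(
            [np.cos(omega * t / 2), np.zeros(n), np.zeros(n), np.sin(omega * t / 2)]
        )
        dot = np.abs(np.sum(ori.quats * expected, axis=1))
        angle_err = 2 * np.degrees(np.arccos(np.clip(dot, -1, 1)))
        assert np.max(angle_err) < 0.5

    def test_gyro_bias_corrected_by_accelerometer(self):
        """With a 0.01 rad/s horizontal-axis bias, gain 0.05 keeps the
        inclination error under 2 degrees over 60 s while gain 0 drifts
        along the analytic line bias * t."""
        bias = 0.01
        n = int(60 * FS)
        rec = _static_recording(n=n, gyro=(bias, 0.0, 0.0))
        corrected = estimate_orientation(rec, correction_gain=0.05)
        assert np.max(_inclination_error_deg(corrected.quats)) < 2.0
        drifting = estimate_orientation(rec, correction_gain=0.0)
        err = _inclination_error_deg(drifting.quats)
        t = np.arange(n) / FS
        expected = np.degrees(bias * t)
        np.testing.assert_allclose(err, expected, atol=0.05)

    def test_unit_norm_quaternions(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        omega, a_world = _task_kinematics(2, cfg, rng)
        accel, gyro, _ = _render_sensor_frame(omega, a_world, cfg, rng)
        rec = IMURecording(np.arange(len(accel)) / FS, accel, gyro)
        ori = estimate_orientation(rec)
        np.testing.assert_allclose(np.linalg.norm(ori.quats, axis=1), 1.0, atol=1e-6)

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            estimate_orientation(_static_recording(), correction_gain=1.5)


class TestRemoveGravity:
    def test_static_any_orientation_cancels_exactly(self):
        """With the exact orientation supplied, a static tilted sensor's
        linear acceleration is zero to 1e-9."""
        angle = 0.7  # rad about x
        q = np.array([math.cos(angle / 2), math.sin(angle / 2), 0.0, 0.0])
        n = 200
        # gravity in sensor frame: R^T (0,0,g)
        R = quats_to_matrices(q[None])[0]
        accel = np.tile(R.T @ np.array([0, 0, G]), (n, 1))
        rec = IMURecording(np.arange(n) / FS, accel, np.zeros((n, 3)))
        ori = OrientationTrajectory(np.tile(q, (n, 1)))
        lin = remove_gravity(rec, ori)
        assert np.max(np.linalg.norm(lin, axis=1)) < 1e-9

    def test_level_sensor_recovers_sinusoidal_acceleration(self):
        n = 500
        t = np.arange(n) / FS
        a_true = 1.5 * np.sin(2 * np.pi * 2.0 * t)
        accel = np.column_stack([a_true, np.zeros(n), np.full(n, G)])
        rec = IMURecording(t, accel, np.zeros((n, 3)))
        ori = OrientationTrajectory(np.tile([1.0, 0, 0, 0], (n, 1)))
        lin = remove_gravity(rec, ori)
        np.testing.assert_allclose(lin[:, 0], a_true, atol=1e-6)
        np.testing.assert_allclose(lin[:, 1:], 0.0, atol=1e-6)

    def test_45_degree_tilt_hand_computed(self):
        """Sensor tilted 45 degrees about x reads (0, g sin45, g cos45);
        rotation plus subtraction returns ~zero."""
        angle = math.pi / 4
        q = np.array([math.cos(angle / 2), math.sin(angle / 2), 0.0, 0.0])
        n = 100
        accel = np.tile([0.0, G * math.sin(angle), G * math.cos(angle)], (n, 1))
        rec = IMURecording(np.arange(n) / FS, accel, np.zeros((n, 3)))
        lin = remove_gravity(rec, OrientationTrajectory(np.tile(q, (n, 1))))
        np.testing.assert_allclose(lin, 0.0, atol=1e-9)

    def test_length_mismatch_rejected(self):
        rec = _static_recording(n=100)
        ori = OrientationTrajectory(np.tile([1.0, 0, 0, 0], (50, 1)))
        with pytest.raises(ValueError):
            remove_gravity(rec, ori)


class TestRoundTrip:
    def test_session_round_trip_rmse(self):
        """Synthesize a session with known world-frame acceleration, add
        gravity through a known orientation trajectory, then recover the
        linear acceleration via the full filter: RMSE < 0.1 m/s^2."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(3)
        blocks_o, blocks_a = [], []
        for score in [3, 1, 2, 0, 3, 2, 1, 3, 2]:
            o, a = _task_kinematics(score, cfg, rng)
            blocks_o += [o, np.zeros((100, 3))]
            blocks_a += [a, np.zeros((100, 3))]
        omega = np.vstack(blocks_o)
        a_world = np.vstack(blocks_a)
        accel, gyro, _ = _render_sensor_frame(omega, a_world, cfg, rng)
        rec = IMURecording(np.arange(len(accel)) / FS, accel, gyro)
        ori = estimate_orientation(rec, correction_gain=0.02)
        lin = remove_gravity(rec, ori)
        rmse = float(np.sqrt(np.mean((lin - a_world) ** 2)))
        assert rmse < 0.1


def _annotated_recording(n_seconds=120.0):
    n = int(n_seconds * FS)
    rng = np.random.default_rng(9)
    accel = np.tile([0.0, 0.0, G], (n, 1)) + rng.normal(0, 0.01, (n, 3))
    rec = IMURecording(np.arange(n) / FS, accel, np.zeros((n, 3)))
    lin = rng.normal(0, 0.01, (n, 3))
    return rec, lin


class TestSegmentTasks:
    def _ann(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "subject", "session", "arm", "domain", "task",
                "t_start", "t_stop", "score", "attempted",
            ],
        )

    def test_75s_annotation_truncated_to_60s(self):
        rec, lin = _annotated_recording(100.0)
        ann = self._ann([("S01", 1, "more_affected", "grasp", 1, 5.0, 80.0, 2, True)])
        (seg,) = segment_tasks(rec, lin, ann)
        assert seg.n_samples == 3000
        assert seg.duration_s == pytest.approx(60.0)

    def test_unattempted_substituted_with_10s_still_window(self):
        rec, lin = _annotated_recording()
        ann = self._ann([("S01", 1, "more_affected", "grasp", 1, 0.0, 0.0, 3, False)])
        (seg,) = segment_tasks(rec, lin, ann)
        assert seg.duration_s == pytest.approx(10.0)
        assert seg.score == 0
        assert seg.substituted

    def test_two_second_annotation_has_100_samples(self):
        rec, lin = _annotated_recording()
        ann = self._ann([("S01", 1, "more_affected", "grip", 7, 2.0, 4.0, 1, True)])
        (seg,) = segment_tasks(rec, lin, ann)
        assert seg.n_samples == 100

    def test_one_segment_per_annotation_row(self, small_dataset, small_segments):
        assert len(small_segments) == len(small_dataset.annotations)
        assert max(s.n_samples for s in small_segments) <= 3000

    def test_inverted_interval_rejected(self):
        rec, lin = _annotated_recording()
        ann = self._ann([("S01", 1, "more_affected", "grasp", 1, 4.0, 2.0, 1, True)])
        with pytest.raises(ValueError, match="t_stop"):
            segment_tasks(rec, lin, ann)

    def test_out_of_span_annotation_rejected(self):
        rec, lin = _annotated_recording(20.0)
        ann = self._ann([("S01", 1, "more_affected", "grasp", 1, 5.0, 30.0, 1, True)])
        with pytest.raises(ValueError, match="span"):
            segment_tasks(rec, lin, ann)
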