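"""Synthetic ARAT-session generator.

Emulates the statistical structure of two-wrist IMU recordings of the
Action Research Arm Test so that preprocessing, feature extraction and
classification can be exercised end to end without clinical data:

* a latent per-subject, per-arm severity theta in [0, 1] maps to ordinal
  task scores through three ordered thresholds with Gaussian rating noise;
* each attempted task is a sequence of minimum-jerk reach pulses whose
  amplitude and tempo degrade with the score, with a band-limited tremor
  sinusoid (amplitude decreasing with score) superimposed;
* gravity enters the accelerometer through a synthetic orientation
  trajectory (slow wrist tilt integrated from the generated angular
  velocity), so gravity removal downstream is genuinely exercised;
* the less affected arm is skewed toward score 3; tasks go missing with a
  small probability; no task exceeds the 60 s cap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .data import ANNOTATION_COLUMNS, IMURecording, recording_to_frame
from .quaternions import integrate_gyro, quats_to_matrices
from .registry import ARMS, build_task_registry

# reach tempo and relative amplitude per score (score 0 is stationary);
# lower scores move more slowly and over a smaller range
_REACH_PERIOD_S = {1: 3.0, 2: 2.5, 3: 1.5}
_AMPLITUDE_SCALE = {1: 0.35, 2: 0.7, 3: 1.0}
_TILT_AMP_RAD = 0.30  # slow wrist tilt amplitude
_TILT_FREQ_HZ = 0.2
_GYRO_PER_ACCEL_TREMOR = 0.4  # rad/s of gyro tremor per m/s^2 of accel tremor
_REST_S = 2.0  # inter-task rest
_LEAD_IN_S = 3.0  # stationary lead-in at recording start
_MISSING_BLOCK_S = 10.0  # stationary block inserted for unattempted tasks


def draw_task_score(
    severity: float,
    thresholds: tuple[float, float, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> int:
    """Ordinal score from a latent ordered-threshold model.

    The latent ability is ``1 - severity + eps`` with ``eps ~ N(0,
    noise_sd)``; the score is the number of thresholds the ability
    exceeds, hence in {0, 1, 2, 3}.
    """
    t = tuple(thresholds)
    if len(t) != 3 or not (t[0] < t[1] < t[2]):
        raise ValueError("thresholds must be 3 strictly increasing values")
    ability = 1.0 - float(severity) + rng.normal(0.0, noise_sd)
    return int(sum(ability > th for th in t))


def _minimum_jerk_pulses(n: int, amplitude: float, period_s: float, fs: float):
    """Concatenated alternating minimum-jerk point-to-point movements.

    Returns (accel, vel) arrays of length n for 1-D motion of range
    ``amplitude`` metres per reach of duration ``period_s``.
    """
    t = np.arange(n) / fs
    tau = (t % period_s) / period_s
    direction = 1.0 - 2.0 * (np.floor(t / period_s).astype(int) % 2)
    a = (amplitude / period_s**2) * (60 * tau - 180 * tau**2 + 120 * tau**3)
    v = (amplitude / period_s) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return direction * a, direction * v


def _task_kinematics(
    score: int, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """True sensor-frame angular velocity and world-frame movement
    acceleration for one task, before sensor noise.  Returns (omega (n,3)
    rad/s, a_world (n,3) m/s^2)."""
    fs = config.sampling_hz
    if score == 0:
        n = int(round(config.duration_by_score[0] * fs))
        return np.zeros((n, 3)), np.zeros((n, 3))

    duration = float(np.clip(config.duration_by_score[score], 1.5, 60.0))
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    amp = config.reach_amplitude_m * _AMPLITUDE_SCALE[score]
    period = _REACH_PERIOD_S[score]
    a_reach, v_reach = _minimum_jerk_pulses(n, amp, period, fs)

    a_world = np.zeros((n, 3))
    a_world[:, 0] = a_reach
    # secondary, smaller transverse component with its own phase
    a_y, _ = _minimum_jerk_pulses(n, 0.4 * amp, 1.3 * period, fs)
    a_world[:, 1] = a_y

    trem_amp = config.tremor_amp_by_score[score]
    if trem_amp > 0:
        f = rng.uniform(*config.tremor_band_hz)
        ph = rng.uniform(0.0, 2 * math.pi, size=2)
        a_world[:, 0] += trem_amp * np.sin(2 * math.pi * f * t + ph[0])
        a_world[:, 1] += 0.6 * trem_amp * np.sin(2 * math.pi * f * t + ph[1])

    omega = np.zeros((n, 3))
    tilt_amp = _TILT_AMP_RAD * _AMPLITUDE_SCALE[score]
    ph_tilt = rng.uniform(0.0, 2 * math.pi)
    omega[:, 0] = (
        tilt_amp * 2 * math.pi * _TILT_FREQ_HZ
        * np.cos(2 * math.pi * _TILT_FREQ_HZ * t + ph_tilt)
    )
    # forearm rotation tied to the reach velocity profile
    omega[:, 2] = 2.0 * v_reach
    if trem_amp > 0:
        f_g = rng.uniform(*config.tremor_band_hz)
        omega[:, 1] += (
            _GYRO_PER_ACCEL_TREMOR * trem_amp
            * np.sin(2 * math.pi * f_g * t + rng.uniform(0.0, 2 * math.pi))
        )
    return omega, a_world


def _render_sensor_frame(
    omega: np.ndarray,
    a_world: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the true angular velocity to an orientation trajectory and
    express specific force in the sensor frame; add sensor noise.

    Returns (accel_sensor, gyro_sensor, quaternions)."""
    dt = 1.0 / config.sampling_hz
    quats = integrate_gyro(omega, dt)
    R = quats_to_matrices(quats)  # sensor -> world
    g_vec = np.array([0.0, 0.0, 9.81])
    # specific force in sensor frame: R^T (a_world + g)
    f_sensor = np.einsum("nji,nj->ni", R, a_world + g_vec)
    accel = f_sensor + rng.normal(0.0, config.noise_sd_accel, f_sensor.shape)
    gyro = omega + rng.normal(0.0, config.noise_sd_gyro, omega.shape)
    return accel, gyro, quats


def synthesize_task_signal(
    score: int, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """6-channel sensor stream for a single task at the given score.

    Returns ``(accel, gyro)``: sensor-frame specific force (gravity
    included) and angular velocity at ``config.sampling_hz``.  Score 0
    yields a near-stationary noise-only signal of
    ``duration_by_score[0]`` seconds.
    """
    if score not in (0, 1, 2, 3):
        raise ValueError("score must be in {0,1,2,3}")
    omega, a_world = _task_kinematics(score, config, rng)
    accel, gyro, _ = _render_sensor_frame(omega, a_world, config, rng)
    return accel, gyro


@dataclass
class SimulatedDataset:
    """Recordings plus annotations and ground truth from one simulation."""

    recordings: dict[tuple[str, int, str], IMURecording]
    annotations: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a full cohort: every subject, session and arm performs the
    19-task registry in order, with stationary rest between tasks.

    Annotations carry start/stop times on the recording clock; unattempted
    tasks (probability ``missing_rate``) appear with ``attempted=False``
    over a stationary 10 s block and a ground-truth score of 0.
    """
    rng = np.random.default_rng(config.seed)
    registry = build_task_registry(config.domain_counts)
    fs = config.sampling_hz

    severity: dict[tuple[str, str], float] = {}
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    for subj in subjects:
        m_mean, m_sd = config.severity_more_affected
        l_mean, l_sd = config.severity_less_affected
        severity[(subj, "more_affected")] = float(
            np.clip(rng.normal(m_mean, m_sd), 0.0, 1.0)
        )
        severity[(subj, "less_affected")] = float(
            np.clip(rng.normal(l_mean, l_sd), 0.0, 1.0)
        )

    recordings: dict[tuple[str, int, str], IMURecording] = {}
    ann_rows: list[dict] = []
    gt_rows: list[dict] = []

    n_rest = int(round(_REST_S * fs))
    n_lead = int(round(_LEAD_IN_S * fs))
    n_missing = int(round(_MISSING_BLOCK_S * fs))

    for subj in subjects:
        for session in range(1, config.sessions_per_subject + 1):
            for arm in ARMS:
                theta = severity[(subj, arm)]
                omegas = [np.zeros((n_lead, 3))]
                accels_w = [np.zeros((n_lead, 3))]
                cursor = n_lead
                for info in registry:
                    attempted = bool(rng.uniform() >= config.missing_rate)
                    if attempted:
                        score = draw_task_score(
                            theta, config.score_thresholds, config.score_noise_sd, rng
                        )
                        omega, a_world = _task_kinematics(score, config, rng)
                    else:
                        score = 0
                        omega = np.zeros((n_missing, 3))
                        a_world = np.zeros((n_missing, 3))
                    n_task = omega.shape[0]
                    ann_rows.append(
                        {
                            "subject": subj,
                            "session": session,
                            "arm": arm,
                            "domain": info.domain,
                            "task": info.task,
                            "t_start": cursor / fs,
                            "t_stop": (cursor + n_task) / fs,
                            "score": score,
                            "attempted": attempted,
                        }
                    )
                    gt_rows.append(
                        {
                            "subject": subj,
                            "session": session,
                            "arm": arm,
                            "domain": info.domain,
                            "task": info.task,
                            "score": score,
                            "attempted": attempted,
                        }
                    )
                    omegas.append(omega)
                    accels_w.append(a_world)
                    cursor += n_task
                    omegas.append(np.zeros((n_rest, 3)))
                    accels_w.append(np.zeros((n_rest, 3)))
                    cursor += n_rest
                omega_all = np.vstack(omegas)
                a_world_all = np.vstack(accels_w)
                accel, gyro, _ = _render_sensor_frame(
                    omega_all, a_world_all, config, rng
                )
                n = accel.shape[0]
                recordings[(subj, session, arm)] = IMURecording(
                    timestamps=np.arange(n) / fs,
                    accel=accel,
                    gyro=gyro,
                    subject=subj,
                    session=session,
                    arm=arm,
                )

    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    ground_truth = pd.DataFrame(
        gt_rows,
        columns=["subject", "session", "arm", "domain", "task", "score", "attempted"],
    )
    return SimulatedDataset(
        recordings=recordings,
        annotations=annotations,
        ground_truth=ground_truth,
        config=config,
    )


def recording_filename(subject: str, session: int, arm: str) -> str:
    return f"{subject}_ses{session}_{arm}.csv"


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write recordings (one columnar CSV each), annotations.csv,
    ground_truth.csv and a meta.json config snapshot under ``outdir``."""
    outdir = Path(outdir)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for (subj, session, arm), rec in dataset.recordings.items():
        recording_to_frame(rec).to_csv(
            rec_dir / recording_filename(subj, session, arm), index=False
        )
    dataset.annotations.to_csv(outdir / "annotations.csv", index=False)
    dataset.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    if dataset.config is not None:
        meta = {"config": dataset.config.to_dict(), "seed": dataset.config.seed}
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
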