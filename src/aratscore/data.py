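"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of the per-recording signal files
RECORDING_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]

#: columns of the task-annotation table
ANNOTATION_COLUMNS = [
    "subject",
    "session",
    "arm",
    "domain",
    "task",
    "t_start",
    "t_stop",
    "score",
    "attempted",
]


@dataclass
class IMURecording:
    """One continuous 6-axis wrist recording at a nominal 50 Hz.

    ``accel`` is specific force in the sensor frame (movement acceleration
    plus gravity), in m/s^2; ``gyro`` is angular velocity in the sensor
    frame, in rad/s.  Timestamps are seconds relative to recording start.
    """

    timestamps: np.ndarray
    accel: np.ndarray  # (n, 3)
    gyro: np.ndarray  # (n, 3)
    subject: str = ""
    session: int = 1
    arm: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.timestamps)
        if n == 0:
            raise ValueError("recording is empty")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must be (n, 3) arrays matching timestamps")
        dt = np.diff(self.timestamps)
        if n > 1 and not np.all(dt > 0):
            raise ValueError("timestamps must be strictly increasing")
        if n > 1:
            med = float(np.median(dt))
            if not (0.9 / 50.0 <= med <= 1.1 / 50.0):
                raise ValueError(
                    f"median sampling interval {med:.4g}s departs >10% from 1/50s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def sampling_hz(self) -> float:
        if self.n_samples < 2:
            return 50.0
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class TaskSegment:
    """One task execution: gravity-free world-frame linear acceleration
    (m/s^2) plus sensor-frame angular velocity (rad/s), with metadata and
    the clinical 0-3 score.  ``substituted`` marks unattempted tasks for
    which a 10 s non-moving window was inserted in place of real data.
    """

    linear_accel: np.ndarray  # (n, 3), world frame, gravity removed
    gyro: np.ndarray  # (n, 3), sensor frame
    subject: str
    session: int
    arm: str
    domain: str
    task: int
    score: int
    substituted: bool = False
    sampling_hz: float = 50.0

    def __post_init__(self) -> None:
        self.linear_accel = np.asarray(self.linear_accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.linear_accel.ndim != 2 or self.linear_accel.shape[1] != 3:
            raise ValueError("linear_accel must be (n, 3)")
        if self.gyro.shape != self.linear_accel.shape:
            raise ValueError("gyro must match linear_accel shape")
        n = self.linear_accel.shape[0]
        if n == 0:
            raise ValueError("segment is empty")
        if self.duration_s > 60.0 + 1e-9:
            raise ValueError("segment exceeds the 60 s cap")
        if self.score not in (0, 1, 2, 3):
            raise ValueError("score must be in {0,1,2,3}")
        if self.substituted and self.score != 0:
            raise ValueError("substituted segments must carry score 0")

    @property
    def n_samples(self) -> int:
        return self.linear_accel.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_hz

    @property
    def channels(self) -> np.ndarray:
        """(n, 6) array: acc_x..z then gyr_x..z."""
        return np.hstack([self.linear_accel, self.gyro])


def recording_to_frame(rec: IMURecording) -> pd.DataFrame:
    data = np.column_stack([rec.timestamps, rec.accel, rec.gyro])
    return pd.DataFrame(data, columns=RECORDING_COLUMNS)


def frame_to_recording(
    df: pd.DataFrame, subject: str = "", session: int = 1, arm: str = ""
) -> IMURecording:
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recording table missing columns {missing}")
    return IMURecording(
        timestamps=df["time_s"].to_numpy(),
        accel=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        gyro=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(),
        subject=subject,
        session=session,
        arm=arm,
    )
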