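"""CSV readers and writers for eye, IMU, sensor and event tables.

All tables carry a ``time_s`` column plus named channels.  Horizontal eye
positions are stored in the reporting (CW-positive) convention; gyroscope
channels are physical (right-handed) rates in deg/s; accelerometer
channels are in units of g.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .saccades import SaccadeEvent
from .signals import ImuRecord
from .trace import UniformTrace

__all__ = [
    "write_eyes_csv",
    "read_eyes_csv",
    "write_imu_csv",
    "read_imu_csv",
    "write_sensor_csv",
    "read_sensor_csv",
    "write_events_csv",
    "read_events_csv",
]

EYE_COLUMNS = ("left_h", "left_v", "right_h", "right_v")


def _rate_from_times(t: np.ndarray) -> float:
    dt = np.median(np.diff(t))
    if not dt > 0:
        raise ValueError("timestamps must be increasing")
    return 1.0 / float(dt)


def write_eyes_csv(path: str | Path, eyes: dict[str, UniformTrace]) -> None:
    base = eyes[EYE_COLUMNS[0]]
    df = pd.DataFrame({"time_s": base.times()})
    for c in EYE_COLUMNS:
        df[c] = eyes[c].values
    df.to_csv(path, index=False)


def read_eyes_csv(path: str | Path) -> dict[str, UniformTrace]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = _rate_from_times(t)
    return {c: UniformTrace(float(t[0]), rate, df[c].to_numpy(float)) for c in EYE_COLUMNS}


def write_imu_csv(path: str | Path, imu: ImuRecord) -> None:
    df = pd.DataFrame({"time_s": imu.accel.times()})
    for i, ax in enumerate("xyz"):
        df[f"accel_{ax}_g"] = imu.accel.values[:, i]
    for i, ax in enumerate("xyz"):
        df[f"gyro_{ax}_dps"] = imu.gyro.values[:, i]
    df.to_csv(path, index=False)


def read_imu_csv(path: str | Path) -> ImuRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = _rate_from_times(t)
    accel = df[[f"accel_{ax}_g" for ax in "xyz"]].to_numpy(float)
    gyro = df[[f"gyro_{ax}_dps" for ax in "xyz"]].to_numpy(float)
    return ImuRecord(
        accel=UniformTrace(float(t[0]), rate, accel),
        gyro=UniformTrace(float(t[0]), rate, gyro),
    )


def write_sensor_csv(path: str | Path, sensor: UniformTrace) -> None:
    pd.DataFrame({"time_s": sensor.times(), "sensor": sensor.values}).to_csv(path, index=False)


def read_sensor_csv(path: str | Path) -> UniformTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    return UniformTrace(float(t[0]), _rate_from_times(t), df["sensor"].to_numpy(float))


def write_events_csv(path: str | Path, events: list[SaccadeEvent]) -> None:
    pd.DataFrame(
        {
            "eye": [e.eye for e in events],
            "peak_time_s": [e.peak_time for e in events],
            "peak_speed_dps": [e.peak_speed for e in events],
            "peak_vh_dps": [e.peak_vh for e in events],
            "direction": [e.direction for e in events],
            "start_s": [e.start_time for e in events],
            "end_s": [e.end_time for e in events],
            "size_deg": [e.size_h for e in events],
        }
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[SaccadeEvent]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        ev = SaccadeEvent(
            peak_time=float(row.peak_time_s),
            peak_speed=float(row.peak_speed_dps),
            peak_vh=float(row.peak_vh_dps),
            eye=str(row.eye) if isinstance(row.eye, str) else "",
        )
        for attr, col in (("start_time", row.start_s), ("end_time", row.end_s), ("size_h", row.size_deg)):
            if col is not None and np.isfinite(col):
                setattr(ev, attr, float(col))
        out.append(ev)
    return out
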