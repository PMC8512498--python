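"""Reading, unit-normalising and resampling raw IMU recordings.

Recordings are tri-axial accelerometer + gyroscope streams from one of three
placements (lower back at L5, right shank, left shank).  Internally everything
is kept in canonical units -- acceleration in m/s^2, angular velocity in deg/s,
time in seconds from recording start -- so the detectors never have to care
which vendor or export format the data came from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: standard gravity used for g <-> m/s^2 conversion
STANDARD_GRAVITY = 9.81

#: tolerance (s) for declaring a timestamp grid non-uniform
TIMESTAMP_UNIFORMITY_TOL = 1e-6


class Placement(str, Enum):
    L5 = "L5"
    SHANK_RIGHT = "shank_right"
    SHANK_LEFT = "shank_left"


@dataclass(frozen=True)
class AxisConvention:
    """Which channel is device-vertical and which gyro channel is sagittal.

    Axis indices refer to columns of the (n, 3) channel arrays; signs let the
    caller declare an upside-down or mirrored mounting without editing data.
    """

    vertical_accel_axis: int = 2
    vertical_accel_sign: int = 1
    sagittal_gyro_axis: int = 1
    sagittal_gyro_sign: int = 1


@dataclass
class IMURecording:
    """Uniformly sampled tri-axial accel/gyro stream from one placement."""

    placement: Placement
    fs: float
    t: np.ndarray
    accel: np.ndarray  # (n, 3), m/s^2
    gyro: np.ndarray  # (n, 3), deg/s
    axis_convention: AxisConvention = field(default_factory=AxisConvention)
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.t.size
        if self.accel.shape[0] != n or self.gyro.shape[0] != n:
            raise ValueError("accel/gyro length must match timestamps")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > TIMESTAMP_UNIFORMITY_TOL:
                raise ValueError(
                    "timestamps not uniform at the declared sampling rate "
                    f"(max deviation {np.max(np.abs(dt - 1.0 / self.fs)):.2e} s)"
                )
        if not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise ValueError("accel/gyro channels must be finite")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def vertical_accel(self) -> np.ndarray:
        c = self.axis_convention
        return c.vertical_accel_sign * self.accel[:, c.vertical_accel_axis]

    def sagittal_gyro(self) -> np.ndarray:
        c = self.axis_convention
        return c.sagittal_gyro_sign * self.gyro[:, c.sagittal_gyro_axis]


def accel_to_m_s2(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "m_s2":
        return np.asarray(values, dtype=float)
    if unit == "g":
        return np.asarray(values, dtype=float) * STANDARD_GRAVITY
    raise ValueError(f"unknown acceleration unit {unit!r}")


def gyro_to_deg_s(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "deg_s":
        return np.asarray(values, dtype=float)
    if unit == "rad_s":
        return np.rad2deg(np.asarray(values, dtype=float))
    raise ValueError(f"unknown angular-velocity unit {unit!r}")


_ACCEL_ROLES = ("accel_x", "accel_y", "accel_z")
_GYRO_ROLES = ("gyro_x", "gyro_y", "gyro_z")


def read_imu_csv(
    path: str | Path,
    column_map: Mapping[str, str],
    fs: float,
    accel_unit: str = "m_s2",
    gyro_unit: str = "deg_s",
    placement: Placement | str = Placement.L5,
    time_column: str | None = None,
    axis_convention: AxisConvention | None = None,
    subject_id: str = "",
    sep: str = ",",
) -> IMURecording:
    """Read one sensor's delimited text export into an :class:`IMURecording`.

    ``column_map`` maps channel roles (``accel_x`` ... ``gyro_z``) to column
    names in the file.  A missing accel or gyro block is permitted (the channels
    are filled with zeros) but flagged in ``metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas names the line
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc

    for role, col in column_map.items():
        if col not in df.columns:
            raise ValueError(f"column for role {role!r} ({col!r}) absent from header")

    n = len(df)
    metadata: dict = {}

    def _block(roles, unit_fn, unit, label):
        present = [r for r in roles if r in column_map]
        if not present:
            metadata[f"missing_{label}"] = True
            return np.zeros((n, 3))
        out = np.zeros((n, 3))
        for i, role in enumerate(roles):
            if role in column_map:
                col = pd.to_numeric(df[column_map[role]], errors="coerce").to_numpy()
                bad = np.flatnonzero(~np.isfinite(col))
                if bad.size:
                    # +2: header line plus 1-based indexing
                    raise ValueError(
                        f"malformed value in column {column_map[role]!r} "
                        f"at line {bad[0] + 2} of {path}"
                    )
                out[:, i] = unit_fn(col, unit)
            else:
                metadata.setdefault(f"missing_{label}_channels", []).append(role)
        return out

    accel = _block(_ACCEL_ROLES, accel_to_m_s2, accel_unit, "accel")
    gyro = _block(_GYRO_ROLES, gyro_to_deg_s, gyro_unit, "gyro")

    if time_column is not None:
        if time_column not in df.columns:
            raise ValueError(f"time column {time_column!r} absent from header")
        t = pd.to_numeric(df[time_column], errors="coerce").to_numpy(dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError(f"non-numeric timestamps in {path}")
        dt = np.diff(t)
        if t.size >= 2 and np.max(np.abs(dt - 1.0 / fs)) > 1e-4:
            raise ValueError(
                "timestamps in file deviate from the declared sampling rate "
                "beyond tolerance"
            )
        t = t - t[0]
        # snap onto the exact uniform grid to absorb text round-off
        t = np.arange(n) / fs
    else:
        t = np.arange(n) / fs

    return IMURecording(
        placement=Placement(placement),
        fs=fs,
        t=t,
        accel=accel,
        gyro=gyro,
        axis_convention=axis_convention or AxisConvention(),
        subject_id=subject_id,
        metadata=metadata,
    )


def write_imu_csv(rec: IMURecording, path: str | Path) -> None:
    """Write a recording in the canonical column layout read by read_imu_csv."""
    df = pd.DataFrame(
        {
            "time_s": rec.t,
            "accel_x": rec.accel[:, 0],
            "accel_y": rec.accel[:, 1],
            "accel_z": rec.accel[:, 2],
            "gyro_x": rec.gyro[:, 0],
            "gyro_y": rec.gyro[:, 1],
            "gyro_z": rec.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


CANONICAL_COLUMN_MAP = {
    "accel_x": "accel_x",
    "accel_y": "accel_y",
    "accel_z": "accel_z",
    "gyro_x": "gyro_x",
    "gyro_y": "gyro_y",
    "gyro_z": "gyro_z",
}

#: column-map preset for the public multi-site young-adult dataset layout,
#: which ships per-sensor text files with ax..gz headers.  Axis sign
#: conventions are not documented with the data, so the user must supply an
#: AxisConvention explicitly.
DS1_COLUMN_MAP = {
    "accel_x": "ax",
    "accel_y": "ay",
    "accel_z": "az",
    "gyro_x": "gx",
    "gyro_y": "gy",
    "gyro_z": "gz",
}


def resample_recording(rec: IMURecording, target_fs: float) -> IMURecording:
    """Linearly interpolate a recording onto a uniform grid at ``target_fs``.

    Linear interpolation is adequate here because both detectors low-pass the
    signal well below Nyquist; no anti-alias filter is applied when
    downsampling (documented limitation).
    """
    if target_fs <= 0:
        raise ValueError("target sampling rate must be positive")
    if rec.n_samples < 2:
        raise ValueError("cannot resample a recording with fewer than 2 samples")
    if target_fs == rec.fs:
        return replace(rec, t=rec.t.copy(), accel=rec.accel.copy(), gyro=rec.gyro.copy())
    new_t = np.arange(0.0, rec.duration + 0.5 / target_fs, 1.0 / target_fs)
    new_t = new_t[new_t <= rec.duration + 1e-12]
    accel = np.column_stack(
        [np.interp(new_t, rec.t - rec.t[0], rec.accel[:, i]) for i in range(3)]
    )
    gyro = np.column_stack(
        [np.interp(new_t, rec.t - rec.t[0], rec.gyro[:, i]) for i in range(3)]
    )
    return IMURecording(
        placement=rec.placement,
        fs=target_fs,
        t=new_t,
        accel=accel,
        gyro=gyro,
        axis_convention=rec.axis_convention,
        subject_id=rec.subject_id,
        metadata={**rec.metadata, "resampled_from_hz": rec.fs},
    )


def write_events_csv(events, path: str | Path, subject_id: str = "") -> None:
    """Write detected events as a flat table: one row per IC/FC timestamp."""
    rows = []
    series = events if isinstance(events, (list, tuple)) else [events]
    for ev in series:
        sid = subject_id or getattr(ev, "subject_id", "")
        for t in ev.ic_times:
            rows.append((sid, ev.placement.value, ev.side, "IC", t))
        for t in ev.fc_times:
            rows.append((sid, ev.placement.value, ev.side, "FC", t))
    df = pd.DataFrame(rows, columns=["subject_id", "placement", "side", "event_type", "time_s"])
    df.sort_values(["subject_id", "placement", "side", "time_s"], inplace=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "placement", "side", "event_type", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def load_config(path: str | Path) -> dict:
    """Load a key/value sensor config (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
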