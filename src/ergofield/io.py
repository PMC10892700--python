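"""Reading, validation and windowing of joint-angle and insole CSV exports.

Angle CSV: ``time_s, <channel>...`` in degrees; insole CSV: ``time_s,
s001..sNNN`` in N/cm^2; layout CSV: ``sensor_id, length_pct, width_pct``
with length measured from the posterior heel (0%) to the toes (100%) and
width from the medial edge (0%) to the lateral edge (100%).

Time windows are half-open ``[start, end)`` so that adjacent windows
partition a recording without duplicated frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "Session",
    "JointAngleSeries",
    "InsoleRecording",
    "REQUIRED_ANGLE_CHANNELS",
    "BOOLEAN_CHANNELS",
    "read_angles",
    "write_angles",
    "read_insole",
    "write_insole",
    "read_layout",
    "write_layout",
    "window",
]

DEVICE_MAX_PRESSURE = 64.0  # N/cm^2, insole full-scale output
DEVICE_MIN_PRESSURE = 0.6   # N/cm^2, lower bound of the measurement range
MAX_SENSORS = 240

#: Channels the ergonomic scorers consume.  ``*_l`` / ``*_r`` are the left and
#: right limb; flexion is positive, extension negative.  Boolean worksheet
#: items (shoulder raised, twists, side bends, leg support) travel as 0/1
#: traces because IMU exports do not encode checkbox items directly.
REQUIRED_ANGLE_CHANNELS: tuple[str, ...] = (
    "upper_arm_flexion_l", "upper_arm_flexion_r",
    "upper_arm_abduction_l", "upper_arm_abduction_r",
    "shoulder_raised_l", "shoulder_raised_r",
    "lower_arm_flexion_l", "lower_arm_flexion_r",
    "wrist_flexion_l", "wrist_flexion_r",
    "wrist_deviation_l", "wrist_deviation_r",
    "wrist_twist_l", "wrist_twist_r",
    "neck_flexion", "neck_twist", "neck_side_bend",
    "trunk_flexion", "trunk_twist", "trunk_side_bend",
    "legs_supported",
)

BOOLEAN_CHANNELS: frozenset[str] = frozenset({
    "shoulder_raised_l", "shoulder_raised_r",
    "neck_twist", "neck_side_bend",
    "trunk_twist", "trunk_side_bend",
    "legs_supported",
})

_RATE_TOL = 0.01  # relative tolerance on inter-frame gaps (fixed-rate capture)


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class ValidationError(ValueError):
    """Input values violate a physical or structural constraint."""


@dataclass(frozen=True)
class Session:
    """One measurement session of a worker (pre- or post-shift capture)."""

    worker_id: str
    phase: str  # "pre" | "post"
    duration_s: float
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValidationError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be positive")
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class JointAngleSeries:
    """Per-frame joint angles (degrees) for the channels the scorers consume.

    ``data`` holds one column per channel plus the frame times in ``times``;
    all traces share the same length.
    """

    session: Session
    times: np.ndarray          # seconds, monotonically increasing
    data: pd.DataFrame         # n_frames x channels, degrees (booleans as 0/1)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.data):
            raise ValidationError("times and data length mismatch")
        angles = self.data[[c for c in self.data.columns if c not in BOOLEAN_CHANNELS]]
        vals = angles.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.unique(np.nonzero(~np.isfinite(vals))[0])[:10]
            raise ValidationError(f"non-finite angles at frames {bad.tolist()}")
        if np.any(np.abs(vals) > 180.0):
            bad = np.unique(np.nonzero(np.abs(vals) > 180.0)[0])[:10]
            raise ValidationError(f"|angle| > 180 deg at frames {bad.tolist()}")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class InsoleRecording:
    """Frame x sensor plantar pressure matrix (N/cm^2) with sensor layout.

    ``layout`` gives each sensor's normalized foot coordinates
    (``length_pct`` from the posterior heel, ``width_pct`` from the medial
    edge).  ``excluded`` marks sensors (by positional index) that never
    contribute to any metric.
    """

    session: Session
    side: str                  # "left" | "right"
    times: np.ndarray
    pressures: np.ndarray      # n_frames x n_sensors
    layout: pd.DataFrame       # columns: sensor_id, length_pct, width_pct
    excluded: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.pressures.ndim != 2 or self.pressures.shape[0] != len(self.times):
            raise ValidationError("pressures must be n_frames x n_sensors")
        if self.pressures.shape[1] != len(self.layout):
            raise SchemaError(
                f"{self.pressures.shape[1]} pressure columns vs "
                f"{len(self.layout)} layout sensors"
            )
        if len(self.layout) > MAX_SENSORS:
            raise ValidationError(f"sensor count {len(self.layout)} exceeds {MAX_SENSORS}")
        for col in ("length_pct", "width_pct"):
            v = self.layout[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 100)):
                raise ValidationError(f"layout {col} outside [0, 100]")
        if np.any(self.pressures < 0):
            raise ValidationError("negative pressure values")
        if np.any(self.pressures > DEVICE_MAX_PRESSURE):
            raise ValidationError(
                f"pressure above device range {DEVICE_MAX_PRESSURE} N/cm^2"
            )
        if not set(self.excluded) <= set(range(self.n_sensors)):
            raise ValidationError("excluded indices out of range")

    @property
    def n_frames(self) -> int:
        return self.pressures.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.pressures.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.session.sample_rate_hz

    def active_sensors(self) -> np.ndarray:
        """Indices of sensors that are not excluded."""
        return np.array(
            [i for i in range(self.n_sensors) if i not in self.excluded], dtype=int
        )


def _infer_rate(times: np.ndarray, path: str | Path) -> float:
    if len(times) < 2:
        raise ValidationError(f"{path}: need at least 2 frames to infer sample rate")
    gaps = np.diff(times)
    if np.any(gaps <= 0):
        row = int(np.nonzero(gaps <= 0)[0][0]) + 2
        raise ValidationError(f"{path}: time not strictly increasing at row {row}")
    med = float(np.median(gaps))
    if np.any(np.abs(gaps - med) > _RATE_TOL * med):
        raise ValidationError(f"{path}: irregular sampling beyond {_RATE_TOL:.0%} tolerance")
    return 1.0 / med


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise SchemaError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_angles(
    path: str | Path,
    channels: Sequence[str] = REQUIRED_ANGLE_CHANNELS,
    *,
    worker_id: str = "unknown",
    phase: str = "pre",
) -> JointAngleSeries:
    """Read a joint-angle CSV export and validate it against ``channels``.

    The first column must be time in seconds, strictly increasing at a
    near-constant rate; the sample rate is inferred from the median gap.
    """
    df = _read_csv(path)
    tcol = df.columns[0]
    missing = [c for c in channels if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing channel(s) {missing}")
    times = df[tcol].to_numpy(dtype=float)
    rate = _infer_rate(times, path)
    duration = times[-1] - times[0] + 1.0 / rate
    session = Session(worker_id=worker_id, phase=phase,
                      duration_s=float(duration), sample_rate_hz=rate)
    data = df[list(channels)].astype(float).reset_index(drop=True)
    return JointAngleSeries(session=session, times=times, data=data)


def write_angles(series: JointAngleSeries, path: str | Path) -> None:
    out = series.data.copy()
    out.insert(0, "time_s", series.times)
    out.to_csv(path, index=False, float_format="%.6f")


def read_layout(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    need = {"sensor_id", "length_pct", "width_pct"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: layout must have columns {sorted(need)}")
    return df[["sensor_id", "length_pct", "width_pct"]].reset_index(drop=True)


def write_layout(layout: pd.DataFrame, path: str | Path) -> None:
    layout.to_csv(path, index=False, float_format="%.6f")


def read_insole(
    path: str | Path,
    layout_path: str | Path,
    *,
    side: str = "left",
    worker_id: str = "unknown",
    phase: str = "pre",
) -> InsoleRecording:
    """Read a raw insole pressure CSV with its sensor-layout file.

    Columns after the time column must match the layout's sensor IDs
    one-to-one (order taken from the layout).  No calibration is applied.
    """
    layout = read_layout(layout_path)
    df = _read_csv(path)
    tcol = df.columns[0]
    ids = [str(s) for s in layout["sensor_id"]]
    missing = [s for s in ids if s not in df.columns]
    extra = [c for c in df.columns[1:] if c not in ids]
    if missing or extra:
        raise SchemaError(
            f"{path}: pressure columns do not match layout "
            f"(missing {missing[:5]}, unexpected {extra[:5]})"
        )
    times = df[tcol].to_numpy(dtype=float)
    rate = _infer_rate(times, path)
    session = Session(worker_id=worker_id, phase=phase,
                      duration_s=float(times[-1] - times[0] + 1.0 / rate),
                      sample_rate_hz=rate)
    pressures = df[ids].to_numpy(dtype=float)
    return InsoleRecording(session=session, side=side, times=times,
                           pressures=pressures, layout=layout)


def write_insole(rec: InsoleRecording, path: str | Path) -> None:
    out = pd.DataFrame(rec.pressures, columns=[str(s) for s in rec.layout["sensor_id"]])
    out.insert(0, "time_s", rec.times)
    out.to_csv(path, index=False, float_format="%.6f")


def window(obj, start_s: float, end_s: float):
    """Restrict a series/recording to frames with ``start_s <= t < end_s``.

    Times are measured on the object's own clock.  The window must be
    non-empty; metadata (duration) is updated on the returned copy.
    """
    if not (start_s < end_s):
        raise ValidationError("window requires start_s < end_s")
    t0 = obj.times[0]
    mask = (obj.times - t0 >= start_s) & (obj.times - t0 < end_s)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("empty window")
    rate = obj.session.sample_rate_hz
    session = replace(obj.session, duration_s=n / rate)
    if isinstance(obj, JointAngleSeries):
        return JointAngleSeries(session=session, times=obj.times[mask],
                                data=obj.data.loc[mask].reset_index(drop=True))
    if isinstance(obj, InsoleRecording):
        return InsoleRecording(session=session, side=obj.side,
                               times=obj.times[mask],
                               pressures=obj.pressures[mask],
                               layout=obj.layout, excluded=obj.excluded)
    raise TypeError(f"cannot window {type(obj).__name__}")
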