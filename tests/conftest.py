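import numpy as np
import pandas as pd
import pytest

from ergofield.io import (InsoleRecording, JointAngleSeries,
                          REQUIRED_ANGLE_CHANNELS, Session)


def make_session(duration_s=1.0, rate=60.0, phase="pre", worker="w001"):
    return Session(worker_id=worker, phase=phase, duration_s=duration_s,
                   sample_rate_hz=rate)


def make_series(frames: dict[str, np.ndarray] | None = None, n=3, rate=60.0,
                **overrides) -> JointAngleSeries:
    """Angle series of n frames, every channel neutral unless overridden.

    Neutral means 0 deg except the elbow (80 deg working angle) and
    legs_supported = 1.
    """
    data = {}
    for ch in REQUIRED_ANGLE_CHANNELS:
        if ch.startswith("lower_arm_flexion"):
            data[ch] = np.full(n, 80.0)
        elif ch == "legs_supported":
            data[ch] = np.ones(n)
        else:
            data[ch] = np.zeros(n)
    data["neck_flexion"] = np.full(n, 5.0)
    if frames:
        for ch, v in frames.items():
            data[ch] = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
    data.update({k: np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
                 for k, v in overrides.items()})
    t = np.arange(n) / rate
    return JointAngleSeries(session=make_session(n / rate, rate),
                            times=t, data=pd.DataFrame(data))


def neutral_frame() -> dict[str, float]:
    s = make_series(n=1)
    return {c: float(s.data[c].iloc[0]) for c in s.data.columns}


def grid_layout(n_len=5, n_wid=4) -> pd.DataFrame:
    L, W = np.meshgrid(np.linspace(5, 95, n_len), np.linspace(10, 90, n_wid),
                       indexing="ij")
    return pd.DataFrame({
        "sensor_id": [f"s{i + 1:03d}" for i in range(L.size)],
        "length_pct": L.ravel(), "width_pct": W.ravel()})


def make_recording(pressures, rate=100.0, layout=None, side="left",
                   excluded=frozenset()) -> InsoleRecording:
    P = np.asarray(pressures, dtype=float)
    n_frames, n_sensors = P.shape
    if layout is None:
        rng = np.random.default_rng(n_sensors)
        layout = pd.DataFrame({
            "sensor_id": [f"s{i + 1:03d}" for i in range(n_sensors)],
            "length_pct": rng.uniform(0, 100, n_sensors),
            "width_pct": rng.uniform(0, 100, n_sensors)})
    t = np.arange(n_frames) / rate
    return InsoleRecording(session=make_session(n_frames / rate, rate),
                           side=side, times=t, pressures=P, layout=layout,
                           excluded=excluded)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
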