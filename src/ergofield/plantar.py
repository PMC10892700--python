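"""In-shoe plantar pressure kinetics: calibration, region masks and metrics.

The foot is segmented into six regions in normalized foot coordinates
(length measured from the posterior heel, width from the medial edge):

* rearfoot 0-30 % length, midfoot 30-60 %, metatarsal heads 60-80 %,
  forefoot 80-100 % (each over the full width);
* inner foot 0-60 % width, outer foot 60-100 % width (full length).

Length/width cut points are treated as contiguous half-open real
intervals, closed at the upper edge (a sensor at exactly 30 % length is
rearfoot), so the four longitudinal masks partition the active sensors
and the two width masks partition them independently.

Per region the module reports mean pressure, peak pressure (mean over the
member sensors of each sensor's own maximum), the pressure-time impulse
(sum of pressure x dt per sensor, averaged over members, Ns/cm^2), the
loaded-time fraction and the percentage of loaded sensors.  "Loaded"
means at or above the device's lower measurement bound (0.6 N/cm^2 by
default).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .io import (DEVICE_MIN_PRESSURE, InsoleRecording, SchemaError,
                 ValidationError)

__all__ = [
    "REGION_NAMES",
    "LENGTH_REGIONS",
    "WIDTH_REGIONS",
    "EXCLUSION_COUNTS",
    "zero_calibrate",
    "exclude_rear_lateral",
    "assign_regions",
    "sensor_impulse",
    "region_metrics",
    "loaded_sensor_pct",
    "contrast",
]

LENGTH_REGIONS: dict[str, tuple[float, float]] = {
    "rearfoot": (0.0, 30.0),
    "midfoot": (30.0, 60.0),
    "metatarsal_heads": (60.0, 80.0),
    "forefoot": (80.0, 100.0),
}
WIDTH_REGIONS: dict[str, tuple[float, float]] = {
    "inner_foot": (0.0, 60.0),
    "outer_foot": (60.0, 100.0),
}
REGION_NAMES: tuple[str, ...] = tuple(LENGTH_REGIONS) + tuple(WIDTH_REGIONS)

#: Rear-lateral sensors excluded per EU shoe size (safety-shoe heel guidance).
EXCLUSION_COUNTS: dict[int, int] = {39: 3, 41: 4, 43: 4, 45: 5}

METRIC_COLUMNS = ("mean_pressure", "peak_pressure", "impulse",
                  "loaded_time_fraction", "loaded_sensor_pct")


def zero_calibrate(recording: InsoleRecording,
                   baseline: InsoleRecording) -> InsoleRecording:
    """Subtract the per-sensor mean of an unloaded baseline capture.

    Removes the static lace/binding pressure recorded while sitting with
    the feet raised; negative results are clamped to zero.
    """
    if not recording.layout["sensor_id"].equals(baseline.layout["sensor_id"]):
        raise SchemaError("recording/baseline layout mismatch")
    offset = baseline.pressures.mean(axis=0)
    calibrated = np.clip(recording.pressures - offset, 0.0, None)
    return replace(recording, pressures=calibrated)


def exclude_rear_lateral(recording: InsoleRecording,
                         shoe_size: int) -> InsoleRecording:
    """Mark the rear-lateral sensors excluded for a given EU shoe size.

    The most posterior-lateral sensors (ranked by ascending length, ties
    broken by descending width) pick up shell curvature of the safety
    shoe's heel guidance rather than foot load; 3 (EU 39) to 5 (EU 45)
    are dropped from all downstream metrics.
    """
    if shoe_size not in EXCLUSION_COUNTS:
        raise ValidationError(
            f"unsupported shoe size {shoe_size}; supported: "
            f"{sorted(EXCLUSION_COUNTS)}")
    k = EXCLUSION_COUNTS[shoe_size]
    lay = recording.layout
    order = np.lexsort((-lay["width_pct"].to_numpy(dtype=float),
                        lay["length_pct"].to_numpy(dtype=float)))
    excluded = frozenset(recording.excluded) | frozenset(int(i) for i in order[:k])
    return replace(recording, excluded=excluded)


def assign_regions(layout: pd.DataFrame,
                   excluded: frozenset[int] = frozenset()) -> dict[str, np.ndarray]:
    """Map each active sensor to its longitudinal and width region.

    Returns per region the member sensor indices.  Interval convention:
    lower-open/upper-closed except the first interval, which includes 0,
    so each sensor lands in exactly one longitudinal and one width region.
    """
    L = layout["length_pct"].to_numpy(dtype=float)
    W = layout["width_pct"].to_numpy(dtype=float)
    active = np.array([i for i in range(len(layout)) if i not in excluded], dtype=int)
    masks: dict[str, np.ndarray] = {}
    for name, (lo, hi) in LENGTH_REGIONS.items():
        sel = (L[active] <= hi) & ((L[active] > lo) if lo > 0 else (L[active] >= 0))
        masks[name] = active[sel]
    for name, (lo, hi) in WIDTH_REGIONS.items():
        sel = (W[active] <= hi) & ((W[active] > lo) if lo > 0 else (W[active] >= 0))
        masks[name] = active[sel]
    return masks


def sensor_impulse(trace: np.ndarray, dt: float) -> float:
    """Pressure-time impulse of one sensor: sum of pressure x dt (Ns/cm^2)."""
    if not dt > 0:
        raise ValidationError("dt must be positive")
    return float(np.sum(np.asarray(trace, dtype=float)) * dt)


def region_metrics(recording: InsoleRecording,
                   masks: dict[str, np.ndarray] | None = None,
                   load_thresh: float = DEVICE_MIN_PRESSURE,
                   *,
                   mean_over: str = "loaded",
                   loaded_sensor_min_fraction: float = 0.01) -> pd.DataFrame:
    """Kinetic metrics per foot region, one row per region.

    ``mean_pressure`` averages each member sensor's time-mean over its
    loaded frames (frames >= ``load_thresh``), then over sensors; sensors
    never loaded contribute 0.  ``mean_over='all'`` uses whole-recording
    per-sensor means instead.  ``peak_pressure`` is the mean of per-sensor
    maxima; ``impulse`` the mean per-sensor pressure-time integral;
    ``loaded_time_fraction`` the mean fraction of loaded frames; and
    ``loaded_sensor_pct`` the percentage of member sensors loaded in at
    least ``loaded_sensor_min_fraction`` of frames.
    """
    if mean_over not in ("loaded", "all"):
        raise ValidationError("mean_over must be 'loaded' or 'all'")
    if masks is None:
        masks = assign_regions(recording.layout, recording.excluded)
    P = recording.pressures
    dt = recording.dt
    n_frames = recording.n_frames
    loaded = P >= load_thresh
    rows = {}
    for name, idx in masks.items():
        if len(idx) == 0:
            raise ValidationError(f"region {name!r} has no member sensors")
        sub = P[:, idx]
        sub_loaded = loaded[:, idx]
        n_loaded = sub_loaded.sum(axis=0)
        with np.errstate(invalid="ignore"):
            loaded_means = np.where(
                n_loaded > 0,
                np.sum(sub * sub_loaded, axis=0) / np.maximum(n_loaded, 1),
                0.0)
        if mean_over == "loaded":
            mean_p = float(loaded_means.mean())
        else:
            mean_p = float(sub.mean())
        rows[name] = {
            "mean_pressure": mean_p,
            "peak_pressure": float(sub.max(axis=0).mean()),
            "impulse": float((sub.sum(axis=0) * dt).mean()),
            "loaded_time_fraction": float((n_loaded / n_frames).mean()),
            "loaded_sensor_pct": float(
                100.0 * np.mean(n_loaded / n_frames >= loaded_sensor_min_fraction)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]
    out.index.name = "region"
    return out


def loaded_sensor_pct(recording: InsoleRecording,
                      load_thresh: float = DEVICE_MIN_PRESSURE,
                      min_fraction: float = 0.01) -> float:
    """Whole-foot percentage of active sensors loaded in >= ``min_fraction`` of frames."""
    idx = recording.active_sensors()
    if len(idx) == 0:
        raise ValidationError("no active sensors")
    frac = (recording.pressures[:, idx] >= load_thresh).mean(axis=0)
    return float(100.0 * np.mean(frac >= min_fraction))


def contrast(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre differences per region (positive: post > pre)."""
    if set(pre.index) != set(post.index):
        raise SchemaError("region sets differ between pre and post metrics")
    return post.loc[pre.index] - pre
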