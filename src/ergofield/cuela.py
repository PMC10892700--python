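"""CUELA-style green/yellow/red posture-zone analysis.

CUELA (the DGUV posture measurement and long-term analysis scheme) grades
each joint angle into three zones: green (acceptable), yellow (limited
acceptable) and red (unacceptable).  Per frame, a channel's zone comes
from editable per-channel angle bands; the frame zone is the worst zone
over all evaluated channels.  The session result is the relative time
distribution over the three zones plus a continuous final score
``1*p_green + 2*p_yellow + 3*p_red`` on the 1-3 scale, which makes the
zone distribution comparable to a RULA-style single score.

Default bands ship in ``data/cuela_thresholds.csv`` (the DGUV 208-033
angle ranges are not public tabular data, so the defaults encode the
common ergonomic ranges and are meant to be edited).  Zone boundaries are
closed on the greener side: an angle exactly on a green/yellow boundary is
green.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import BOOLEAN_CHANNELS, JointAngleSeries, SchemaError, ValidationError
from .rula import RiskDistribution

__all__ = [
    "ZONE_LABELS",
    "ZoneThresholds",
    "CuelaResult",
    "default_thresholds",
    "categorize_frame",
    "cuela_score",
]

ZONE_LABELS: tuple[str, ...] = ("green", "yellow", "red")
_ZONE_WEIGHTS = np.array([1.0, 2.0, 3.0])


@dataclass(frozen=True)
class ZoneThresholds:
    """Per-channel green/yellow angle bands (degrees).

    ``bands[channel] = (green_lo, green_hi, yellow_lo, yellow_hi)`` with
    the yellow interval containing the green one; angles outside yellow
    are red.  Intervals are closed, and green wins on shared boundaries.
    """

    bands: Mapping[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for ch, (glo, ghi, ylo, yhi) in self.bands.items():
            if not (ylo <= glo <= ghi <= yhi):
                raise ValidationError(
                    f"{ch}: require yellow_lo <= green_lo <= green_hi <= yellow_hi")
            # the green band must contain the channel's neutral working
            # posture (0 deg for most channels, ~90 deg elbow flexion);
            # that is the threshold author's responsibility, not checkable here

    def zone_codes(self, channel: str, angles: np.ndarray) -> np.ndarray:
        """0 = green, 1 = yellow, 2 = red for each angle."""
        if channel not in self.bands:
            raise SchemaError(f"no zone thresholds configured for channel {channel!r}")
        glo, ghi, ylo, yhi = self.bands[channel]
        a = np.asarray(angles, dtype=float)
        return np.select([(a >= glo) & (a <= ghi), (a >= ylo) & (a <= yhi)],
                         [0, 1], default=2)


@dataclass(frozen=True)
class CuelaResult:
    """Zone time distribution and the distribution-weighted final score."""

    distribution: RiskDistribution
    final_score: float

    def __post_init__(self) -> None:
        if not 1.0 - 1e-9 <= self.final_score <= 3.0 + 1e-9:
            raise ValidationError(f"final_score {self.final_score} outside [1, 3]")


def read_thresholds(path: str | Path) -> ZoneThresholds:
    """Read a threshold table ``channel, green_lo, green_hi, yellow_lo, yellow_hi``."""
    df = pd.read_csv(path)
    need = {"channel", "green_lo", "green_hi", "yellow_lo", "yellow_hi"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: threshold file must have columns {sorted(need)}")
    bands = {
        str(r.channel): (float(r.green_lo), float(r.green_hi),
                         float(r.yellow_lo), float(r.yellow_hi))
        for r in df.itertuples()
    }
    return ZoneThresholds(bands=bands)


def default_thresholds() -> ZoneThresholds:
    with resources.as_file(
        resources.files("ergofield.data").joinpath("cuela_thresholds.csv")
    ) as p:
        return read_thresholds(p)


def categorize_frame(
    angles: Mapping[str, float], thresholds: ZoneThresholds
) -> tuple[dict[str, str], str]:
    """Zone per channel and the frame's worst zone (red > yellow > green).

    Every channel in ``angles`` must be covered by the threshold table;
    a channel without thresholds is a configuration error.
    """
    per_channel: dict[str, str] = {}
    worst = 0
    for ch in angles:
        code = int(thresholds.zone_codes(ch, np.asarray([angles[ch]]))[0])
        per_channel[ch] = ZONE_LABELS[code]
        worst = max(worst, code)
    if not per_channel:
        raise SchemaError("no channels to categorize")
    return per_channel, ZONE_LABELS[worst]


def cuela_score(
    series: JointAngleSeries, thresholds: ZoneThresholds | None = None
) -> CuelaResult:
    """Zone distribution and final score for a whole session.

    All non-boolean (angle) channels of the series are zoned; any such
    channel without configured thresholds is a configuration error.
    """
    if series.n_frames == 0:
        raise ValidationError("empty series")
    thresholds = thresholds or default_thresholds()
    worst = np.zeros(series.n_frames, dtype=int)
    angle_channels = [c for c in series.data.columns if c not in BOOLEAN_CHANNELS]
    if not angle_channels:
        raise SchemaError("no angle channel present in the series")
    for ch in angle_channels:
        worst = np.maximum(worst, thresholds.zone_codes(
            ch, series.data[ch].to_numpy(dtype=float)))
    counts = np.bincount(worst, minlength=3)
    p = counts / series.n_frames
    dist = RiskDistribution(levels=ZONE_LABELS, proportions=p)
    return CuelaResult(distribution=dist, final_score=float(_ZONE_WEIGHTS @ p))
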