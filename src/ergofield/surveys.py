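"""Borg CR-10 body-map composites and fatigue VAS handling.

The Borg CR-10 body map collects a 0-10 perceived-exertion rating per
body region.  Regions belong to one of three groups — upper extremity
(UE), core, lower extremity (LE) — and the analysis consumes four
composites: the total (mean over all regions) and one unweighted mean per
group.  Perceived fatigue is a single 0-10 visual-analog-scale value.

Banding follows the field's usage of the scale: exertion below 2 is low,
2-4 moderate, above 4 high; fatigue 2-5 is mild.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import ValidationError

__all__ = [
    "DEFAULT_REGION_GROUPS",
    "BodyMapRating",
    "FatigueVas",
    "composite_scores",
    "classify_exertion",
]

#: Default 14-region body map with UE / core / LE group membership.
DEFAULT_REGION_GROUPS: dict[str, str] = {
    "shoulder_l": "UE", "shoulder_r": "UE",
    "upper_arm_l": "UE", "upper_arm_r": "UE",
    "forearm_hand_l": "UE", "forearm_hand_r": "UE",
    "neck": "core", "upper_back": "core", "lower_back": "core", "abdomen": "core",
    "thigh_l": "LE", "thigh_r": "LE",
    "lower_leg_foot_l": "LE", "lower_leg_foot_r": "LE",
}

GROUPS = ("UE", "core", "LE")


@dataclass(frozen=True)
class BodyMapRating:
    """One worker's Borg CR-10 body-map ratings (0-10 per region)."""

    ratings: Mapping[str, float]
    groups: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_REGION_GROUPS))

    def __post_init__(self) -> None:
        for region, g in self.groups.items():
            if g not in GROUPS:
                raise ValidationError(f"{region}: unknown group {g!r}")
        for region, v in self.ratings.items():
            if region not in self.groups:
                raise ValidationError(f"unknown body-map region {region!r}")
            if not 0.0 <= float(v) <= 10.0:
                raise ValidationError(f"{region}: rating {v} outside [0, 10]")


@dataclass(frozen=True)
class FatigueVas:
    """Perceived fatigue on a 0-10 visual analog scale."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 10.0:
            raise ValidationError(f"VAS {self.value} outside [0, 10]")


def composite_scores(rating: BodyMapRating) -> dict[str, float]:
    """Total, UE, core and LE composites as unweighted group means.

    Every configured region must be rated; missing ones are listed in the
    error.
    """
    missing = [r for r in rating.groups if r not in rating.ratings]
    if missing:
        raise ValidationError(f"missing body-map rating(s): {missing}")
    by_group: dict[str, list[float]] = {g: [] for g in GROUPS}
    for region, g in rating.groups.items():
        by_group[g].append(float(rating.ratings[region]))
    out = {g: float(np.mean(v)) for g, v in by_group.items()}
    out["total"] = float(np.mean([float(rating.ratings[r]) for r in rating.groups]))
    return out


def classify_exertion(score: float, kind: str = "exertion") -> str:
    """Band a 0-10 score: exertion <2 low, 2-4 moderate, >4 high.

    Fatigue bands (``kind='fatigue'``): <2 low, 2-5 mild, >5 high.
    Band edges are inclusive on the lower band (2 and 4 are moderate).
    """
    if not 0.0 <= score <= 10.0:
        raise ValidationError(f"score {score} outside [0, 10]")
    if kind == "exertion":
        if score < 2.0:
            return "low"
        return "moderate" if score <= 4.0 else "high"
    if kind == "fatigue":
        if score < 2.0:
            return "low"
        return "mild" if score <= 5.0 else "high"
    raise ValidationError(f"unknown kind {kind!r}")
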