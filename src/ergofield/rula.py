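"""Continuous RULA scoring from joint-angle time series.

RULA (Rapid Upper Limb Assessment) grades working postures 1 (acceptable)
to 7 (change required immediately) by combining partial scores per body
region through three lookup tables: Table A (upper arm, lower arm, wrist,
wrist twist), Table B (neck, trunk, legs) and Table C (grand score from the
modifier-adjusted A and B scores).  The worksheet tables and angle bins
ship as editable package data (``data/rula_tables.json``).

Beyond the classic single-posture worksheet, this module scores every
captured frame, reports the distribution of working time over the four
action levels, and condenses the whole work process into a continuous
final score (time-weighted mean grand score by default).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .io import BOOLEAN_CHANNELS, JointAngleSeries, ValidationError

__all__ = [
    "ACTION_LEVEL_LABELS",
    "ForceLoadSpec",
    "RulaFrameScore",
    "RiskDistribution",
    "grand_from_partials",
    "score_frame",
    "score_series",
    "detect_static",
    "action_level_distribution",
    "final_rula_score",
]

#: The four RULA action levels as working-time bands (grand 1-2, 3-4, 5-6, 7).
ACTION_LEVEL_LABELS: tuple[str, ...] = (
    "acceptable",
    "measures in the near future",
    "measures shortly",
    "measures directly",
)


def _load_tables() -> dict:
    with resources.files("ergofield.data").joinpath("rula_tables.json").open() as fh:
        return json.load(fh)


_T = _load_tables()
TABLE_A = np.asarray(_T["table_a"], dtype=int)   # [ua-1, la-1, wrist-1, twist-1]
TABLE_B = np.asarray(_T["table_b"], dtype=int)   # [neck-1, trunk-1, legs-1]
TABLE_C = np.asarray(_T["table_c"], dtype=int)   # [A-1 (cap 8), B-1 (cap 7)]
_BINS = _T["bins"]


@dataclass(frozen=True)
class ForceLoadSpec:
    """Force/load context of the task.

    ``load_band`` is one of ``low`` (<2 kg), ``mid`` (2-10 kg) or ``high``
    (>10 kg); ``repetitive``/``static`` escalate the worksheet force
    modifier (mid: +1, +2 if repeated/static; high: +2, +3).
    """

    load_band: str = "low"
    repetitive: bool = False
    static: bool = False

    _BANDS = ("low", "mid", "high")

    def __post_init__(self) -> None:
        if self.load_band not in self._BANDS:
            raise ValidationError(f"load_band must be one of {self._BANDS}")

    @property
    def force_modifier(self) -> int:
        escalated = self.repetitive or self.static
        if self.load_band == "low":
            return 0
        if self.load_band == "mid":
            return 2 if escalated else 1
        return 3 if escalated else 2


@dataclass(frozen=True)
class RulaFrameScore:
    """All partial scores, modifiers and the grand score for one frame."""

    upper_arm: int
    lower_arm: int
    wrist: int
    wrist_twist: int
    neck: int
    trunk: int
    legs: int
    muscle_a: int
    force_a: int
    muscle_b: int
    force_b: int
    score_a: int
    score_b: int
    grand: int

    def __post_init__(self) -> None:
        if not 1 <= self.grand <= 7:
            raise ValidationError(f"grand score {self.grand} outside [1, 7]")


@dataclass(frozen=True)
class RiskDistribution:
    """Fraction of working time spent in each ordered risk level."""

    levels: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != len(self.levels):
            raise ValidationError("levels/proportions length mismatch")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("proportions must be >= 0 and sum to 1")
        object.__setattr__(self, "proportions", p)

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.levels))


# ---------------------------------------------------------------------------
# partial-score bins (vectorized over frame arrays)

def _upper_arm_score(flexion, abduction, raised):
    f = np.asarray(flexion, dtype=float)
    lo, hi = _BINS["upper_arm_flexion"]["score1"]
    base = np.select(
        [(f >= lo) & (f <= hi),
         (f < lo) | (f <= _BINS["upper_arm_flexion"]["score2_flex"][1]),
         f <= _BINS["upper_arm_flexion"]["score3"][1]],
        [1, 2, 3], default=4)
    mod = (np.asarray(raised) > 0.5).astype(int)
    mod += (np.abs(np.asarray(abduction, dtype=float))
            > _BINS["upper_arm_abducted_above_deg"]).astype(int)
    return base + mod  # max 6, within Table A's range


def _lower_arm_score(flexion):
    f = np.asarray(flexion, dtype=float)
    lo, hi = _BINS["lower_arm_flexion_score1"]
    return np.where((f >= lo) & (f <= hi), 1, 2)


def _wrist_score(flexion, deviation):
    f = np.abs(np.asarray(flexion, dtype=float))
    b = _BINS["wrist_flexion"]
    base = np.select([f <= b["score1_abs"], f <= b["score2_abs"]], [1, 2], default=3)
    dev = (np.abs(np.asarray(deviation, dtype=float))
           > _BINS["wrist_deviated_above_deg"]).astype(int)
    return base + dev  # max 4


def _wrist_twist_score(twist):
    t = np.abs(np.asarray(twist, dtype=float))
    return np.where(t > _BINS["wrist_twist_endrange_above_deg"], 2, 1)


def _neck_score(flexion, twist, side_bend):
    f = np.asarray(flexion, dtype=float)
    b = _BINS["neck_flexion"]
    base = np.select(
        [f < b["score4_extension_below"], f <= b["score1"][1], f <= b["score2"][1]],
        [4, 1, 2], default=3)
    mod = (np.asarray(twist) > 0.5).astype(int) + (np.asarray(side_bend) > 0.5).astype(int)
    return np.minimum(base + mod, 6)


def _trunk_score(flexion, twist, side_bend):
    f = np.asarray(flexion, dtype=float)
    b = _BINS["trunk_flexion"]
    base = np.select(
        [np.abs(f) <= b["score1_abs"], f < b["extension_below"],
         f <= b["score2"][1], f <= b["score3"][1]],
        [1, 2, 2, 3], default=4)
    mod = (np.asarray(twist) > 0.5).astype(int) + (np.asarray(side_bend) > 0.5).astype(int)
    return np.minimum(base + mod, 6)


def _legs_score(supported):
    return np.where(np.asarray(supported) > 0.5, 1, 2)


def grand_from_partials(upper_arm, lower_arm, wrist, wrist_twist,
                        neck, trunk, legs,
                        muscle_a=0, force_a=0, muscle_b=0, force_b=0):
    """Grand score from integer partial scores via Tables A, B and C.

    Inputs are clipped into each table's valid index range; A is capped at
    8 and B at 7 before the Table C lookup, as on the worksheet.
    Vectorized over arrays of equal shape.
    """
    ua = np.clip(np.asarray(upper_arm, dtype=int), 1, 6) - 1
    la = np.clip(np.asarray(lower_arm, dtype=int), 1, 3) - 1
    wr = np.clip(np.asarray(wrist, dtype=int), 1, 4) - 1
    tw = np.clip(np.asarray(wrist_twist, dtype=int), 1, 2) - 1
    nk = np.clip(np.asarray(neck, dtype=int), 1, 6) - 1
    tr = np.clip(np.asarray(trunk, dtype=int), 1, 6) - 1
    lg = np.clip(np.asarray(legs, dtype=int), 1, 2) - 1
    score_a = TABLE_A[ua, la, wr, tw] + np.asarray(muscle_a) + np.asarray(force_a)
    score_b = TABLE_B[nk, tr, lg] + np.asarray(muscle_b) + np.asarray(force_b)
    grand = TABLE_C[np.clip(score_a, 1, 8) - 1, np.clip(score_b, 1, 7) - 1]
    return score_a, score_b, grand


def _side_partials(ch: Mapping[str, np.ndarray], side: str) -> dict[str, np.ndarray]:
    s = f"_{side}"
    return {
        "upper_arm": _upper_arm_score(ch[f"upper_arm_flexion{s}"],
                                      ch[f"upper_arm_abduction{s}"],
                                      ch[f"shoulder_raised{s}"]),
        "lower_arm": _lower_arm_score(ch[f"lower_arm_flexion{s}"]),
        "wrist": _wrist_score(ch[f"wrist_flexion{s}"], ch[f"wrist_deviation{s}"]),
        "wrist_twist": _wrist_twist_score(ch[f"wrist_twist{s}"]),
        "neck": _neck_score(ch["neck_flexion"], ch["neck_twist"], ch["neck_side_bend"]),
        "trunk": _trunk_score(ch["trunk_flexion"], ch["trunk_twist"], ch["trunk_side_bend"]),
        "legs": _legs_score(ch["legs_supported"]),
    }


def detect_static(trace: np.ndarray, sample_rate_hz: float,
                  window_s: float = 60.0,
                  range_thresh_deg: float = 10.0) -> np.ndarray:
    """Flag frames whose trailing ``window_s`` angle range is below threshold.

    Implements the worksheet's "static posture held > 1 min" muscle-use
    trigger on a continuous trace.  Frames without a full trailing window
    are never static.
    """
    t = np.asarray(trace, dtype=float)
    n = len(t)
    w = int(round(window_s * sample_rate_hz))
    out = np.zeros(n, dtype=bool)
    if w < 1 or n < w:
        return out
    s = pd.Series(t)
    rng = (s.rolling(w).max() - s.rolling(w).min()).to_numpy()
    out[w - 1:] = rng[w - 1:] < range_thresh_deg
    return out


def _muscle_flags(ch: Mapping[str, np.ndarray], rate: float, side: str,
                  repetitive_a: bool, repetitive_b: bool,
                  use_static_detection: bool) -> tuple[np.ndarray, np.ndarray]:
    n = len(ch["neck_flexion"])
    a = np.full(n, bool(repetitive_a))
    b = np.full(n, bool(repetitive_b))
    if use_static_detection:
        s = f"_{side}"
        for name in (f"upper_arm_flexion{s}", f"lower_arm_flexion{s}",
                     f"wrist_flexion{s}"):
            a |= detect_static(ch[name], rate)
        for name in ("neck_flexion", "trunk_flexion"):
            b |= detect_static(ch[name], rate)
    return a.astype(int), b.astype(int)


def score_series(series: JointAngleSeries,
                 force_spec: ForceLoadSpec = ForceLoadSpec(),
                 *,
                 repetitive_a: bool = False,
                 repetitive_b: bool = False,
                 use_static_detection: bool = True,
                 combine: str = "max") -> np.ndarray:
    """Per-frame grand-score trace for a whole session.

    Left and right limbs are scored separately; per frame the reported
    grand is the worse (higher) side when ``combine='max'``.
    """
    if series.n_frames == 0:
        raise ValidationError("empty series")
    ch = {c: series.data[c].to_numpy(dtype=float) for c in series.data.columns}
    rate = series.session.sample_rate_hz
    force = force_spec.force_modifier
    grands = []
    for side in ("l", "r"):
        p = _side_partials(ch, side)
        mu_a, mu_b = _muscle_flags(ch, rate, side, repetitive_a, repetitive_b,
                                   use_static_detection)
        _, _, grand = grand_from_partials(**p, muscle_a=mu_a, force_a=force,
                                          muscle_b=mu_b, force_b=force)
        grands.append(grand)
    if combine == "max":
        return np.maximum(grands[0], grands[1])
    if combine == "mean":  # informational; worksheet scores stay integer per side
        return np.mean(grands, axis=0)
    raise ValidationError(f"unknown combine {combine!r}")


def score_frame(angles: Mapping[str, float],
                force_spec: ForceLoadSpec = ForceLoadSpec(),
                static_flags: Mapping[str, bool] | None = None) -> RulaFrameScore:
    """Score a single posture; returns the worse side's full score sheet.

    ``static_flags`` may carry ``{"group_a": bool, "group_b": bool}`` for
    the muscle-use modifier (static posture held > 1 min per group).
    """
    for name, v in angles.items():
        if name not in BOOLEAN_CHANNELS and abs(float(v)) > 180.0:
            raise ValidationError(f"{name}={v} outside [-180, 180] deg")
    ch = {k: np.asarray([float(v)]) for k, v in angles.items()}
    flags = static_flags or {}
    mu_a = int(bool(flags.get("group_a", False)))
    mu_b = int(bool(flags.get("group_b", False)))
    force = force_spec.force_modifier
    best: RulaFrameScore | None = None
    for side in ("l", "r"):
        p = _side_partials(ch, side)
        score_a, score_b, grand = grand_from_partials(
            **p, muscle_a=mu_a, force_a=force, muscle_b=mu_b, force_b=force)
        fs = RulaFrameScore(
            upper_arm=int(p["upper_arm"][0]), lower_arm=int(p["lower_arm"][0]),
            wrist=int(p["wrist"][0]), wrist_twist=int(p["wrist_twist"][0]),
            neck=int(p["neck"][0]), trunk=int(p["trunk"][0]), legs=int(p["legs"][0]),
            muscle_a=mu_a, force_a=force, muscle_b=mu_b, force_b=force,
            score_a=int(score_a[0]), score_b=int(score_b[0]), grand=int(grand[0]))
        if best is None or fs.grand > best.grand:
            best = fs
    assert best is not None
    return best


def action_level_distribution(grand: np.ndarray) -> RiskDistribution:
    """Working-time distribution over the four RULA action levels.

    Grand 1-2 -> level 1, 3-4 -> level 2, 5-6 -> level 3, 7 -> level 4.
    """
    g = np.asarray(grand)
    if g.size == 0:
        raise ValidationError("empty grand trace")
    level = np.clip((g - 1) // 2, 0, 3)
    counts = np.bincount(level.astype(int), minlength=4)
    return RiskDistribution(levels=ACTION_LEVEL_LABELS, proportions=counts / g.size)


def final_rula_score(grand: np.ndarray, method: str = "mean") -> float:
    """Condense a grand-score trace into one continuous final score.

    ``mean`` (default) is the time-weighted mean grand score, preserving
    the dynamics of the whole work process on the 1-7 scale; ``mode`` and
    ``p90`` (90th percentile) are alternatives.
    """
    g = np.asarray(grand, dtype=float)
    if g.size == 0:
        raise ValidationError("empty grand trace")
    if method == "mean":
        return float(g.mean())
    if method == "mode":
        counts = Counter(g.tolist())
        top = max(counts.values())
        return float(min(k for k, v in counts.items() if v == top))
    if method == "p90":
        return float(np.percentile(g, 90))
    raise ValidationError(f"unknown method {method!r}")
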