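"""Synthetic work-shift cohort generator.

Emulates the data-generating situation of a two-capture field study: for
every worker, a pre- and a post-shift session with joint-angle streams
(workstation-dependent posture means plus sinusoidal work cycles and
Gaussian jitter), bilateral in-shoe pressure recordings driven by a cyclic
heel-to-toe gait model, unloaded baseline captures (static lace pressure),
and Borg CR-10 body-map / fatigue-VAS survey rows.

The generator's defaults mirror the study design: 24 workers (3/4
production, the rest office), two 12 min sessions, surveys for everyone,
insoles for the production workers only, a right-dominant cohort with a
programmable right/left mean-pressure ratio, a programmable pre-to-post
exertion shift (Cohen's d on the 0-10 scale), and no pre/post effect on
pressure.  Everything is reproducible from an integer seed.

The gait model is deliberately minimal — a pressure blob translating from
heel to toe over stance with a two-peaked amplitude profile (heel strike,
push-off) — its only job is to carry the statistical structure the
analysis pipeline assumes (regional loading order, side asymmetry, cyclic
loading), not biomechanical fidelity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (DEVICE_MAX_PRESSURE, InsoleRecording, JointAngleSeries,
                 REQUIRED_ANGLE_CHANNELS, Session, ValidationError,
                 write_angles, write_insole, write_layout)
from .surveys import DEFAULT_REGION_GROUPS

__all__ = [
    "CohortSpec",
    "WorkerData",
    "CohortData",
    "foot_layout",
    "simulate_gait_pressure",
    "simulate_cohort",
]

_SHOE_SIZES = (39, 41, 43, 45)
_LAYOUT_ROWS = {39: 13, 41: 14, 43: 15, 45: 16}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Effect parameters: ``post_shift_d`` and ``fatigue_shift_d`` are
    Cohen's d pre-to-post shifts on the 0-10 exertion/fatigue scales;
    ``side_asymmetry_ratio`` is the right/left mean-pressure ratio of the
    (right-dominant) cohort; ``pressure_time_effect`` is the fractional
    pre-to-post change in gait pressure amplitude (0 = none).
    """

    n_workers: int = 24
    fraction_production: float = 0.75
    seed: int = 0
    pre_exertion_mean: float = 3.49
    exertion_sd: float = 2.0
    post_shift_d: float = 0.78
    pre_fatigue_mean: float = 2.58
    fatigue_sd: float = 2.0
    fatigue_shift_d: float = 0.65
    within_subject_r: float = 0.6
    side_asymmetry_ratio: float = 1.15
    pressure_time_effect: float = 0.0
    session_s: float = 720.0
    angle_rate_hz: float = 60.0
    pressure_rate_hz: float = 100.0
    cadence_spm: float = 50.0
    base_peak_pressure: float = 30.0

    def __post_init__(self) -> None:
        if self.n_workers < 2:
            raise ValidationError("n_workers must be >= 2")
        if not 0.0 <= self.fraction_production <= 1.0:
            raise ValidationError("fraction_production must lie in [0, 1]")
        if not self.side_asymmetry_ratio > 0:
            raise ValidationError("side_asymmetry_ratio must be positive")
        for name in ("post_shift_d", "fatigue_shift_d", "pressure_time_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.session_s <= 0 or self.angle_rate_hz <= 0 or self.pressure_rate_hz <= 0:
            raise ValidationError("durations and rates must be positive")


@dataclass
class WorkerData:
    worker_id: str
    workstation: str                      # "production" | "office"
    shoe_size: int
    layout: pd.DataFrame
    angles: dict                          # phase -> JointAngleSeries
    insoles: dict                         # (phase, side) -> raw InsoleRecording
    baselines: dict                       # side -> unloaded InsoleRecording


@dataclass
class CohortData:
    """In-memory bundle of one simulated cohort; ``write`` lays it out on disk."""

    spec: CohortSpec
    workers: list
    surveys: pd.DataFrame                 # worker_id, phase, region, rating
    vas: pd.DataFrame                     # worker_id, phase, vas

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cohort_spec.json").write_text(
            json.dumps(asdict(self.spec), indent=2, sort_keys=True) + "\n")
        self.surveys.to_csv(out / "surveys.csv", index=False)
        self.vas.to_csv(out / "vas.csv", index=False)
        meta = []
        for w in self.workers:
            wd = out / w.worker_id
            wd.mkdir(exist_ok=True)
            write_layout(w.layout, wd / "layout.csv")
            for phase, series in w.angles.items():
                write_angles(series, wd / f"angles_{phase}.csv")
            for (phase, side), rec in w.insoles.items():
                write_insole(rec, wd / f"insole_{phase}_{side}.csv")
            for side, rec in w.baselines.items():
                write_insole(rec, wd / f"baseline_{side}.csv")
            meta.append({"worker_id": w.worker_id, "workstation": w.workstation,
                         "shoe_size": w.shoe_size})
        pd.DataFrame(meta).to_csv(out / "workers.csv", index=False)
        return out


def foot_layout(shoe_size: int = 43) -> pd.DataFrame:
    """Foot-shaped sensor grid in normalized coordinates for one shoe size.

    Rows run from the posterior heel (length 2 %) to the toes (98 %); six
    columns span the medial (8 %) to lateral (92 %) edge.  Larger sizes
    carry more sensor rows, mirroring the size-dependent sensor counts of
    resistive insoles.
    """
    if shoe_size not in _LAYOUT_ROWS:
        raise ValidationError(f"unsupported shoe size {shoe_size}")
    rows = _LAYOUT_ROWS[shoe_size]
    length = np.linspace(2.0, 98.0, rows)
    width = np.linspace(8.0, 92.0, 6)
    Ls, Ws = np.meshgrid(length, width, indexing="ij")
    return pd.DataFrame({
        "sensor_id": [f"s{i + 1:03d}" for i in range(Ls.size)],
        "length_pct": Ls.ravel(),
        "width_pct": Ws.ravel(),
    })


def _stance_profile(s: np.ndarray) -> np.ndarray:
    """Two-humped amplitude envelope over normalized stance time s in [0,1]."""
    heel = 0.55 * np.exp(-(((s - 0.18) / 0.14) ** 2))
    push = 0.45 * np.exp(-(((s - 0.78) / 0.16) ** 2))
    return (heel + push) / 0.55  # normalized so the heel-strike peak is 1


def simulate_gait_pressure(side: str, n_steps: int, cadence_spm: float,
                           peak_scale: float, layout: pd.DataFrame,
                           rate_hz: float = 100.0,
                           rng: np.random.Generator | None = None,
                           noise_sd: float = 0.03,
                           stance_fraction: float = 0.6,
                           worker_id: str = "synthetic",
                           phase: str = "pre") -> InsoleRecording:
    """Cyclic heel-to-toe gait pressure for one foot.

    Per step a Gaussian pressure blob travels from 10 % to 90 % foot
    length over the stance phase, modulated by a heel-strike/push-off
    amplitude envelope whose heel peak equals ``peak_scale`` (N/cm^2);
    the swing phase is unloaded.  Multiplicative frame noise of relative
    SD ``noise_sd`` is applied and values are clipped to the device range.
    """
    if cadence_spm <= 0:
        raise ValidationError("cadence must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    period = 60.0 / cadence_spm
    duration = n_steps * period
    n_frames = int(round(duration * rate_hz))
    t = np.arange(n_frames) / rate_hz
    u = (t / period) % 1.0
    in_stance = u < stance_fraction
    s = np.where(in_stance, u / stance_fraction, 0.0)
    center = 10.0 + 80.0 * s                       # % foot length
    amp = peak_scale * _stance_profile(s) * in_stance
    L = layout["length_pct"].to_numpy(dtype=float)
    W = layout["width_pct"].to_numpy(dtype=float)
    blob = np.exp(-0.5 * ((L[None, :] - center[:, None]) / 12.0) ** 2
                  - 0.5 * ((W[None, :] - 50.0) / 30.0) ** 2)
    P = amp[:, None] * blob
    P = P * (1.0 + noise_sd * rng.standard_normal(P.shape))
    P = np.clip(P, 0.0, DEVICE_MAX_PRESSURE)
    session = Session(worker_id=worker_id, phase=phase, duration_s=duration,
                      sample_rate_hz=rate_hz)
    return InsoleRecording(session=session, side=side, times=t,
                           pressures=P, layout=layout)


def _bool_trace(rng: np.random.Generator, n: int, rate_hz: float,
                duty: float, block_s: float = 5.0) -> np.ndarray:
    """0/1 trace toggling in ~block_s segments with on-probability duty."""
    block = max(1, int(round(block_s * rate_hz)))
    n_blocks = n // block + 1
    on = rng.random(n_blocks) < duty
    return np.repeat(on, block)[:n].astype(float)


# channel -> (mean, cycle amplitude, cycle period s, jitter SD), degrees
_PRODUCTION_PROFILE = {
    "trunk_flexion": (20.0, 20.0, 8.0, 2.0),
    "neck_flexion": (15.0, 12.0, 6.0, 2.0),
    "upper_arm_flexion_l": (28.0, 28.0, 5.0, 3.0),
    "upper_arm_flexion_r": (34.0, 30.0, 5.0, 3.0),
    "upper_arm_abduction_l": (10.0, 10.0, 5.0, 2.0),
    "upper_arm_abduction_r": (12.0, 12.0, 5.0, 2.0),
    "lower_arm_flexion_l": (80.0, 25.0, 5.0, 3.0),
    "lower_arm_flexion_r": (80.0, 28.0, 5.0, 3.0),
    "wrist_flexion_l": (0.0, 20.0, 2.5, 3.0),
    "wrist_flexion_r": (0.0, 22.0, 2.5, 3.0),
    "wrist_deviation_l": (0.0, 8.0, 2.5, 2.0),
    "wrist_deviation_r": (0.0, 9.0, 2.5, 2.0),
    "wrist_twist_l": (0.0, 30.0, 4.0, 5.0),
    "wrist_twist_r": (0.0, 35.0, 4.0, 5.0),
}
_OFFICE_PROFILE = {
    "trunk_flexion": (5.0, 4.0, 12.0, 1.0),
    "neck_flexion": (22.0, 6.0, 9.0, 1.5),
    "upper_arm_flexion_l": (15.0, 8.0, 6.0, 2.0),
    "upper_arm_flexion_r": (18.0, 10.0, 6.0, 2.0),
    "upper_arm_abduction_l": (5.0, 4.0, 6.0, 1.0),
    "upper_arm_abduction_r": (6.0, 5.0, 6.0, 1.0),
    "lower_arm_flexion_l": (90.0, 8.0, 6.0, 2.0),
    "lower_arm_flexion_r": (90.0, 10.0, 6.0, 2.0),
    "wrist_flexion_l": (8.0, 12.0, 3.0, 2.0),
    "wrist_flexion_r": (10.0, 14.0, 3.0, 2.0),
    "wrist_deviation_l": (0.0, 5.0, 3.0, 1.0),
    "wrist_deviation_r": (0.0, 6.0, 3.0, 1.0),
    "wrist_twist_l": (15.0, 20.0, 5.0, 3.0),
    "wrist_twist_r": (18.0, 22.0, 5.0, 3.0),
}
_BOOL_DUTY = {
    "production": {"shoulder_raised_l": 0.05, "shoulder_raised_r": 0.08,
                   "neck_twist": 0.05, "neck_side_bend": 0.05,
                   "trunk_twist": 0.10, "trunk_side_bend": 0.05,
                   "legs_supported": 1.0},
    "office": {"shoulder_raised_l": 0.01, "shoulder_raised_r": 0.02,
               "neck_twist": 0.03, "neck_side_bend": 0.02,
               "trunk_twist": 0.03, "trunk_side_bend": 0.01,
               "legs_supported": 1.0},
}


def _simulate_angles(rng: np.random.Generator, workstation: str,
                     session: Session) -> JointAngleSeries:
    n = int(round(session.duration_s * session.sample_rate_hz))
    t = np.arange(n) / session.sample_rate_hz
    profile = _PRODUCTION_PROFILE if workstation == "production" else _OFFICE_PROFILE
    data = {}
    for ch in REQUIRED_ANGLE_CHANNELS:
        if ch in profile:
            mean, amp, period, jitter = profile[ch]
            phi = rng.uniform(0, 2 * np.pi)
            trace = (mean + amp * np.sin(2 * np.pi * t / period + phi)
                     + jitter * rng.standard_normal(n))
            data[ch] = np.clip(trace, -175.0, 175.0)
        else:
            duty = _BOOL_DUTY[workstation][ch]
            data[ch] = (np.ones(n) if duty >= 1.0
                        else _bool_trace(rng, n, session.sample_rate_hz, duty))
    return JointAngleSeries(session=session, times=t,
                            data=pd.DataFrame(data, columns=list(REQUIRED_ANGLE_CHANNELS)))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               size=None) -> np.ndarray:
    """Normal draw clipped to the 0-10 response scale."""
    return np.clip(rng.normal(mean, sd, size=size), 0.0, 10.0)


def simulate_cohort(spec: CohortSpec,
                    out_dir: str | Path | None = None) -> CohortData:
    """Generate a full cohort bundle; optionally write it to ``out_dir``.

    Production workers get bilateral insole recordings plus unloaded
    baselines in both phases; all workers get angle streams and surveys.
    The exertion/fatigue post shift, the right/left pressure ratio and the
    (default zero) pre/post pressure effect are programmed per the spec
    fields, with within-subject correlation between phases.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_prod = int(round(spec.n_workers * spec.fraction_production))
    workers: list[WorkerData] = []
    survey_rows = []
    vas_rows = []
    r = spec.within_subject_r
    regions = list(DEFAULT_REGION_GROUPS)
    group_offset = {"UE": 0.5, "core": 0.0, "LE": -0.5}

    n_steps = max(1, int(round(spec.session_s / (60.0 / spec.cadence_spm))))
    base_block_s = 5.0  # baseline capture length

    for i in range(spec.n_workers):
        wid = f"w{i + 1:03d}"
        workstation = "production" if i < n_prod else "office"
        shoe_size = int(rng.choice(_SHOE_SIZES))
        layout = foot_layout(shoe_size)

        angles = {}
        insoles = {}
        baselines = {}

        # worker-level gait amplitude, shared by both sides so the
        # programmed right/left ratio survives between-subject variance
        base_amp = spec.base_peak_pressure * float(np.exp(rng.normal(0.0, 0.2)))
        lace = rng.uniform(0.2, 1.2, size=len(layout))

        for phase in ("pre", "post"):
            session = Session(worker_id=wid, phase=phase,
                              duration_s=spec.session_s,
                              sample_rate_hz=spec.angle_rate_hz)
            angles[phase] = _simulate_angles(rng, workstation, session)

        if workstation == "production":
            for phase in ("pre", "post"):
                time_factor = (1.0 + spec.pressure_time_effect
                               if phase == "post" else 1.0)
                for side in ("left", "right"):
                    side_factor = (spec.side_asymmetry_ratio
                                   if side == "right" else 1.0)
                    session_noise = float(np.exp(rng.normal(0.0, 0.05)))
                    amp = base_amp * side_factor * time_factor * session_noise
                    rec = simulate_gait_pressure(
                        side, n_steps, spec.cadence_spm, amp, layout,
                        rate_hz=spec.pressure_rate_hz, rng=rng,
                        worker_id=wid, phase=phase)
                    raw = np.clip(rec.pressures + lace[None, :],
                                  0.0, DEVICE_MAX_PRESSURE)
                    insoles[(phase, side)] = InsoleRecording(
                        session=rec.session, side=side, times=rec.times,
                        pressures=raw, layout=layout)
            for side in ("left", "right"):
                nb = int(round(base_block_s * spec.pressure_rate_hz))
                tb = np.arange(nb) / spec.pressure_rate_hz
                noise = np.abs(rng.normal(0.0, 0.03, size=(nb, len(layout))))
                baselines[side] = InsoleRecording(
                    session=Session(worker_id=wid, phase="pre",
                                    duration_s=base_block_s,
                                    sample_rate_hz=spec.pressure_rate_hz),
                    side=side, times=tb,
                    pressures=np.clip(lace[None, :] + noise, 0.0,
                                      DEVICE_MAX_PRESSURE),
                    layout=layout)

        # surveys: correlated pre/post latents with the programmed d shifts
        z_pre, z_ind = rng.standard_normal(2)
        e_pre = spec.pre_exertion_mean + spec.exertion_sd * z_pre
        e_post = (spec.pre_exertion_mean + spec.post_shift_d * spec.exertion_sd
                  + spec.exertion_sd * (r * z_pre + np.sqrt(1 - r ** 2) * z_ind))
        z_pre_f, z_ind_f = rng.standard_normal(2)
        f_pre = spec.pre_fatigue_mean + spec.fatigue_sd * z_pre_f
        f_post = (spec.pre_fatigue_mean + spec.fatigue_shift_d * spec.fatigue_sd
                  + spec.fatigue_sd * (r * z_pre_f + np.sqrt(1 - r ** 2) * z_ind_f))
        for phase, latent in (("pre", e_pre), ("post", e_post)):
            for region in regions:
                val = latent + group_offset[DEFAULT_REGION_GROUPS[region]] \
                    + rng.normal(0.0, 0.8)
                rating = float(np.round(np.clip(val, 0.0, 10.0) * 2) / 2)
                survey_rows.append({"worker_id": wid, "phase": phase,
                                    "region": region, "rating": rating})
        for phase, latent in (("pre", f_pre), ("post", f_post)):
            vas_rows.append({"worker_id": wid, "phase": phase,
                             "vas": float(np.round(np.clip(latent, 0.0, 10.0), 1))})

        workers.append(WorkerData(worker_id=wid, workstation=workstation,
                                  shoe_size=shoe_size, layout=layout,
                                  angles=angles, insoles=insoles,
                                  baselines=baselines))

    cohort = CohortData(spec=spec, workers=workers,
                        surveys=pd.DataFrame(survey_rows),
                        vas=pd.DataFrame(vas_rows))
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
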