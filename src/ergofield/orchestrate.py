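"""End-to-end study runner: score every session, compute pressure kinetics,
and run the pre/post and left/right repeated-measures comparisons.

``run_study`` consumes a cohort bundle (in memory from
:func:`ergofield.synthetic.simulate_cohort`, or loaded from a directory
with matching CSV exports) and emits the study's reporting shapes:

* a final-score table (mean +/- SD of the continuous RULA and CUELA
  scores per phase),
* a loaded-sensor percentage table by side x phase,
* a per-region impulse table by side x phase with signed post-minus-pre
  differences,
* the survey composites and their rmANOVA, and
* rmANOVA effect tables (time, side, time x side) for every kinetic
  variable, with Bonferroni post hocs.

Table outputs are rounded to two decimals; the tidy machine-readable
frames keep full precision.  Re-running on the same inputs is
deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cuela, plantar, rula, stats
from .io import (InsoleRecording, read_angles, read_insole, read_layout,
                 ValidationError)
from .surveys import BodyMapRating, composite_scores
from .synthetic import CohortData, CohortSpec, WorkerData

__all__ = ["StudyReport", "run_study", "load_cohort"]

log = logging.getLogger("ergofield")

KINETIC_VARS = ("mean_pressure", "peak_pressure", "impulse", "loaded_time_fraction")


@dataclass
class StudyReport:
    scores: pd.DataFrame            # worker x phase RULA/CUELA finals
    survey_composites: pd.DataFrame
    pressure_metrics: pd.DataFrame  # tidy worker x phase x side x region
    foot_metrics: pd.DataFrame      # whole-foot kinetics per worker x phase x side
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    anova: pd.DataFrame             # stacked effects, column 'variable'
    posthoc: pd.DataFrame
    run_log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("scores", "survey_composites", "pressure_metrics",
                     "foot_metrics", "anova", "posthoc"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        for name in ("table1", "table2", "table3"):
            getattr(self, name).round(2).to_csv(out / f"{name}.csv")
        (out / "run_log.json").write_text(
            json.dumps(self.run_log, indent=2, sort_keys=True, default=str) + "\n")
        return out


def load_cohort(bundle_dir: str | Path) -> CohortData:
    """Load a cohort bundle previously written by ``CohortData.write``."""
    root = Path(bundle_dir)
    spec = CohortSpec(**json.loads((root / "cohort_spec.json").read_text()))
    meta = pd.read_csv(root / "workers.csv")
    workers = []
    for row in meta.itertuples():
        wd = root / row.worker_id
        layout = read_layout(wd / "layout.csv")
        angles = {}
        insoles = {}
        baselines = {}
        for phase in ("pre", "post"):
            angles[phase] = read_angles(wd / f"angles_{phase}.csv",
                                        worker_id=row.worker_id, phase=phase)
            for side in ("left", "right"):
                p = wd / f"insole_{phase}_{side}.csv"
                if p.exists():
                    insoles[(phase, side)] = read_insole(
                        p, wd / "layout.csv", side=side,
                        worker_id=row.worker_id, phase=phase)
        for side in ("left", "right"):
            p = wd / f"baseline_{side}.csv"
            if p.exists():
                baselines[side] = read_insole(p, wd / "layout.csv", side=side,
                                              worker_id=row.worker_id, phase="pre")
        workers.append(WorkerData(worker_id=row.worker_id,
                                  workstation=row.workstation,
                                  shoe_size=int(row.shoe_size), layout=layout,
                                  angles=angles, insoles=insoles,
                                  baselines=baselines))
    return CohortData(spec=spec, workers=workers,
                      surveys=pd.read_csv(root / "surveys.csv"),
                      vas=pd.read_csv(root / "vas.csv"))


def _survey_table(cohort: CohortData) -> pd.DataFrame:
    rows = []
    for (wid, phase), grp in cohort.surveys.groupby(["worker_id", "phase"]):
        rating = BodyMapRating(ratings=dict(zip(grp["region"], grp["rating"])))
        comp = composite_scores(rating)
        rows.append({"worker_id": wid, "phase": phase, **comp})
    df = pd.DataFrame(rows)
    return df.merge(cohort.vas, on=["worker_id", "phase"], how="left")


def _phase_anova(df: pd.DataFrame, dv: str, variable: str) -> pd.DataFrame:
    res = stats.rm_anova(df, dv=dv, within=["phase"], subject="worker_id")
    res.insert(0, "variable", variable)
    return res


def run_study(cohort: CohortData, *,
              force_spec: rula.ForceLoadSpec = rula.ForceLoadSpec(),
              zone_thresholds: cuela.ZoneThresholds | None = None,
              rula_method: str = "mean",
              strict: bool = False) -> StudyReport:
    """Run the full analysis on a cohort bundle.

    Workers with incomplete session data are skipped with a warning, or
    raise under ``strict=True``.
    """
    zone_thresholds = zone_thresholds or cuela.default_thresholds()
    score_rows = []
    metric_rows = []
    foot_rows = []
    for w in cohort.workers:
        if set(w.angles) != {"pre", "post"}:
            msg = f"{w.worker_id}: missing angle session(s) {set(w.angles) ^ {'pre', 'post'}}"
            if strict:
                raise ValidationError(msg)
            log.warning("skipping %s", msg)
            continue
        for phase in ("pre", "post"):
            series = w.angles[phase]
            grand = rula.score_series(series, force_spec)
            dist = rula.action_level_distribution(grand)
            cres = cuela.cuela_score(series, zone_thresholds)
            score_rows.append({
                "worker_id": w.worker_id, "workstation": w.workstation,
                "phase": phase,
                "rula_final": rula.final_rula_score(grand, rula_method),
                "cuela_final": cres.final_score,
                **{f"rula_level{j + 1}": p
                   for j, p in enumerate(dist.proportions)},
                **{f"cuela_{z}": p
                   for z, p in zip(cuela.ZONE_LABELS, cres.distribution.proportions)},
            })
        if not w.insoles:
            continue
        expected = {(p, s) for p in ("pre", "post") for s in ("left", "right")}
        if set(w.insoles) != expected or set(w.baselines) != {"left", "right"}:
            msg = f"{w.worker_id}: incomplete insole data"
            if strict:
                raise ValidationError(msg)
            log.warning("skipping %s", msg)
            continue
        for (phase, side), raw in sorted(w.insoles.items()):
            rec = plantar.zero_calibrate(raw, w.baselines[side])
            rec = plantar.exclude_rear_lateral(rec, w.shoe_size)
            masks = plantar.assign_regions(rec.layout, rec.excluded)
            rm = plantar.region_metrics(rec, masks)
            for region, vals in rm.iterrows():
                metric_rows.append({"worker_id": w.worker_id, "phase": phase,
                                    "side": side, "region": region,
                                    **vals.to_dict()})
            foot = plantar.region_metrics(
                rec, {"foot": rec.active_sensors()})
            foot_rows.append({"worker_id": w.worker_id, "phase": phase,
                              "side": side, **foot.loc["foot"].to_dict(),
                              "loaded_sensor_pct":
                                  plantar.loaded_sensor_pct(rec)})

    scores = pd.DataFrame(score_rows)
    metrics = pd.DataFrame(metric_rows)
    foot = pd.DataFrame(foot_rows)
    surveys = _survey_table(cohort)

    # Table analogues --------------------------------------------------
    table1 = scores.groupby("phase")[["rula_final", "cuela_final"]].agg(
        ["mean", "std"]).reindex(["pre", "post"])

    if not foot.empty:
        table2 = (foot.groupby(["phase", "side"])["loaded_sensor_pct"]
                  .agg(["mean", "std"])
                  .reindex([("pre", "left"), ("pre", "right"),
                            ("post", "left"), ("post", "right")]))
    else:
        table2 = pd.DataFrame()

    if not metrics.empty:
        imp = metrics.pivot_table(index=["side", "region"], columns="phase",
                                  values="impulse", aggfunc=["mean", "std"])
        table3 = pd.DataFrame({
            "pre_mean": imp[("mean", "pre")], "pre_sd": imp[("std", "pre")],
            "post_mean": imp[("mean", "post")], "post_sd": imp[("std", "post")],
        })
        table3["difference"] = table3["post_mean"] - table3["pre_mean"]
    else:
        table3 = pd.DataFrame()

    # Inference --------------------------------------------------------
    anovas = []
    posthocs = []
    for dv, name in (("total", "exertion_total"), ("UE", "exertion_UE"),
                     ("core", "exertion_core"), ("LE", "exertion_LE"),
                     ("vas", "fatigue_vas")):
        anovas.append(_phase_anova(surveys, dv, name))
    ph = stats.bonferroni_posthoc(surveys, dv="total", within="phase",
                                  subject="worker_id", pairs=[("post", "pre")])
    ph.insert(0, "variable", "exertion_total")
    posthocs.append(ph)
    ph = stats.bonferroni_posthoc(surveys, dv="vas", within="phase",
                                  subject="worker_id", pairs=[("post", "pre")])
    ph.insert(0, "variable", "fatigue_vas")
    posthocs.append(ph)

    for dv in ("rula_final", "cuela_final"):
        anovas.append(_phase_anova(scores, dv, dv))

    if not foot.empty:
        for dv in KINETIC_VARS:
            res = stats.rm_anova(foot, dv=dv, within=["phase", "side"],
                                 subject="worker_id")
            res.insert(0, "variable", dv)
            anovas.append(res)
            collapsed = (foot.groupby(["worker_id", "side"], as_index=False)[dv]
                         .mean())
            ph = stats.bonferroni_posthoc(collapsed, dv=dv, within="side",
                                          subject="worker_id",
                                          pairs=[("right", "left")])
            ph.insert(0, "variable", dv)
            posthocs.append(ph)

    anova = pd.concat(anovas, ignore_index=True)
    posthoc = pd.concat(posthocs, ignore_index=True)
    run_log = {
        "spec": cohort.spec.__dict__,
        "force_spec": force_spec.__dict__,
        "rula_method": rula_method,
        "n_workers_scored": int(scores["worker_id"].nunique()) if not scores.empty else 0,
        "n_workers_insole": int(foot["worker_id"].nunique()) if not foot.empty else 0,
    }
    return StudyReport(scores=scores, survey_composites=surveys,
                       pressure_metrics=metrics, foot_metrics=foot,
                       table1=table1, table2=table2, table3=table3,
                       anova=anova, posthoc=posthoc, run_log=run_log)
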