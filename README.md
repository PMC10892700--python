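# ergofield

Field-ergonomics analytics for wearable-sensor studies of occupational
load: continuous **RULA** and **CUELA** risk scoring from IMU joint-angle
streams, six-region **in-shoe plantar pressure** kinetics, **Borg CR-10 /
fatigue-VAS** survey composites, and the repeated-measures statistics
that compare pre- vs post-shift measurements and left vs right sides.

It is written for ergonomists and movement scientists who capture whole
work processes with inertial suits and pressure insoles and want
worksheet-grade risk scores and foot kinetics computed per frame instead
of from a single observed posture.

## What it computes

**RULA (Rapid Upper Limb Assessment).** Each frame's joint angles are
binned into the worksheet partial scores (upper arm, lower arm, wrist,
wrist twist, neck, trunk, legs), combined through lookup Tables A and B
with muscle-use and force modifiers (A = Table A + μ_A + f_A,
B = Table B + μ_B + f_B), and mapped to the grand score
C = TableC[min(A,8), min(B,7)] ∈ [1, 7]. Left and right limbs are scored
separately; per frame the worse side counts. The session result is the
working-time distribution over the four action levels (grand 1–2, 3–4,
5–6, 7) and a continuous final score — by default the time-weighted mean
of the per-frame grand scores, so the dynamics of the whole process are
preserved on the 1–7 scale. Static postures held longer than one minute
are detected from the angle traces (trailing 60 s range < 10°) and feed
the muscle-use modifier.

**CUELA.** Each angle channel is categorized per frame into green
(acceptable), yellow (limited acceptable) or red (unacceptable) zones
from an editable threshold table; the frame zone is the worst channel.
The session yields the zone time distribution and a continuous score
`1·p_green + 2·p_yellow + 3·p_red ∈ [1, 3]`, which makes the
three-zone distribution comparable to a RULA-style single score.

**Plantar pressure.** Recordings are zero-calibrated against an unloaded
baseline, rear-lateral sensors are excluded by shoe size (3–5 for EU
39–45), and the foot is segmented into rearfoot / midfoot / metatarsal
heads / forefoot (0–30 / 30–60 / 60–80 / 80–100 % foot length) and inner
/ outer foot (0–60 / 60–100 % width). Per region: mean pressure over
loaded frames, peak pressure (mean of per-sensor maxima), the
pressure-time impulse ∑ p·Δt (Ns/cm²), loaded-time fraction and the
percentage of loaded sensors.

**Statistics.** Shapiro–Wilk screening, one- and two-factor
repeated-measures ANOVA with Greenhouse–Geisser correction (ε from the
contrast-score covariance; ε ≡ 1 for two-level factors, where
F = t²_paired), partial η² = SS_effect/(SS_effect+SS_error) with Cohen's
bands, and Bonferroni-adjusted paired contrasts with simultaneous CIs.
No outlier exclusion, α = 0.05.

**Synthetic cohorts.** Because raw field recordings are rarely shareable,
`ergofield.synthetic` generates complete work-shift bundles — angle
streams, cyclic heel-to-toe gait pressure for both feet, baselines and
surveys — with programmable exertion shift (Cohen's d), right/left
pressure ratio and pre/post pressure effect, fully reproducible from a
seed.

## Worked example

```bash
printf '{"n_workers": 4, "session_s": 10.0, "seed": 4}\n' > tiny_spec.json
ergofield simulate --out demo --spec tiny_spec.json
ergofield score-rula --angles demo/w001/angles_pre.csv
```

```
final RULA score (mean): 3.10
  acceptable: 8.8%
  measures in the near future: 90.8%
  measures shortly: 0.3%
  measures directly: 0.0%
```

Worker w001's simulated production shift spends ~91 % of frames at
action level 2 (grand scores 3–4): postures that warrant intervention in
the near future, averaging to a continuous score of 3.10 on the 1–7
scale. The same session under CUELA:

```
$ ergofield score-cuela --angles demo/w001/angles_pre.csv
final CUELA score: 2.12
  green: 2.3%
  yellow: 83.0%
  red: 14.7%
```

i.e. mostly "limited acceptable" joint-angle zones (score 2.12 on the
1–3 scale). Pressure kinetics for the left insole:

```
$ ergofield pressure --recording demo/w001/insole_pre_left.csv \
    --baseline demo/w001/baseline_left.csv --layout demo/w001/layout.csv --size 43
region            mean_pressure  peak_pressure  impulse  loaded_time_fraction  loaded_sensor_pct
rearfoot                  8.515         17.052   18.921                 0.221              100.0
midfoot                   3.801         10.226   14.825                 0.391              100.0
...
```

Rearfoot peak pressure exceeds midfoot, as expected for heel-strike
dominated gait; the impulse column weights sustained moderate loading
rather than transient peaks. `ergofield run-study --bundle demo --out
report` then produces the cohort tables (final scores by phase, loaded
sensor percentages by side × phase, per-region impulse with signed
post-minus-pre differences) and the full rmANOVA effects table.

## Layout

```
src/ergofield/
  io.py         CSV readers/writers, Session / JointAngleSeries / InsoleRecording, windowing
  rula.py       worksheet tables (data/rula_tables.json), per-frame scoring, action levels
  cuela.py      zone thresholds (data/cuela_thresholds.csv), zone distributions
  plantar.py    calibration, sensor exclusion, region masks, kinetic metrics
  surveys.py    Borg CR-10 body-map composites, exertion/fatigue bands
  stats.py      Shapiro screen, rmANOVA + GG, partial eta^2, Bonferroni post hocs
  synthetic.py  cohort and gait-pressure generators
  orchestrate.py  run_study end-to-end runner
  cli.py        typer front-end (ergofield simulate|score-rula|score-cuela|pressure|run-study)
```
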