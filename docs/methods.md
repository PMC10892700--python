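# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what its synthetic data can and cannot show.

## Continuous RULA scoring

The classic RULA worksheet grades a single observed posture. Here every
captured frame is graded and the session is summarized by the
distribution of working time over the four action levels plus one
continuous final score.

**Angle bins.** The worksheet's verbal categories are encoded as angle
cut points in `data/rula_tables.json` (editable). Flexion is positive,
extension negative. Cut points follow the published worksheet: upper arm
1 within ±20°, 2 to 45° (or extension beyond −20°), 3 to 90°, 4 above;
lower arm 1 within 60–100°; wrist 2 within ±15°, 3 beyond; neck 1 to
10°, 2 to 20°, 3 beyond, 4 in extension; trunk 2 to 20°, 3 to 60°, 4
beyond. Two categories the worksheet defines only at exactly 0°
(wrist "1 if neutral", trunk "1 if upright") get a ±5° tolerance band,
because a continuous IMU trace is almost never exactly zero; without a
band those scores would be unreachable. Judgement items without a
printed angle (shoulder raised, twists, side bends, leg support) travel
as 0/1 channels in the export; upper-arm abduction and wrist deviation
are thresholded at 45° and 10°. The lower-arm midline modifier has no
corresponding export channel and is omitted. All bins are closed on the
safer (lower-score) side.

**Modifiers.** Muscle use adds +1 to the A score (arms/wrists) or B
score (neck/trunk/legs) when any contributing channel is static —
trailing 60 s range below 10° — or when a repetition flag is set in the
call; automatic repetition counting is out of scope. Force adds 0 / +1
/ +2 for <2 kg / 2–10 kg / >10 kg, escalated by +1 when the load is
static or repeated.

**Bilateral combination.** Left and right are scored independently per
frame and the worse side is kept (`combine="max"`). A mean-of-sides
variant exists but is informational: the max is the conservative choice
when the instrument itself gives no combination rule.

**Final score.** The default transfer from the action-level distribution
to one number is the time-weighted mean of per-frame grand scores. It is
continuous (cohort means need not be integers), bounded by the observed
min/max grand, and reduces to the worksheet score for a static posture.
A mode and a 90th-percentile variant are selectable where a
worst-dominated summary is wanted.

## CUELA zones

Zone bands per channel live in `data/cuela_thresholds.csv` as
`green_lo, green_hi, yellow_lo, yellow_hi` with yellow enclosing green
and red elsewhere. The shipped defaults encode common ergonomic ranges
(e.g. trunk flexion green to 20°, yellow to 60°; neck green to 25°,
yellow to 45°); the authoritative DGUV tables are not public tabular
data, so the file is meant to be edited to the user's instrument.
Boundaries are closed on the greener side (exactly 20° trunk flexion is
green) — a deterministic tie-break that gives the benefit of the doubt
to the safer category. The frame zone is the worst channel zone; the
final score is the zone-weighted distribution `1·p_g + 2·p_y + 3·p_r`,
a linear map that puts the three-zone result on a bounded 1–3 scale
comparable in spirit to the RULA score.

## Plantar pressure kinetics

Coordinates: foot length 0 % at the posterior heel, width 0 % at the
medial edge, so "inner foot 0–60 % width" is medial as anatomy requires.
Region cut points are treated as contiguous real intervals, upper-closed
(a sensor at exactly 30 % length is rearfoot); no sensor can fall in a
gap, and the four longitudinal masks exactly partition the active
sensors, as do the two width masks.

Calibration subtracts the per-sensor mean of an unloaded sitting
baseline and clamps negatives to zero. Rear-lateral exclusion removes
the k most posterior-lateral sensors (ranked by ascending length, then
descending width), k = 3/4/4/5 for EU 39/41/43/45 — these sensors read
shell curvature of the safety-shoe heel guidance, not foot load.

"Loaded" means ≥ 0.6 N/cm², the lower bound of the device's measurement
range; readings below it are within sensor noise. Mean pressure averages
each sensor over its *loaded* frames before averaging over sensors, so
long unloaded (swing/idle) periods do not dilute the level of load that
actually occurs; a `mean_over="all"` switch restores whole-recording
means, since either denominator is defensible. A sensor never loaded
contributes 0. A sensor counts as "loaded" for the loaded-sensor
percentage when it exceeds the threshold in at least 1 % of frames —  a
single-frame criterion would be noise-fragile. Peak pressure is the mean
of per-sensor maxima (not the single regional maximum), and the impulse
is the per-sensor time integral ∑ p·Δt averaged over member sensors. The
impulse is additive over time windows and linear in pressure and Δt,
which the property tests assert.

## Statistics

One- and two-factor within-subject ANOVA is computed from the cell-means
sum-of-squares decomposition, each effect tested against its own
effect×subject interaction. Greenhouse–Geisser ε is computed from the
covariance of the effect's orthonormal (Helmert) contrast scores,
ε = tr(S)² / (r·tr(S²)), clipped to [1/r, 1]; for two-level factors
ε = 1 exactly and F equals the squared paired-t statistic. Corrected
p-values use the ε-scaled F distribution. Effect size is partial η²;
pingouin serves as an independent cross-check in the test suite, never
as the implementation, and the SS terms are exposed (`ss_effect`,
`ss_error`, `.attrs["ss_subjects"]`, `.attrs["ss_total"]`) so the
decomposition can be audited. Degenerate inputs: a 0/0 F (identical
conditions) is reported as F = 0, p = 1; a zero-variance Shapiro–Wilk
input is reported as non-computable rather than raising mid-pipeline.
Missing cells are an error — no imputation. Normality screening is
attached as metadata and never gates the ANOVA (repeated-measures ANOVA
is robust to that violation alone), and no outliers are excluded.
Bonferroni post hocs report the paired mean difference with the CI at
the adjusted level 1−α/m and p_adj = min(1, m·p); α = 0.05 throughout.
The time×side interaction is computed and reported but flagged
informational — the analysis questions are the two main effects.

## Synthetic cohorts

The generator reproduces the study *design*, not any worker's data: 24
workers (75 % production, the rest office), two sessions per worker,
surveys for all, bilateral insoles plus baselines for production workers
only. Defaults (all `CohortSpec` fields): pre-shift exertion mean 3.49
(SD 2.0) with a post shift of d = 0.78 and within-subject correlation
0.6 between phases; fatigue VAS pre 2.58 with d = 0.65; right/left
mean-pressure ratio 1.15 applied to a shared per-worker gait amplitude
(lognormal, ~30 N/cm² heel peak) so the ratio survives between-subject
variance; pre/post pressure effect 0; 12 min sessions at 60 Hz (angles)
and 100 Hz (insoles); cadence 50 steps/min; shoe sizes drawn from
{39, 41, 43, 45} with size-dependent sensor counts (78–96 of a possible
240). Ratings are quantized to the half-point grid of the response
scale and truncated to [0, 10].

The gait model is a Gaussian pressure blob translating from 10 % to
90 % foot length over a 60 % stance phase, amplitude-modulated by a
two-humped heel-strike/push-off envelope, with 3 % multiplicative frame
noise, clipped to the 0–64 N/cm² device range; swing is unloaded.
Static lace pressure (uniform 0.2–1.2 N/cm² per sensor) is added to raw
recordings and captured in the baselines, exercising the calibration
path.

What this does **not** emulate: postural transitions between tasks,
standing/idle periods (the synthetic workers walk continuously, so
absolute impulse magnitudes are larger than in a mixed work shift),
sensor drift and saturation, step-to-step timing variability, or any
biomechanically validated pressure distribution. Passing tests
therefore demonstrate that the pipeline recovers statistical structure
it is pointed at (shifts, asymmetries, null effects) at field-study
sample sizes — not that it has been validated against real insole or
IMU recordings.

## Problem sizes in tests and scripts

Tests and the acceptance script run the cohort generator with shortened
sessions (6–60 s instead of the 12 min design default, which is kept in
`CohortSpec.session_s`): all pipeline quantities are time-normalized or
per-frame except the impulse, whose contrasts are invariant to session
length. The stochastic parameter-recovery check runs 100 cohorts at
study scale (n = 24 surveys, n = 18 insole workers, seeds 1–100) with
12 s sessions; effect parameters are the design defaults above.

## Known limitations

* Worksheet angle bins and zone thresholds are shipped as editable data
  because the primary instruments publish categories, not machine-ready
  tables; users should verify them against their local standard.
* No shear forces, no center-of-pressure or spatiotemporal gait
  parameters, no moment/force-based zone evaluation — the pipeline is
  posture- and vertical-pressure-based by design.
* Repetition (cycles/min) is a user-supplied flag, not detected.
* The CUELA↔RULA comparability mapping is a bounded linear proposal,
  not a calibrated equivalence.
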