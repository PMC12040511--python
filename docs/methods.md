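# Methods

This note documents the models and numerical choices behind `cmtcalf`:
what the synthetic generator assumes, how it was calibrated, what the
analysis operations compute, and what a green test does and does not
establish.

## Quantification

A visit is a single axial calf slice: a fat-fraction map (percent,
0-100) and an integer label map on the same pixel grid, codes 1-6 for
the right-side muscles (tibialis anterior, peroneus longus, lateral
gastrocnemius, medial gastrocnemius, soleus, posterior tibial group)
and 7-12 for the left. Per muscle ROI:

* `ff_mean` — arithmetic mean of ROI pixels; NaN pixels are excluded
  from the mean but kept in the area (they are segmented tissue with a
  failed fit) and counted.
* `csa = n_pixels * pixel_area` (mm² internally; cm² only in report
  tables, factor 100).
* `rma = csa * (100 - ff_mean) / 100` — remaining muscle area, a
  contractile-tissue proxy. The formula is validated against the
  published control-group baselines (117.4 cm² at 3.24 % → 113.6 cm²).

The whole-calf summary weights each included muscle's FF by its CSA
over all 12 ROIs of both sides jointly (whether the in-vivo analysis
averaged legs first is not documented; joint weighting is our
interpretation of a "bilateral" summary). Within one visit, summing
per-muscle RMA equals applying the RMA formula to the summary CSA and
weighted FF — an exact identity by linearity. Across subjects the
order of aggregation matters: severe patients have high FF *and* low
CSA, so the mean of per-subject RMAs exceeds the RMA of the group
means; the test suite reproduces this gap, which is also visible in
the published patient baseline row.

Artifact policy: exclusion is whole-muscle, never pixelwise. In
synthetic mode a muscle is excluded when the artifact mask covers more
than 5 % of its ROI; in real-data mode the flag is user-supplied. The
quantifier trusts the label map (neurovascular exclusion is the
mask-maker's job); maps must share one grid, and no interpolation is
performed.

## Grading

The modified Mercuri scale is mapped from fat fraction by fixed bands:
grade 0 below 2.5 %, 1 at [2.5, 15), 2 at [15, 30), 3 at [30, 60),
4 at [60, 90), 5 at ≥ 90 %. Grades 2-4 follow the published fat-volume
bands (<30 %, 30-60 %, >60 %); the 0/1 and 5 cut-offs are our choice,
set so healthy-control FF (~3 %) grades 0-1 and grade 5 means almost
no residual muscle. Boundaries belong to the upper grade. Rater noise
is modelled as a ±1-step misgrade with fixed probability (default 0.10
in cohort simulation), clipped to [0, 5]. STIR hyperintensity is
simulated at the observed prevalences (patients: 9 % mild, 1 % marked;
controls: 6 % mild, none marked), persistent per muscle across visits.

## Responsiveness

Visit timings scatter, so change scores are linearly prorated to the
nominal interval of their visit (12, 27 or 49 months):
`standardized = raw * nominal / actual`. Linearity is the minimal
reading of interval conversion and is exact for subject-constant
rates over short horizons.

Within-group change is tested against zero: Shapiro-Wilk on the
changes (p > 0.05 → paired t-test, otherwise Wilcoxon signed-rank; the
paired analogue is used deliberately where the source nomenclature
says "rank sum"). All tests are two-sided at α = 0.05. The SRM
(mean change / SD of change) is categorised by Cohen's bands on its
magnitude and suppressed ("n.a.") when the change is not significant
or n < 5, matching natural-history table conventions; n = 2 groups
report a mean only (no normality check is possible below n = 3).
Zero-variance changes are flagged degenerate rather than given an SRM.

Baseline strata partition [0, 100] %ff as normal [0, 5), intermediate
[5, 70], end stage (70, 100]; boundary values at 5 belong to
intermediate, at 70 to intermediate, consistent with the verbal
definitions "<5", "5-70", ">70".

## The synthetic cohort

The generator's defaults state the published study design: 20 patients
and 20 controls, four visits with actual timings drawn around
0/12.4/27.4/47.2 months (SDs 0/1.0/2.2/7.1; visit four truncated to
the observed 34.9-56.8 month range) while standardization uses the
nominal 0/12/27/49; monotone dropout with per-follow-up probabilities
(0.15, 0.18, 0.28) approximating the observed attrition 20→17→14→10.

**Progression law.** True muscle FF follows logistic growth
`dF/dt = r F (1 - F/100)` (closed form
`F(t) = 100 / (1 + ((100-F0)/F0) e^{-rt})`), one rate `r` per subject,
lognormal across subjects with median 0.142/yr and log-SD 0.6 — the
median calibrated so a muscle at 17 %ff gains ≈ 2 %ff in a year. This
single-parameter law reproduces the observed three-band behaviour:
slow progression below 5 %, fastest progression at intermediate FF,
and an end-stage plateau approached near saturation.

**Baseline severity.** A subject's baseline whole-calf FF comes from a
three-component mixture matching the published strata (probabilities
0.5/0.4/0.1): normal N(2.33, 1.41²) truncated to (0.5, 5); end stage
N(81.33, 1.49²) truncated to (70, 100); intermediate a two-component
form — a truncated lognormal bulk at low FF (log-median 10.7) plus an
11 % high-FF tail N(57, 7²) on [40, 70] — jointly fitted to the
published stratum moments 17.16 ± 15.10 (a single truncated lognormal
cannot reach that SD at that mean). Controls draw FF from
N(3.24, 1.60²) truncated to (0.5, 6) with r = 0 (noise only).
Per-muscle baselines scatter around the subject's severity on a
log-odds scale with an anatomical gradient (peroneus longus worst,
then tibialis anterior and medial gastrocnemius, soleus best); a
common offset is solved per subject so the CSA-weighted summary equals
the drawn baseline exactly.

**Measurement noise.** Observed per-muscle FF adds Gaussian noise of
SD 1 %ff, rising to 2 %ff above 70 %ff where segmentation of residual
tissue is unreliable; observations are clipped to [0, 100]. With the
default CSA weights this yields a summary-FF test-retest SD of
≈ 0.35 %ff, which reproduces the published control change SD
(0.49 %ff at 12 months) almost exactly.

**Atrophy.** Total baseline calf CSA is `C0 e^{-1.45 FF0/100}` with
`C0` lognormal around 123 cm² (CV 20 %), times 0.92 for patients
(neurogenic atrophy beyond fat replacement); this reproduces the
published control (117.4 cm²) and patient (≈ 93 cm²) baselines and the
FF-CSA covariance. Over time `CSA(t) = CSA0 (1 - (F(t)-F0)/100)`, so
RMA falls faster than CSA. Per-muscle CSA observation noise is 9 % CV,
matching the published control change SDs.

**Clinical coupling.** A latent severity scalar ties the CMTES to FF:
`latent0 = 3.5 + 2.5 ln(FF0) + N(0, 2.2²)`, drifting at
`0.6 * (r F0 (1-F0/100)) / 1.278` points/year — i.e. proportional to
the subject's initial fat-accumulation rate, normalised so the
patient-mixture mean drift is the observed 0.6 points/year. Observed
CMTES adds N(0, 0.9²) and rounds/clips to [0, 28]. This one shared
rate is what the bridging analysis detects; `couple_progression=False`
replaces the drift by an independent draw from the same marginal
(the falsifiability ablation). The coupling constants were chosen to
reproduce the printed cross-sectional (ρ ≈ 0.8) and bridging
(ρ ≈ 0.65-0.71) correlation magnitudes; they are a modelling choice,
not an estimate from data. MRC sum score and SF-36 are carried as
opaque columns with plausible moments and no time trend.

**Reproducibility.** All randomness flows from one master seed through
per-subject `SeedSequence` sub-streams keyed by (group, index), so a
given subject is identical in cohorts of different sizes and identical
seed + config gives byte-identical tables.

**Images.** `render_visit_image` paints non-overlapping ellipses
(areas roughly proportional to each muscle's CSA share) on a
schematic two-leg layout, with optional pixel noise and injected
artifact patches; it exists to exercise the ROI chain, not to look
like anatomy. NIfTI export uses isotropic in-plane spacing equal to
the square root of the pixel area.

## Validity analyses

The pooled FF-CMTES correlation uses all subject-visits of the patient
group with no clustering correction — deliberately mirroring the
in-vivo analysis; the resulting n overstates the effective sample
size, a known limitation. "Rate of progression" is (last − baseline) /
elapsed years, not a regression slope — the minimal reading for sparse
irregular visits. The ROC for the 5 %ff cut-off sweeps integer CMTES
thresholds only (the score is integer-valued) and integrates by
trapezoid; this equals the probability-of-correct-ranking estimator
with half credit for ties, which the suite verifies by exhaustive pair
counting and against an independent library implementation.

## What green tests establish — and what they do not

The generator shares the analysis chain's assumptions by construction:
calibration echoes confirm internal consistency with the published
cohort-level magnitudes, not in-vivo validity. Real data differ in
ways the generator does not model: informative dropout (sicker
patients leaving), rater drift, scanner changes, non-logistic
trajectories, and left-right correlation of disease. Two specific
tensions with the published tables are worth knowing:

* Under any per-subject-constant progression law calibrated to the
  published 12-month changes, the 27-month change must be ≥ 2.2× the
  12-month change; the published pair (2.00 → 3.71 %ff in the
  intermediate stratum) grows sub-linearly, which the source attributes
  partly to dropout making visits non-comparable. The generator
  therefore overshoots the printed 27-month intermediate mean (≈ 4.8 vs
  3.7 %ff), and the corresponding acceptance check is expected to fail;
  we report the discrepancy rather than bend the law or the dropout
  model to hide it.
* The logistic law only plateaus near saturation, so muscles at
  70-90 %ff still progress ≈ 2.5 %ff/yr and the end-stage *muscle*
  band's mean annualized change can exceed the intermediate band's;
  the published evidence is itself mixed on this point (the 12-month
  end-stage subject-stratum change exceeds the intermediate one).

## Numerical details

* Logistic outputs are clamped to the open interval (0, 100) at
  machine precision to survive floating-point saturation at the
  asymptote.
* Truncated draws use rejection sampling (bounded retries).
* The per-subject log-odds offset is solved by Brent's method on
  [-8, 8]; the rate-recovery fit is bounded least squares over
  (FF0, r) ∈ (0.1, 99.9) × (0, 5).
* Report CSVs are written with `%.6g` floats for byte-stable re-runs;
  statistical rounding (2 d.p. for %ff and SRM, 1 d.p. for cm² and
  clinical scores) is applied only at presentation.
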