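# cmtcalf

Quantitative calf-muscle MRI fat-fraction biomarkers for Charcot-Marie-Tooth
disease type 1A (CMT1A): longitudinal responsiveness, baseline stratification,
and bridging-biomarker validity against the CMT Examination Score.

## The problem

CMT1A is a slowly progressive hereditary neuropathy. Clinical scales such as
the CMT Examination Score (CMTES, integer 0-28) change by well under a point
per year, which makes adequately powered treatment trials impractically long.
Dixon MRI measures the fat fraction (FF, 0-100 %) of denervated calf muscle,
a continuous quantity that progresses measurably within a year. This package
implements the analysis chain that turns per-visit fat-fraction maps into
evidence about that biomarker:

* **ROI quantification** — per-muscle mean FF, cross-sectional area
  (CSA) and remaining muscle area, `RMA = CSA * (100 - FF) / 100`, for six
  calf muscles per side (tibialis anterior, peroneus longus, lateral/medial
  gastrocnemius, soleus, posterior tibial group); whole-calf summary FF as
  the CSA-weighted average over all 12 ROIs, with whole-muscle exclusion of
  artifacted ROIs.
* **Ordinal grading** — modified Mercuri scale (0 normal ... 5 end stage)
  from FF bands, STIR hyperintensity grades, and Spearman agreement between
  grades and quantitative FF.
* **Responsiveness** — change scores linearly standardized to nominal 12/27/49
  month intervals; Shapiro-Wilk-gated paired t / Wilcoxon signed-rank tests;
  the standardised response mean `SRM = mean(change) / SD(change)` with
  Cohen's bands (<0.2 minimal, 0.2-0.5 small, 0.5-0.8 moderate, >0.8 large);
  stratification by baseline calf FF (normal <5 %, intermediate 5-70 %,
  end stage >70 %); inter-muscle ANOVA with Bonferroni post hocs.
* **Validity** — pooled FF-CMTES Spearman correlation, CMTES cut-off
  classification of the 5 %ff threshold with an integer-threshold ROC, and
  the bridging-biomarker analysis: annualized FF progression and 12-month
  FF change correlated against annualized CMTES change at final visit.
* **Synthetic cohort generator** — the study's patient data are not public,
  so a generator with known ground truth stands in: logistic FF progression
  `dF/dt = r F (1 - F/100)` with per-subject lognormal rates, a baseline
  severity mixture calibrated to the published cohort, coupled CSA atrophy,
  a latent severity scalar linking FF to the integer CMTES (drifting 0.6
  points/year on average), Mercuri/STIR grades, visit-time jitter and
  monotone dropout — plus rendered single-slice FF/label NIfTI images for
  testing the ROI chain end to end.

## Worked example

```python
from cmtcalf import (CohortConfig, simulate_cohort, stratified_responsiveness,
                     pooled_ff_clinical_correlation, bridging_correlation)

cohort, truth = simulate_cohort(CohortConfig(seed=1))   # 20 patients + 20 controls
res = stratified_responsiveness(cohort, visit=3)        # 27-month interval
for name, r in res.items():
    print(name, r.n, round(r.mean_change, 2), r.category)
```

prints (seed 1):

```
          all: n=11 change= 5.42 sd=5.25 p=0.006 srm=1.03 (large)
       normal: n= 2 change= 0.89 (n.a.)
 intermediate: n= 8 change= 6.89 sd=5.48 p=0.009 srm=1.26 (large)
    end_stage: n= 1 change= 2.75 (n.a.)
```

i.e. at 27 months the whole patient group shows a significant calf-FF
increase with large responsiveness, the intermediate-baseline stratum
progresses fastest, and strata with n < 5 or non-significant change have
their SRM suppressed (`n.a.`), mirroring natural-history reporting. On the
same cohort,

```python
pooled_ff_clinical_correlation(cohort)   # rho = 0.846, p < 1e-15, n = 55
bridging_correlation(cohort)             # rate_vs_rate rho = 0.79 (p = 0.004)
                                         # ff12_vs_rate rho = 0.80 (p = 0.003)
```

the pooled cross-sectional FF-CMTES correlation is strong, and the
12-month FF change predicts the annualized long-term CMTES change — the
bridging-biomarker property.

A command-line interface wraps the same library:

```sh
cmtcalf simulate --seed 1 --out cohort.csv
cmtcalf respond  --cohort cohort.csv --interval 27 --out responsiveness.csv
cmtcalf validate --cohort cohort.csv --analysis all --out validity.json
cmtcalf run-all  --seed 1 --out-dir run/     # full bundle + manifest
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the remaining-muscle-area worked
example from the published control-group baseline means; and two
calibration echoes of the synthetic generator at its documented defaults —
the mean 12-month standardized calf-FF change across 500 replicate
17-completer cohorts, and the mean 27-month standardized change in the
intermediate baseline stratum across 500 replicate cohorts. See
`docs/methods.md` for the generative model, its calibration and its known
limitations.
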