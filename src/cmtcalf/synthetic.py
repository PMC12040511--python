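"""Synthetic longitudinal CMT1A cohort and image generator.

The study this package models followed 20 CMT1A patients and 20 matched
controls with quantitative calf-muscle MRI at roughly 0/12/27/49 months.
Raw patient data are not public, so this module generates cohorts with
the same statistical structure and known ground truth:

* Disease progression follows logistic growth of muscle fat fraction,
  ``dF/dt = r * F * (1 - F/100)``, with a per-subject constant rate
  ``r`` (lognormal across subjects).  This reproduces the observed
  three-band behaviour: near-normal muscles (<5 %ff) progress slowly,
  intermediate muscles (5-70 %ff) progress fastest, and end-stage
  muscles (>70 %ff) plateau with increased measurement variability.
* Baseline severity is drawn from a three-component stratum mixture
  calibrated to the published cohort (half the patients in the normal
  band, most of the rest low-intermediate, a small high tail, and two
  of twenty end stage).
* Muscle cross-sectional area declines as fat replaces contractile
  tissue, and a latent severity scalar couples fat fraction to the
  integer CMT Examination Score (CMTES, 0-28), which drifts at 0.6
  points/year on average, proportionally to the subject's rate -- the
  coupling that the bridging-biomarker analysis measures.

All randomness flows from a single master seed through per-subject
sub-streams, so a cohort is reproducible and individual subjects are
stable under changes of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .grading import mercuri_from_ff, simulate_stir
from .muscles import (CSA_FRACTION, INVOLVEMENT_SHIFT, MUSCLES, SIDES,
                      LABEL_OF, muscle_column)

# --------------------------------------------------------------------------
# calibration constants (defaults reproduce the published cohort tables)
# --------------------------------------------------------------------------

#: lognormal subject progression rate: median 0.142/yr, log-SD 0.6,
#: chosen so a muscle at 17 %ff gains ~2 %ff over one year.
RATE_MEDIAN = 0.142
RATE_LOG_SD = 0.6
RATE_MEAN = RATE_MEDIAN * math.exp(RATE_LOG_SD ** 2 / 2)

#: baseline whole-calf FF stratum mixture for patients (10/8/2 of 20)
STRATUM_PROBS = (0.5, 0.4, 0.1)
NORMAL_FF = (2.33, 1.41, 0.5, 5.0)        # mean, sd, lo, hi (truncated normal)
ENDSTAGE_FF = (81.33, 1.49, 70.0, 100.0)
CONTROL_FF = (3.24, 1.60, 0.5, 6.0)
#: intermediate band: low-FF lognormal bulk plus a small high-FF tail,
#: jointly fitted to the published stratum mean 17.16 and SD 15.10
INTERMEDIATE_LO = (2.3707, 0.45, 5.0, 35.0)   # log-mu, log-sd, lo, hi
INTERMEDIATE_HI = (57.0, 7.0, 40.0, 70.0)     # mean, sd, lo, hi
INTERMEDIATE_HI_WEIGHT = 0.1138

#: FF measurement noise per muscle (%ff); doubles at end stage where
#: segmentation of residual tissue is unreliable
FF_NOISE_SD = 1.0
FF_NOISE_SD_ENDSTAGE = 2.0
ENDSTAGE_FF_THRESHOLD = 70.0

#: CSA model: total calf CSA ~ C0 * exp(-k * FF0/100), controls 117.4 cm2
CSA_BASE_CM2 = 123.0
CSA_LOG_SD = 0.2
CSA_FF_DECAY = 1.45
CSA_PATIENT_ATROPHY = 0.92        # neurogenic atrophy beyond fat replacement
CSA_NOISE_CV = 0.09               # per-muscle segmentation noise
CSA_FF_COUPLING_ALPHA = 1.0       # CSA(t) = csa0 * (1 - a*(F-F0)/100)

#: per-muscle spread around subject severity on the log-odds scale
MUSCLE_LOGODDS_SD = 0.35
SIDE_LOGODDS_SD = 0.15

#: CMTES latent coupling: latent0 = a + b*ln(FF0) + noise, drift 0.6/yr
CMTES_COUPLING = (3.5, 2.5, 2.2)  # intercept, slope on ln(FF0), latent sd
CMTES_DRIFT_PER_YEAR = 0.6
#: mean initial FF slope r*F0*(1-F0/100) over the patient mixture (%ff/yr),
#: the normaliser that keeps the cohort-mean CMTES drift at 0.6/yr while
#: each subject's clinical progression tracks their fat-accumulation rate
FF_SLOPE_MEAN = 1.278
CMTES_OBS_SD = 0.9
CMTES_MAX = 28
CMTES_LL_FRACTION = 0.79          # lower-limb components / total, observed ratio
CMTES_LL_MAX = 20

MERCURI_RATER_NOISE = 0.1


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the published study design: 20 patients, 20
    controls, four visits at nominal 0/12/27/49 months whose actual
    timings scatter around 0/12.4/27.4/47.2 months with SDs
    0/1.0/2.2/7.1 (visit four truncated to the observed 34.9-56.8
    month range), and monotone dropout at each follow-up.
    """

    n_patients: int = 20
    n_controls: int = 20
    visit_nominal_months: tuple = (0.0, 12.0, 27.0, 49.0)
    visit_mean_months: tuple = (0.0, 12.4, 27.4, 47.2)
    visit_jitter_sd_months: tuple = (0.0, 1.0, 2.2, 7.1)
    visit4_month_range: tuple = (34.9, 56.8)
    dropout_prob_per_visit: tuple = (0.15, 0.18, 0.28)
    pixel_area_mm2: float = 1.0
    seed: int | None = None
    couple_progression: bool = True   # False ablates the FF-CMTES rate coupling
    rater_noise: float = MERCURI_RATER_NOISE

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_patients + self.n_controls < 1:
            raise ValueError("need at least one subject")
        months = tuple(self.visit_nominal_months)
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit months must be strictly increasing")
        if len(self.visit_jitter_sd_months) != len(months):
            raise ValueError("one jitter SD per visit required")
        if len(self.dropout_prob_per_visit) != len(months) - 1:
            raise ValueError("one dropout probability per follow-up visit")
        if any(not 0 <= p <= 1 for p in self.dropout_prob_per_visit):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if self.pixel_area_mm2 <= 0:
            raise ValueError("pixel_area_mm2 must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrajectoryParams:
    """Ground-truth generative parameters for one subject."""

    subject_id: str
    group: str                     # 'patient' | 'control'
    stratum: str                   # 'normal' | 'intermediate' | 'end_stage'
    ff0_summary: float             # baseline CSA-weighted calf FF (%)
    rate: float                    # logistic rate r (per year)
    cmtes_drift: float             # CMTES latent drift (points/year)
    cmtes_latent0: float
    csa0_total: float              # mm^2
    ff0_muscle: dict = field(default_factory=dict)   # (side, muscle) -> %ff
    csa0_muscle: dict = field(default_factory=dict)  # (side, muscle) -> mm^2

    def __post_init__(self):
        if not 0.0 < self.ff0_summary < 100.0:
            raise ValueError("ff0 must lie in (0, 100)")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


# --------------------------------------------------------------------------
# progression law
# --------------------------------------------------------------------------

def ff_trajectory(ff0, r, t):
    """Logistic fat-fraction trajectory F(t), in percent.

    ``F(t) = 100 / (1 + ((100 - F0)/F0) * exp(-r t))`` -- the closed
    form of ``dF/dt = r F (1 - F/100)`` with F(0) = ``ff0``.  Monotone
    non-decreasing in ``t`` for ``r > 0`` and bounded in (0, 100).

    Parameters are broadcast; ``t`` is in years.
    """
    ff0 = np.asarray(ff0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((ff0 <= 0) | (ff0 >= 100)):
        raise ValueError("ff0 must lie strictly inside (0, 100)")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = 100.0 / (1.0 + ((100.0 - ff0) / ff0) * np.exp(-np.asarray(r) * t))
    # keep the open interval under floating-point saturation at the asymptote
    out = np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(100.0, 0.0))
    return out if out.ndim else float(out)


def fit_logistic_rate(t_years, ff_obs, bounds=(0.0, 5.0)):
    """Least-squares fit of (ff0, r) of the logistic law to observed FF.

    Used for ground-truth recovery checks; returns ``(ff0_hat, r_hat)``.
    """
    t = np.asarray(t_years, dtype=float)
    y = np.asarray(ff_obs, dtype=float)
    f0 = float(np.clip(y[np.argmin(t)], 0.2, 99.8))

    def resid(p):
        return ff_trajectory(p[0], p[1], t) - y

    res = optimize.least_squares(
        resid, x0=[f0, RATE_MEDIAN],
        bounds=([0.1, bounds[0]], [99.9, bounds[1]]))
    return float(res.x[0]), float(res.x[1])


def simulate_cmtes(latent, t, drift: float = CMTES_DRIFT_PER_YEAR,
                   noise_sd: float = 0.0, rng=None):
    """Integer CMTES at time ``t`` years from a latent continuous score.

    The latent score drifts linearly at ``drift`` points/year; optional
    Gaussian observation noise is added before rounding and clipping to
    [0, 28].  With ``noise_sd=0`` the mapping is deterministic.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    score = np.asarray(latent, dtype=float) + drift * t
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        score = score + rng.normal(0.0, noise_sd, size=np.shape(score))
    score = np.clip(np.rint(score), 0, CMTES_MAX).astype(int)
    return score if score.ndim else int(score)


# --------------------------------------------------------------------------
# subject-level draws
# --------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated normal rejection failed")


def _truncated_lognormal(rng, mu, sigma, lo, hi):
    for _ in range(1000):
        x = rng.lognormal(mu, sigma)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated lognormal rejection failed")


def _draw_baseline_summary_ff(rng, group):
    """Draw (stratum, baseline summary FF) from the calibrated mixture."""
    if group == "control":
        return "control", _truncated_normal(rng, *CONTROL_FF)
    u = rng.random()
    if u < STRATUM_PROBS[0]:
        return "normal", _truncated_normal(rng, *NORMAL_FF)
    if u < STRATUM_PROBS[0] + STRATUM_PROBS[1]:
        if rng.random() < INTERMEDIATE_HI_WEIGHT:
            return "intermediate", _truncated_normal(rng, *INTERMEDIATE_HI)
        return "intermediate", _truncated_lognormal(rng, *INTERMEDIATE_LO)
    return "end_stage", _truncated_normal(rng, *ENDSTAGE_FF)


def cmtes_drift_from_slope(rate: float, ff0: float) -> float:
    """CMTES latent drift (points/year) coupled to the subject's initial
    fat-accumulation rate ``r*F0*(1-F0/100)``, normalised so the
    patient-mixture mean drift is 0.6 points/year."""
    slope = rate * ff0 * (100.0 - ff0) / 100.0
    return CMTES_DRIFT_PER_YEAR * slope / FF_SLOPE_MEAN


def _logit(f):
    return np.log(f / (100.0 - f))


def _expit100(x):
    return 100.0 / (1.0 + np.exp(-x))


def _draw_muscle_ff0(rng, ff0_summary, csa_weights):
    """Per-muscle baseline FFs whose CSA-weighted mean equals the target.

    Muscles scatter around the subject's severity on a log-odds scale
    with an anatomical involvement gradient (peroneus longus worst,
    soleus best); a common offset is then solved so the weighted
    summary reproduces the subject's drawn baseline exactly.
    """
    lam = _logit(np.clip(ff0_summary, 0.2, 99.8))
    shifts = np.array([
        INVOLVEMENT_SHIFT[m] + rng.normal(0.0, SIDE_LOGODDS_SD)
        + rng.normal(0.0, MUSCLE_LOGODDS_SD)
        for _s in SIDES for m in MUSCLES])
    w = np.asarray(csa_weights, dtype=float)
    w = w / w.sum()

    def summary(c):
        return float(w @ _expit100(lam + shifts + c)) - ff0_summary

    c = optimize.brentq(summary, -8.0, 8.0)
    return _expit100(lam + shifts + c)


def draw_subject(rng, subject_id, group) -> TrajectoryParams:
    """Draw one subject's ground-truth generative parameters."""
    stratum, ff0 = _draw_baseline_summary_ff(rng, group)
    rate = 0.0 if group == "control" else float(
        rng.lognormal(math.log(RATE_MEDIAN), RATE_LOG_SD))

    csa_total = (CSA_BASE_CM2 * 100.0          # cm^2 -> mm^2
                 * math.exp(rng.normal(0.0, CSA_LOG_SD))
                 * math.exp(-CSA_FF_DECAY * ff0 / 100.0))
    if group == "patient":
        csa_total *= CSA_PATIENT_ATROPHY
    fractions = np.array([CSA_FRACTION[m] for _s in SIDES for m in MUSCLES])
    fractions = fractions * rng.lognormal(0.0, 0.08, size=fractions.size)
    fractions /= fractions.sum()
    csa_m = csa_total * fractions

    ff_m = _draw_muscle_ff0(rng, ff0, csa_m)

    a, b, lat_sd = CMTES_COUPLING
    if group == "patient":
        latent0 = float(np.clip(a + b * math.log(ff0)
                                + rng.normal(0.0, lat_sd), 0.0, CMTES_MAX))
        drift = cmtes_drift_from_slope(rate, ff0)
    else:
        latent0 = float(np.clip(abs(rng.normal(0.7, 0.6)), 0.0, CMTES_MAX))
        drift = 0.0

    keys = [(s, m) for s in SIDES for m in MUSCLES]
    return TrajectoryParams(
        subject_id=subject_id, group=group, stratum=stratum,
        ff0_summary=float(ff0), rate=rate, cmtes_drift=float(drift),
        cmtes_latent0=latent0, csa0_total=float(csa_total),
        ff0_muscle=dict(zip(keys, ff_m.tolist())),
        csa0_muscle=dict(zip(keys, csa_m.tolist())))


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _subject_rng(seed, group_idx, i):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_idx, i)))


def _draw_visit_months(rng, config) -> np.ndarray:
    months = [0.0]
    nv = len(config.visit_nominal_months)
    for k in range(1, nv):
        mean = config.visit_mean_months[k]
        sd = config.visit_jitter_sd_months[k]
        lo, hi = (config.visit4_month_range if k == nv - 1
                  else (months[-1] + 1.0, float("inf")))
        for _ in range(1000):
            m = rng.normal(mean, sd)
            if lo <= m <= hi and m > months[-1] + 1.0:
                break
        else:
            raise RuntimeError("visit-time rejection failed")
        months.append(float(m))
    return np.asarray(months)


def _last_visit_present(rng, config) -> int:
    """Monotone dropout: index of the last attended visit."""
    for k, p in enumerate(config.dropout_prob_per_visit, start=1):
        if rng.random() < p:
            return k - 1
    return len(config.visit_nominal_months) - 1


def simulate_subject_visits(params: TrajectoryParams, rng,
                            config: CohortConfig,
                            decouple_rng=None) -> list[dict]:
    """Simulate one subject's attended visits as table rows."""
    months = _draw_visit_months(rng, config)
    last = _last_visit_present(rng, config)
    keys = [(s, m) for s in SIDES for m in MUSCLES]
    ff0 = np.array([params.ff0_muscle[k] for k in keys])
    csa0 = np.array([params.csa0_muscle[k] for k in keys])
    stir = simulate_stir(len(keys), params.group, rng)

    rows = []
    for k in range(last + 1):
        t = months[k] / 12.0
        ff_true = ff_trajectory(ff0, params.rate, t)
        noise_sd = np.where(ff_true > ENDSTAGE_FF_THRESHOLD,
                            FF_NOISE_SD_ENDSTAGE, FF_NOISE_SD)
        ff_obs = np.clip(ff_true + rng.normal(0.0, 1.0, ff0.size) * noise_sd,
                         0.0, 100.0)
        csa_true = csa0 * (1.0 - CSA_FF_COUPLING_ALPHA * (ff_true - ff0) / 100.0)
        csa_obs = np.clip(csa_true * (1.0 + rng.normal(0.0, CSA_NOISE_CV,
                                                       ff0.size)), 0.0, None)
        mercuri = mercuri_from_ff(ff_true, config.rater_noise, rng)
        rma_obs = csa_obs * (100.0 - ff_obs) / 100.0

        calf_csa = float(csa_obs.sum())
        calf_ff = float((ff_obs * csa_obs).sum() / calf_csa)
        calf_rma = float(rma_obs.sum())

        cmtes = simulate_cmtes(params.cmtes_latent0, t,
                               drift=params.cmtes_drift,
                               noise_sd=CMTES_OBS_SD, rng=rng)
        ll_latent = CMTES_LL_FRACTION * (params.cmtes_latent0
                                         + params.cmtes_drift * t)
        cmtes_ll = int(np.clip(np.rint(ll_latent + rng.normal(0.0, 0.8)),
                               0, CMTES_LL_MAX))
        mrc = float(np.clip(207.8 - 2.0 * (params.cmtes_latent0 - 8.0)
                            + rng.normal(0.0, 5.0), 60.0, 260.0))
        sf36 = float(np.clip(73.9 - 0.4 * (params.cmtes_latent0 - 8.0)
                             + rng.normal(0.0, 12.0), 0.0, 100.0))

        row = {"subject_id": params.subject_id, "group": params.group,
               "visit": k + 1, "months": months[k],
               "calf_ff": calf_ff, "calf_csa": calf_csa, "calf_rma": calf_rma,
               "cmtes": int(cmtes), "cmtes_ll": cmtes_ll,
               "mrc_sum": round(mrc, 1), "sf36": round(sf36, 1)}
        for j, (s, m) in enumerate(keys):
            row[muscle_column(s, m, "ff")] = float(ff_obs[j])
            row[muscle_column(s, m, "ff_true")] = float(ff_true[j])
            row[muscle_column(s, m, "csa")] = float(csa_obs[j])
            row[muscle_column(s, m, "mercuri")] = int(mercuri[j])
            row[muscle_column(s, m, "stir")] = int(stir[j])
        rows.append(row)
    return rows


def simulate_cohort(config: CohortConfig):
    """Simulate a longitudinal cohort.

    Returns
    -------
    cohort : pandas.DataFrame
        One row per attended subject-visit: identifiers, months since
        baseline, whole-calf summaries (CSA-weighted FF in %, total CSA
        and RMA in mm^2), clinical scores, and per-muscle observed FF,
        true FF, CSA, Mercuri and STIR columns.
    truth : pandas.DataFrame
        One row per subject with the generative ground truth
        (stratum, baseline summary FF, logistic rate, CMTES drift...).
    """
    config.validate()
    rows, truth_rows = [], []
    groups = [("patient", 0, config.n_patients, "P"),
              ("control", 1, config.n_controls, "C")]
    for group, gidx, n, prefix in groups:
        for i in range(n):
            rng = _subject_rng(config.seed, gidx, i)
            params = draw_subject(rng, f"{prefix}{i + 1:03d}", group)
            if not config.couple_progression and group == "patient":
                # ablation: clinical drift drawn from the same marginal
                # but fully independent of the subject's FF trajectory
                r_indep = rng.lognormal(math.log(RATE_MEDIAN), RATE_LOG_SD)
                _, ff0_indep = _draw_baseline_summary_ff(rng, "patient")
                params.cmtes_drift = cmtes_drift_from_slope(r_indep, ff0_indep)
            rows.extend(simulate_subject_visits(params, rng, config))
            tr = {"subject_id": params.subject_id, "group": group,
                  "stratum": params.stratum,
                  "ff0_summary": params.ff0_summary, "rate": params.rate,
                  "cmtes_drift": params.cmtes_drift,
                  "cmtes_latent0": params.cmtes_latent0,
                  "csa0_total": params.csa0_total}
            for (s, m), v in params.ff0_muscle.items():
                tr[muscle_column(s, m, "ff0")] = v
            truth_rows.append(tr)
    cohort = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

@dataclass
class SyntheticVisitImage:
    """A single-slice synthetic fat-fraction map with its label map."""

    ff_map: np.ndarray        # float %, in [0, 100]
    label_map: np.ndarray     # int codes 0 (background) .. 12
    artifact_mask: np.ndarray  # bool
    pixel_area_mm2: float = 1.0

    def __post_init__(self):
        if not (self.ff_map.shape == self.label_map.shape
                == self.artifact_mask.shape):
            raise ValueError("map shapes must match")
        if self.ff_map.min() < 0 or self.ff_map.max() > 100:
            raise ValueError("ff_map values must lie in [0, 100]")


def default_layout(shape=(160, 160)) -> dict:
    """Non-overlapping elliptical ROIs for the 12 muscles on two 'legs'.

    Returns ``{label: (cy, cx, ry, rx)}`` in pixel units.  The layout is
    schematic (not anatomical); ellipse areas are roughly proportional
    to each muscle's share of the calf cross-section.
    """
    h, w = shape
    layout = {}
    # six muscle positions per leg on a 2x3 grid
    grid = {"TA": (0.18, 0.25), "PL": (0.18, 0.75), "LG": (0.50, 0.25),
            "MG": (0.50, 0.75), "SOL": (0.82, 0.30), "PT": (0.82, 0.78)}
    for si, side in enumerate(SIDES):
        x0 = 0.0 if si == 0 else 0.5
        for m in MUSCLES:
            fy, fx = grid[m]
            area_frac = CSA_FRACTION[m]
            # scale radii so the largest muscle still fits its grid cell
            base = math.sqrt(area_frac / 0.20)
            ry = max(3, int(round(0.13 * h * base)))
            rx = max(3, int(round(0.09 * w * base)))
            cy = int(round(fy * h))
            cx = int(round((x0 + 0.5 * fx) * w))
            layout[LABEL_OF[(side, m)]] = (cy, cx, ry, rx)
    return layout


def _paint_labels(shape, layout) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int16)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for label, (cy, cx, ry, rx) in sorted(layout.items()):
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if np.any(labels[inside] != 0):
            raise ValueError(f"ROI for label {label} overlaps another ROI")
        labels[inside] = label
    return labels


def render_visit_image(ff_means, layout=None, shape=(160, 160),
                       noise_sd: float = 0.0, artifacts=None,
                       rng=None, pixel_area_mm2: float = 1.0,
                       background_ff: float = 85.0) -> SyntheticVisitImage:
    """Render a synthetic single-slice FF map from per-muscle means.

    Parameters
    ----------
    ff_means : mapping label -> %ff, or sequence of 12 values (labels 1-12)
        Requested per-ROI mean fat fraction, each in (0, 100).
    layout : dict, optional
        ``{label: (cy, cx, ry, rx)}`` ellipses; defaults to
        :func:`default_layout`.  Overlapping ROIs raise ``ValueError``.
    noise_sd : float
        Pixelwise Gaussian noise SD (%ff), clipped to [0, 100].
    artifacts : list of dict, optional
        Each ``{"label": int, "fraction": float, "delta": float}``
        shifts the first ``fraction`` of the ROI's pixels by ``delta``
        %ff and marks them in the artifact mask.
    background_ff : float
        FF assigned outside any ROI (subcutaneous fat is fat-bright).
    """
    if not isinstance(ff_means, dict):
        vals = list(ff_means)
        if len(vals) != 12:
            raise ValueError("expected 12 per-muscle FF means")
        ff_means = {lab + 1: v for lab, v in enumerate(vals)}
    for lab, v in ff_means.items():
        if not 0.0 < v < 100.0:
            raise ValueError(f"requested mean for label {lab} outside (0,100)")
    layout = default_layout(shape) if layout is None else layout
    label_map = _paint_labels(shape, layout)
    if noise_sd > 0 and rng is None:
        rng = np.random.default_rng(0)

    ff_map = np.full(shape, float(background_ff))
    for lab, mean in ff_means.items():
        idx = label_map == lab
        if not idx.any():
            raise ValueError(f"label {lab} absent from layout")
        vals = np.full(int(idx.sum()), float(mean))
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, vals.size)
        ff_map[idx] = vals

    artifact_mask = np.zeros(shape, dtype=bool)
    for spec in (artifacts or []):
        lab, frac, delta = spec["label"], spec["fraction"], spec["delta"]
        ys, xs = np.nonzero(label_map == lab)
        n_art = int(round(frac * ys.size))
        sel = (ys[:n_art], xs[:n_art])     # contiguous block in scan order
        ff_map[sel] += delta
        artifact_mask[sel] = True

    np.clip(ff_map, 0.0, 100.0, out=ff_map)
    return SyntheticVisitImage(ff_map=ff_map, label_map=label_map,
                               artifact_mask=artifact_mask,
                               pixel_area_mm2=pixel_area_mm2)


def save_visit_image(image: SyntheticVisitImage, ff_path, label_path,
                     artifact_path=None) -> None:
    """Write the FF and label maps (and optionally the artifact mask)
    as single-slice NIfTI files with isotropic in-plane spacing."""
    import nibabel as nib

    spacing = math.sqrt(image.pixel_area_mm2)
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(image.ff_map[..., None].astype(np.float32),
                             affine), str(ff_path))
    nib.save(nib.Nifti1Image(image.label_map[..., None].astype(np.int16),
                             affine), str(label_path))
    if artifact_path is not None:
        nib.save(nib.Nifti1Image(
            image.artifact_mask[..., None].astype(np.uint8), affine),
            str(artifact_path))
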