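"""Criterion and longitudinal validity of the FF biomarker.

Three families of analyses:

* Cross-sectional: Spearman correlation between whole-calf FF and the
  CMT Examination Score pooled over all subject-visits, and a
  CMTES-threshold classification of the 5 %ff cut-off (with an ROC over
  integer CMTES thresholds).
* Longitudinal ("bridging biomarker"): in subjects with at least three
  visits, the annualized FF progression rate -- and, critically, the
  12-month standardized FF change alone -- are correlated with the
  annualized CMTES change at the final visit.  A short-horizon imaging
  change that predicts long-horizon clinical change is what makes the
  biomarker useful for shortening trials.
* Baseline-predicts-progression: per-muscle annualized FF change
  summarised by baseline FF band (fastest progression is expected at
  intermediate baseline FF), with an optional contrast by baseline
  STIR hyperintensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grading import CorrelationResult
from .muscles import MUSCLES, SIDES, muscle_column
from .responsiveness import DEFAULT_STRATA, change_table


def _spearman(x, y, min_n: int = 5) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} pairs, got {x.size}")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size))


def pooled_ff_clinical_correlation(cohort: pd.DataFrame,
                                   score: str = "cmtes",
                                   ff_col: str = "calf_ff",
                                   group: str = "patient"
                                   ) -> CorrelationResult:
    """Spearman correlation of calf FF with a clinical score, pooling
    all subject-visits of one group (no clustering correction --
    repeated measures are pooled, a deliberate simplification that
    inflates n; see the methods note)."""
    sub = cohort if group is None else cohort[cohort["group"] == group]
    return _spearman(sub[ff_col], sub[score])


def _per_subject_rates(cohort: pd.DataFrame, score: str,
                       min_visits: int) -> pd.DataFrame:
    """Annualized FF and clinical rates (last minus baseline over
    elapsed years) for patients with enough visits."""
    pat = cohort[cohort["group"] == "patient"].sort_values("visit")
    rows = []
    for sid, g in pat.groupby("subject_id"):
        if len(g) < min_visits:
            continue
        first, last = g.iloc[0], g.iloc[-1]
        years = (last["months"] - first["months"]) / 12.0
        if years <= 0:
            continue
        rows.append({"subject_id": sid,
                     "ff_rate": (last["calf_ff"] - first["calf_ff"]) / years,
                     "score_rate": (last[score] - first[score]) / years,
                     "n_visits": len(g)})
    return pd.DataFrame(rows)


def bridging_correlation(cohort: pd.DataFrame, score: str = "cmtes",
                         min_visits: int = 3) -> dict:
    """The bridging-biomarker analysis.

    Returns two Spearman correlations over patients with at least
    ``min_visits`` visits:

    * ``"rate_vs_rate"`` -- annualized FF progression (last minus
      baseline calf FF over elapsed years) against annualized change in
      the clinical score at the final visit;
    * ``"ff12_vs_rate"`` -- the 12-month standardized calf FF change
      against the same annualized clinical change (the bridging claim:
      1-year imaging change predicts long-term clinical progression).
    """
    rates = _per_subject_rates(cohort, score, min_visits)
    if len(rates) < 5:
        raise ValueError(
            f"only {len(rates)} patients have >= {min_visits} visits; "
            "need at least 5")
    out = {"rate_vs_rate": _spearman(rates["ff_rate"], rates["score_rate"])}

    ch12 = change_table(cohort[cohort["group"] == "patient"], "calf_ff", 2)
    merged = rates.merge(ch12[["subject_id", "standardized_change"]],
                         on="subject_id")
    if len(merged) < 5:
        raise ValueError(
            f"only {len(merged)} eligible patients also have a 12-month "
            "visit; need at least 5")
    out["ff12_vs_rate"] = _spearman(merged["standardized_change"],
                                    merged["score_rate"])
    return out


# --------------------------------------------------------------------------
# CMTES cut-off classification / ROC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """ROC of an integer score against a binary reference label."""

    auc: float
    points: pd.DataFrame = field(repr=False)   # threshold, sens, spec, acc

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.auc)


def roc_integer_score(score, label) -> ROCResult:
    """ROC sweeping integer thresholds t (predict positive when
    ``score >= t``); AUC by the trapezoid rule over (FPR, TPR)."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(label, dtype=bool)
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        return ROCResult(float("nan"), pd.DataFrame(
            columns=["threshold", "sensitivity", "specificity", "accuracy"]))
    thresholds = np.arange(np.floor(s.min()), np.ceil(s.max()) + 2)
    rows = []
    for t in thresholds:
        pred = s >= t
        tp = int((pred & y).sum())
        tn = int((~pred & ~y).sum())
        rows.append({"threshold": float(t), "sensitivity": tp / pos,
                     "specificity": tn / neg,
                     "accuracy": (tp + tn) / y.size})
    pts = pd.DataFrame(rows)
    # descending threshold <=> ascending (FPR, TPR); anchor both ends
    fpr = np.concatenate([[0.0], 1.0 - pts["specificity"].to_numpy()[::-1],
                          [1.0]])
    tpr = np.concatenate([[0.0], pts["sensitivity"].to_numpy()[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc, pts)


def cmtes_cutoff_classification(cohort: pd.DataFrame, ff_cut: float = 5.0,
                                low_cut: int = 5, high_cut: int = 7,
                                score: str = "cmtes",
                                group: str = "patient") -> dict:
    """How well does the integer clinical score predict the FF cut-off?

    Over pooled patient visits: ``accuracy_low`` is the fraction of
    visits with score < ``low_cut`` whose calf FF is below ``ff_cut``
    (clinically: a mild score predicts normal calf fat); ``accuracy_high``
    the fraction with score > ``high_cut`` whose FF is at or above the
    cut (a high score predicts at-least-intermediate calf fat).  The
    ROC sweeps integer score thresholds against the FF >= cut label.
    """
    sub = cohort if group is None else cohort[cohort["group"] == group]
    s = sub[score].to_numpy(dtype=float)
    ff = sub["calf_ff"].to_numpy(dtype=float)
    keep = np.isfinite(s) & np.isfinite(ff)
    s, ff = s[keep], ff[keep]
    label = ff >= ff_cut
    if s.size < 10:
        raise ValueError(f"need >= 10 visits, got {s.size}")
    # single-class data leaves the AUC undefined (flagged NaN downstream)

    low = s < low_cut
    high = s > high_cut
    return {
        "n_visits": int(s.size),
        "accuracy_low": float((ff[low] < ff_cut).mean()) if low.any()
        else float("nan"),
        "n_low": int(low.sum()),
        "accuracy_high": float((ff[high] >= ff_cut).mean()) if high.any()
        else float("nan"),
        "n_high": int(high.sum()),
        "roc": roc_integer_score(s, label),
    }


# --------------------------------------------------------------------------
# baseline predicts progression (per-muscle)
# --------------------------------------------------------------------------

def per_muscle_progression(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per patient-muscle: baseline FF, baseline STIR flag and
    annualized FF change from first to last attended visit."""
    pat = cohort[cohort["group"] == "patient"].sort_values("visit")
    rows = []
    for sid, g in pat.groupby("subject_id"):
        if len(g) < 2:
            continue
        first, last = g.iloc[0], g.iloc[-1]
        years = (last["months"] - first["months"]) / 12.0
        for side in SIDES:
            for m in MUSCLES:
                ff_col = muscle_column(side, m, "ff")
                rows.append({
                    "subject_id": sid, "side": side, "muscle": m,
                    "baseline_ff": first[ff_col],
                    "baseline_stir": int(first[muscle_column(side, m, "stir")])
                    if muscle_column(side, m, "stir") in g.columns else 0,
                    "annualized_change": (last[ff_col] - first[ff_col]) / years,
                })
    return pd.DataFrame(rows)


def baseline_predicts_progression(cohort: pd.DataFrame,
                                  strata=DEFAULT_STRATA) -> dict:
    """Per-band summary of per-muscle annualized FF change.

    Returns ``{"bands": DataFrame, "correlation": CorrelationResult,
    "stir_contrast": dict | None}``.  Bands with no muscles are
    omitted; the correlation is Spearman between baseline muscle FF
    and annualized change (expected non-monotone across the full range,
    reported for completeness); the STIR contrast compares annualized
    change in muscles with and without baseline STIR hyperintensity.
    """
    rec = per_muscle_progression(cohort)
    if rec.empty:
        raise ValueError("no longitudinal per-muscle records")
    band_rows = []
    for s in strata:
        sel = rec[[s.contains(f) for f in rec["baseline_ff"]]]
        if sel.empty:
            continue
        band_rows.append({"band": s.name, "n_muscles": len(sel),
                          "mean_annualized_change":
                              float(sel["annualized_change"].mean()),
                          "sd_annualized_change":
                              float(sel["annualized_change"].std(ddof=1))})
    out = {"bands": pd.DataFrame(band_rows),
           "correlation": _spearman(rec["baseline_ff"],
                                    rec["annualized_change"])}
    stir_pos = rec[rec["baseline_stir"] > 0]["annualized_change"]
    stir_neg = rec[rec["baseline_stir"] == 0]["annualized_change"]
    if len(stir_pos) >= 3 and len(stir_neg) >= 3:
        t = stats.ttest_ind(stir_pos, stir_neg, equal_var=False)
        out["stir_contrast"] = {
            "n_stir": int(len(stir_pos)), "n_normal": int(len(stir_neg)),
            "mean_stir": float(stir_pos.mean()), "sd_stir": float(stir_pos.std(ddof=1)),
            "mean_normal": float(stir_neg.mean()),
            "sd_normal": float(stir_neg.std(ddof=1)), "p": float(t.pvalue)}
    else:
        out["stir_contrast"] = None
    return out
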