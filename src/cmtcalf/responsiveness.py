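"""Change scores, interval standardization, SRM responsiveness, strata.

Follow-up visits happen at heterogeneous times, so each raw change
score is linearly prorated to the nominal interval for its visit
(12, 27 or 49 months).  Within-group change is tested against zero by
paired t-test when the changes pass Shapiro-Wilk normality (p > 0.05),
otherwise by Wilcoxon signed-rank.  Responsiveness is the standardised
response mean, SRM = mean change / SD of change, categorised by Cohen's
rule of thumb (<0.2 minimal, 0.2-0.5 small, 0.5-0.8 moderate, >0.8
large) and reported only when the change is significant and the group
is large enough -- otherwise "n.a.", mirroring the reporting convention
of natural-history tables.

Patients are stratified by baseline whole-calf FF: normal <5 %,
intermediate 5-70 %, end stage >70 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_N = 5
NOMINAL_INTERVALS = (12.0, 27.0, 49.0)   # visits 2, 3, 4


@dataclass(frozen=True)
class StratumDefinition:
    """A baseline-FF band with explicit boundary ownership, so the
    default bands partition [0, 100]: normal [0,5), intermediate
    [5,70], end stage (70,100]."""

    name: str
    lower: float
    upper: float
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def contains(self, ff: float) -> bool:
        lo_ok = ff >= self.lower if self.lower_inclusive else ff > self.lower
        hi_ok = ff <= self.upper if self.upper_inclusive else ff < self.upper
        return lo_ok and hi_ok


DEFAULT_STRATA = (
    StratumDefinition("normal", 0.0, 5.0),
    StratumDefinition("intermediate", 5.0, 70.0, upper_inclusive=True),
    StratumDefinition("end_stage", 70.0, 100.0, lower_inclusive=False,
                      upper_inclusive=True))


def assign_stratum(ff: float, strata=DEFAULT_STRATA) -> str:
    for s in strata:
        if s.contains(ff):
            return s.name
    raise ValueError(f"baseline FF {ff} not covered by strata")


@dataclass(frozen=True)
class ResponsivenessResult:
    """Within-group change and its responsiveness for one measure,
    interval and (optionally) stratum."""

    n: int
    mean_change: float
    sd_change: float
    p_value: float
    test_used: str            # 'paired-t' | 'wilcoxon' | 'n.a.'
    srm: float                # NaN when suppressed
    category: str             # Cohen band or 'n.a.'
    degenerate: bool = False  # zero-variance changes

    def to_dict(self) -> dict:
        return {"n": self.n, "mean_change": self.mean_change,
                "sd_change": self.sd_change, "p": self.p_value,
                "test": self.test_used, "srm": self.srm,
                "category": self.category}


def standardize_change(raw_change, actual_months, nominal_months):
    """Linearly prorate a change score to the nominal follow-up interval.

    ``standardized = raw * nominal / actual``; the identity when the
    actual interval equals the nominal one.  Linearity is the minimal
    reading of interval conversion and matches per-subject constant
    progression rates.
    """
    actual = np.asarray(actual_months, dtype=float)
    if np.any(actual <= 0):
        raise ValueError("actual interval must be positive")
    if np.any(np.asarray(nominal_months, dtype=float) <= 0):
        raise ValueError("nominal interval must be positive")
    out = np.asarray(raw_change, dtype=float) * nominal_months / actual
    return out if out.ndim else float(out)


def cohen_category(srm: float) -> str:
    """Cohen's responsiveness band for an SRM magnitude."""
    a = abs(srm)
    if a < 0.2:
        return "minimal"
    if a <= 0.5:
        return "small"
    if a <= 0.8:
        return "moderate"
    return "large"


def responsiveness(changes, alpha: float = DEFAULT_ALPHA,
                   min_n: int = DEFAULT_MIN_N) -> ResponsivenessResult:
    """Test a vector of change scores against zero and compute the SRM.

    Normality of the changes is assessed by Shapiro-Wilk (needs n >= 3);
    normal changes use the paired t-test, non-normal the Wilcoxon
    signed-rank test.  The SRM and its Cohen category are reported only
    when the change is significant (p < ``alpha``) and n >= ``min_n``.
    Zero-variance changes are flagged degenerate (p and SRM undefined).
    """
    x = np.asarray(changes, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 change scores, got {n}")
    mean, sd = float(x.mean()), float(x.std(ddof=1))

    if sd == 0.0:
        return ResponsivenessResult(n, mean, 0.0, float("nan"), "n.a.",
                                    float("nan"), "n.a.", degenerate=True)
    if n < 3:
        # too few for a normality check or a meaningful test
        return ResponsivenessResult(n, mean, sd, float("nan"), "n.a.",
                                    float("nan"), "n.a.")

    shapiro_p = float(stats.shapiro(x).pvalue)
    if shapiro_p > 0.05:
        test, p = "paired-t", float(stats.ttest_1samp(x, 0.0).pvalue)
    else:
        test, p = "wilcoxon", float(stats.wilcoxon(x).pvalue)

    srm = mean / sd
    if p < alpha and n >= min_n:
        return ResponsivenessResult(n, mean, sd, p, test, srm,
                                    cohen_category(srm))
    return ResponsivenessResult(n, mean, sd, p, test, float("nan"), "n.a.")


# --------------------------------------------------------------------------
# cohort-table helpers
# --------------------------------------------------------------------------

def _nominal_for_visit(visit: int, nominals=NOMINAL_INTERVALS) -> float:
    if visit < 2 or visit - 2 >= len(nominals):
        raise ValueError(f"no nominal interval for visit {visit}")
    return nominals[visit - 2]


def change_table(cohort: pd.DataFrame, measure: str,
                 visit: int) -> pd.DataFrame:
    """Per-subject standardized change from baseline to ``visit``.

    Returns columns subject_id, group, baseline, raw_change,
    actual_months, standardized_change.
    """
    base = cohort[cohort["visit"] == 1].set_index("subject_id")
    follow = cohort[cohort["visit"] == visit].set_index("subject_id")
    common = base.index.intersection(follow.index)
    nominal = _nominal_for_visit(visit)
    raw = follow.loc[common, measure] - base.loc[common, measure]
    actual = follow.loc[common, "months"] - base.loc[common, "months"]
    out = pd.DataFrame({
        "subject_id": common,
        "group": base.loc[common, "group"].to_numpy(),
        "baseline": base.loc[common, measure].to_numpy(),
        "baseline_calf_ff": base.loc[common, "calf_ff"].to_numpy(),
        "raw_change": raw.to_numpy(),
        "actual_months": actual.to_numpy(),
        "nominal_months": nominal,
    })
    out["standardized_change"] = standardize_change(
        out["raw_change"].to_numpy(), out["actual_months"].to_numpy(), nominal)
    return out.reset_index(drop=True)


def stratified_responsiveness(cohort: pd.DataFrame, measure: str = "calf_ff",
                              visit: int = 3, strata=DEFAULT_STRATA,
                              group: str = "patient",
                              alpha: float = DEFAULT_ALPHA,
                              min_n: int = DEFAULT_MIN_N) -> dict:
    """Per-stratum responsiveness of ``measure`` at one follow-up visit.

    Subjects are assigned a stratum by their baseline whole-calf FF;
    the whole-group result is returned under key ``"all"``.  Strata
    with fewer than 2 subjects are reported n.a. (n, mean only).
    """
    ch = change_table(cohort, measure, visit)
    ch = ch[ch["group"] == group]
    results = {"all": responsiveness(ch["standardized_change"], alpha, min_n)}
    for s in strata:
        sel = ch[[s.contains(f) for f in ch["baseline_calf_ff"]]]
        x = sel["standardized_change"].to_numpy()
        if x.size < 2:
            results[s.name] = ResponsivenessResult(
                int(x.size), float(x.mean()) if x.size else float("nan"),
                float("nan"), float("nan"), "n.a.", float("nan"), "n.a.")
        else:
            results[s.name] = responsiveness(x, alpha, min_n)
    return results


def responsiveness_table(cohort: pd.DataFrame, measures,
                         visits=(2, 3, 4)) -> pd.DataFrame:
    """Natural-history-style wide table: per measure and group, the
    baseline mean +/- SD and, per follow-up visit, the standardized
    mean change, SD, p and SRM."""
    rows = []
    for measure in measures:
        for group in ("control", "patient"):
            sub = cohort[cohort["group"] == group]
            if sub.empty:
                continue
            base = sub.loc[sub["visit"] == 1, measure]
            row = {"measure": measure, "group": group,
                   "baseline_mean": base.mean(), "baseline_sd": base.std(),
                   "baseline_n": int(base.notna().sum())}
            for v in visits:
                ch = change_table(sub, measure, v)
                tag = f"{int(_nominal_for_visit(v))}mo"
                if len(ch) < 2:
                    row.update({f"change_{tag}": np.nan, f"sd_{tag}": np.nan,
                                f"p_{tag}": np.nan, f"srm_{tag}": np.nan,
                                f"n_{tag}": len(ch)})
                    continue
                res = responsiveness(ch["standardized_change"])
                row.update({f"change_{tag}": res.mean_change,
                            f"sd_{tag}": res.sd_change,
                            f"p_{tag}": res.p_value,
                            f"srm_{tag}": res.srm, f"n_{tag}": res.n})
            rows.append(row)
    return pd.DataFrame(rows)


def per_muscle_responsiveness(cohort: pd.DataFrame, columns,
                              visits=(2, 3, 4)) -> pd.DataFrame:
    """Individual-muscle FF responsiveness table (one row per muscle,
    change/SD/p/SRM per follow-up interval), patients only."""
    sub = cohort[cohort["group"] == "patient"]
    rows = []
    for col in columns:
        row = {"muscle": col}
        for v in visits:
            ch = change_table(sub, col, v)
            tag = f"{int(_nominal_for_visit(v))}mo"
            if len(ch) < 2:
                continue
            res = responsiveness(ch["standardized_change"])
            row.update({f"change_{tag}": res.mean_change,
                        f"sd_{tag}": res.sd_change, f"p_{tag}": res.p_value,
                        f"srm_{tag}": res.mean_change / res.sd_change
                        if res.sd_change else np.nan, f"n_{tag}": res.n})
        rows.append(row)
    return pd.DataFrame(rows)


def inter_muscle_comparison(ff_by_muscle: dict) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA of baseline FF across muscles with Bonferroni
    post hoc pairwise t-tests.

    ``ff_by_muscle`` maps muscle name -> vector of per-patient baseline
    FFs (available-case: vectors may differ in length).  Returns the
    ANOVA p-value and a DataFrame of pairwise raw and adjusted p-values
    (adjusted = raw x number of pairs, capped at 1).
    """
    names = list(ff_by_muscle)
    if len(names) < 2:
        raise ValueError("need at least two muscles")
    samples = [np.asarray(ff_by_muscle[n], dtype=float) for n in names]
    samples = [s[np.isfinite(s)] for s in samples]
    if any(s.size < 3 for s in samples):
        raise ValueError("need at least 3 subjects per muscle")
    anova_p = float(stats.f_oneway(*samples).pvalue)
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(stats.ttest_ind(samples[i], samples[j]).pvalue)
            rows.append({"muscle_a": names[i], "muscle_b": names[j],
                         "p_raw": p, "p_bonferroni": min(1.0, p * n_pairs)})
    return anova_p, pd.DataFrame(rows)
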