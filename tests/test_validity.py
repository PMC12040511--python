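"""Cross-sectional, cut-off/ROC and bridging-biomarker validity."""

import numpy as np
import pandas as pd
import pytest

from cmtcalf import (baseline_predicts_progression, bridging_correlation,
                     cmtes_cutoff_classification,
                     pooled_ff_clinical_correlation, roc_integer_score)
from cmtcalf.muscles import MUSCLES, SIDES, muscle_column


def _visits_frame(ff, cmtes, group="patient"):
    n = len(ff)
    return pd.DataFrame({
        "subject_id": [f"P{i:03d}" for i in range(n)],
        "group": group, "visit": 1, "months": 0.0,
        "calf_ff": ff, "cmtes": cmtes})


class TestPooledCorrelation:
    def test_monotone_score_gives_rho_one(self):
        ff = np.linspace(1, 90, 30)
        res = pooled_ff_clinical_correlation(_visits_frame(ff, np.sqrt(ff)))
        assert res.rho == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        ff = rng.uniform(0, 90, 200)
        score = rng.integers(0, 28, 200)
        res = pooled_ff_clinical_correlation(_visits_frame(ff, score))
        assert abs(res.rho) < 0.15

    def test_spearman_invariant_under_monotone_transform(self, rng):
        ff = rng.uniform(1, 90, 60)
        score = ff + rng.normal(0, 10, 60)
        a = pooled_ff_clinical_correlation(_visits_frame(ff, score))
        b = pooled_ff_clinical_correlation(_visits_frame(np.exp(ff / 20),
                                                         score))
        assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_refuses_tiny_n(self):
        with pytest.raises(ValueError):
            pooled_ff_clinical_correlation(_visits_frame([1, 2, 3], [1, 2, 3]))

    def test_default_cohort_in_published_band(self, default_cohort):
        """Pooled FF-CMTES Spearman lands near the in-vivo 0.798."""
        cohort, _ = default_cohort
        res = pooled_ff_clinical_correlation(cohort)
        assert 0.7 <= res.rho <= 0.9
        assert res.p < 0.001


def _longitudinal_toy(rates, noise=None, months=(0.0, 12.0, 48.0)):
    rows = []
    for i, r in enumerate(rates):
        for v, m in enumerate(months, start=1):
            rows.append({"subject_id": f"P{i:03d}", "group": "patient",
                         "visit": v, "months": m,
                         "calf_ff": 10.0 + r * m / 12.0,
                         "cmtes": 5.0 + 2.0 * r * m / 12.0})
    return pd.DataFrame(rows)


class TestBridging:
    def test_exactly_proportional_rates_give_rho_one(self):
        toy = _longitudinal_toy([0.2, 0.5, 1.0, 1.5, 2.0, 3.0])
        res = bridging_correlation(toy)
        assert res["rate_vs_rate"].rho == pytest.approx(1.0)
        assert res["ff12_vs_rate"].rho == pytest.approx(1.0)

    def test_refuses_with_count_in_message(self):
        toy = _longitudinal_toy([0.2, 0.5, 1.0])
        with pytest.raises(ValueError, match="3 patients"):
            bridging_correlation(toy)

    def test_min_visits_filter(self):
        toy = _longitudinal_toy([0.2, 0.5, 1.0, 1.5, 2.0, 3.0])
        toy = toy[~((toy["subject_id"] == "P000") & (toy["visit"] == 3))]
        res = bridging_correlation(toy, min_visits=3)
        assert res["rate_vs_rate"].n == 5


class TestCutoffClassification:
    def test_perfectly_separable(self):
        ff = np.concatenate([np.full(10, 2.0), np.full(10, 40.0)])
        cmtes = np.concatenate([np.full(10, 2), np.full(10, 12)])
        out = cmtes_cutoff_classification(_visits_frame(ff, cmtes))
        assert out["accuracy_low"] == 1.0
        assert out["accuracy_high"] == 1.0
        assert out["roc"].auc == pytest.approx(1.0)

    def test_shuffled_labels_auc_near_half(self, rng):
        ff = rng.uniform(0, 60, 400)
        cmtes = rng.permutation(np.clip(ff / 3, 0, 28).astype(int))
        out = cmtes_cutoff_classification(_visits_frame(ff, cmtes))
        assert out["roc"].auc == pytest.approx(0.5, abs=0.1)

    def test_single_class_flagged(self):
        ff = np.full(20, 2.0)
        out = cmtes_cutoff_classification(_visits_frame(ff, np.arange(20)))
        assert out["roc"].missing

    def test_too_few_visits_rejected(self):
        with pytest.raises(ValueError, match="10 visits"):
            cmtes_cutoff_classification(_visits_frame([1.0, 9.0], [1, 9]))


class TestROC:
    def test_auc_equals_pair_counting(self, rng):
        """Trapezoid AUC over integer thresholds equals the probability
        of correct ranking (ties at half credit), counted exhaustively."""
        score = rng.integers(0, 15, 50).astype(float)
        label = rng.random(50) < 0.4
        if label.all() or not label.any():
            label[0] = ~label[0]
        auc = roc_integer_score(score, label).auc
        pos, neg = score[label], score[~label]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        score = rng.integers(0, 20, 80).astype(float)
        label = rng.random(80) < 0.5
        label[:2] = [True, False]
        assert roc_integer_score(score, label).auc == pytest.approx(
            roc_auc_score(label, score), abs=1e-12)

    def test_points_ordered_by_threshold(self, rng):
        score = rng.integers(0, 10, 40).astype(float)
        label = score + rng.normal(0, 2, 40) > 5
        label[:2] = [True, False]
        pts = roc_integer_score(score, label).points
        assert pts["threshold"].is_monotonic_increasing


def _muscle_toy():
    """Two subjects x two visits with controlled per-muscle FF slopes."""
    rows = []
    base = {("R", "TA"): 2.0, ("R", "PL"): 10.0, ("R", "LG"): 30.0,
            ("R", "MG"): 50.0, ("R", "SOL"): 80.0, ("R", "PT"): 90.0,
            ("L", "TA"): 3.0, ("L", "PL"): 15.0, ("L", "LG"): 35.0,
            ("L", "MG"): 55.0, ("L", "SOL"): 75.0, ("L", "PT"): 85.0}
    slope = {k: (2.0 if 5 <= v <= 70 else 0.5) for k, v in base.items()}
    for sid in ("P000", "P001"):
        for visit, months in ((1, 0.0), (2, 24.0)):
            row = {"subject_id": sid, "group": "patient", "visit": visit,
                   "months": months, "calf_ff": 20.0, "cmtes": 8}
            for (s, m), b in base.items():
                row[muscle_column(s, m, "ff")] = b + slope[(s, m)] * months / 12
                row[muscle_column(s, m, "stir")] = 0
            rows.append(row)
    return pd.DataFrame(rows)


class TestBaselinePredictsProgression:
    def test_hand_computed_band_means(self):
        out = baseline_predicts_progression(_muscle_toy())
        bands = out["bands"].set_index("band")
        assert bands.loc["normal", "mean_annualized_change"] == pytest.approx(0.5)
        assert bands.loc["intermediate",
                         "mean_annualized_change"] == pytest.approx(2.0)
        assert bands.loc["end_stage",
                         "mean_annualized_change"] == pytest.approx(0.5)
        assert bands["n_muscles"].sum() == 24

    def test_single_band_equals_overall(self):
        toy = _muscle_toy()
        for s in SIDES:
            for m in MUSCLES:
                toy[muscle_column(s, m, "ff")] = \
                    toy[muscle_column(s, m, "ff")].clip(5.0, 70.0)
        out = baseline_predicts_progression(toy)
        assert list(out["bands"]["band"]) == ["intermediate"]

    def test_intermediate_band_fastest_vs_normal(self, patients_only):
        cohort, _ = patients_only
        bands = baseline_predicts_progression(cohort)["bands"]
        bands = bands.set_index("band")["mean_annualized_change"]
        assert bands["intermediate"] > bands["normal"]
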