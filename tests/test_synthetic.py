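"""Synthetic cohort generator: trajectory law, cohort structure, images."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from cmtcalf import (CohortConfig, ff_trajectory, render_visit_image,
                     simulate_cmtes, simulate_cohort)
from cmtcalf.muscles import all_muscle_columns
from cmtcalf.synthetic import draw_subject, _subject_rng


class TestFFTrajectory:
    def test_zero_rate_is_identity(self):
        assert ff_trajectory(10.0, 0.0, 5.0) == pytest.approx(10.0)

    def test_asymptote_is_100(self):
        assert ff_trajectory(50.0, 0.142, 500.0) == pytest.approx(100.0)

    def test_starts_at_baseline(self):
        assert ff_trajectory(33.3, 0.5, 0.0) == pytest.approx(33.3)

    def test_one_year_increment_matches_ode_oracle(self):
        """Closed form equals numerical integration of the logistic ODE,
        and the calibration point (17 %ff, median rate) gains ~2 %ff/yr."""
        ff0, r = 17.0, 0.142
        sol = solve_ivp(lambda _, f: r * f * (1 - f / 100.0), (0.0, 1.0),
                        [ff0], rtol=1e-10, atol=1e-12)
        ode_value = sol.y[0, -1]
        assert ff_trajectory(ff0, r, 1.0) == pytest.approx(ode_value, abs=1e-6)
        assert ode_value - ff0 == pytest.approx(2.0, abs=0.15)

    @pytest.mark.parametrize("bad", [0.0, -3.0, 100.0, 140.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            ff_trajectory(bad, 0.1, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(ff0=st.floats(0.01, 99.99), r=st.floats(0.0, 3.0),
           t1=st.floats(0.0, 50.0), t2=st.floats(0.0, 50.0))
    def test_bounded_and_monotone(self, ff0, r, t1, t2):
        lo, hi = sorted([t1, t2])
        f_lo, f_hi = ff_trajectory(ff0, r, lo), ff_trajectory(ff0, r, hi)
        assert 0.0 < f_lo < 100.0 and 0.0 < f_hi < 100.0
        assert f_hi >= f_lo - 1e-12


class TestSimulateCmtes:
    def test_constant_without_drift_or_noise(self):
        assert simulate_cmtes(7.2, 3.0, drift=0.0) == simulate_cmtes(7.2, 0.0)

    def test_expected_four_year_increment(self, rng):
        """Drift 0.6/yr gives a mean 4-year increment of ~2.4 points."""
        latents = rng.uniform(4.0, 16.0, 4000)
        inc = (simulate_cmtes(latents, 4.0) - simulate_cmtes(latents, 0.0))
        assert inc.mean() == pytest.approx(2.4, abs=0.1)

    def test_integer_and_clipped(self, rng):
        scores = simulate_cmtes(rng.uniform(-5, 40, 500), 2.0,
                                noise_sd=3.0, rng=rng)
        assert scores.dtype.kind == "i"
        assert scores.min() >= 0 and scores.max() <= 28


class TestSimulateCohort:
    def test_controls_only_cohort_stays_in_normal_band(self):
        cohort, truth = simulate_cohort(CohortConfig(
            seed=5, n_patients=0, n_controls=5))
        assert set(cohort["group"]) == {"control"}
        assert truth["ff0_summary"].between(0.5, 6.0).all()
        assert (truth["rate"] == 0).all()

    def test_same_seed_identical_different_seed_not(self):
        a, ta = simulate_cohort(CohortConfig(seed=9))
        b, tb = simulate_cohort(CohortConfig(seed=9))
        c, _ = simulate_cohort(CohortConfig(seed=10))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)
        assert not a.equals(c)

    def test_subjects_stable_under_cohort_growth(self):
        """Per-subject RNG sub-streams: subject P001 is the same person
        in a 5-patient and a 20-patient cohort."""
        small, _ = simulate_cohort(CohortConfig(seed=3, n_patients=5,
                                                n_controls=0))
        big, _ = simulate_cohort(CohortConfig(seed=3, n_patients=20,
                                              n_controls=0))
        a = small[small["subject_id"] == "P001"].reset_index(drop=True)
        b = big[big["subject_id"] == "P001"].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_dropout_is_monotone(self):
        cohort, _ = simulate_cohort(CohortConfig(
            seed=21, n_patients=60, n_controls=0,
            dropout_prob_per_visit=(0.4, 0.4, 0.4)))
        for _, g in cohort.groupby("subject_id"):
            visits = sorted(g["visit"])
            assert visits == list(range(1, len(visits) + 1))
        # with 40% dropout per visit some subjects must have dropped
        assert cohort.groupby("subject_id")["visit"].max().min() < 4

    def test_observed_ff_bounded_true_ff_strict(self, default_cohort):
        cohort, _ = default_cohort
        obs = cohort[all_muscle_columns("ff")].to_numpy()
        true = cohort[all_muscle_columns("ff_true")].to_numpy()
        assert obs.min() >= 0.0 and obs.max() <= 100.0
        assert true.min() > 0.0 and true.max() < 100.0

    def test_visit_months_jittered_and_increasing(self, default_cohort):
        cohort, _ = default_cohort
        for _, g in cohort.groupby("subject_id"):
            months = g.sort_values("visit")["months"].to_numpy()
            assert months[0] == 0.0
            assert (np.diff(months) > 0).all()
        v4 = cohort.loc[cohort["visit"] == 4, "months"]
        if len(v4):
            assert v4.between(34.9, 56.8).all()

    def test_patient_baseline_matches_published_mixture(self):
        """Across many subjects the baseline summary FF reproduces the
        published whole-cohort moments (16.16 +/- 25.16 is a wide-SD
        mixture dominated by mildly affected patients)."""
        cohort, truth = simulate_cohort(CohortConfig(
            seed=11, n_patients=400, n_controls=0))
        ff0 = truth["ff0_summary"]
        assert ff0.mean() == pytest.approx(16.16, abs=2.5)
        assert ff0.std() == pytest.approx(25.16, rel=0.25)
        strata = truth["stratum"].value_counts(normalize=True)
        assert strata["normal"] == pytest.approx(0.5, abs=0.08)
        assert strata["end_stage"] == pytest.approx(0.1, abs=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(seed=None)
        with pytest.raises(ValueError):
            CohortConfig(seed=1, visit_nominal_months=(0, 27, 12, 49))
        with pytest.raises(ValueError):
            CohortConfig(seed=1, dropout_prob_per_visit=(0.5, 1.2, 0.1))

    def test_draw_subject_truth_consistency(self):
        rng = _subject_rng(99, 0, 0)
        p = draw_subject(rng, "P001", "patient")
        w = np.array([p.csa0_muscle[k] for k in p.ff0_muscle])
        ff = np.array(list(p.ff0_muscle.values()))
        assert (w @ ff) / w.sum() == pytest.approx(p.ff0_summary, abs=1e-6)


class TestRenderVisitImage:
    def test_noise_free_rois_are_exact(self):
        img = render_visit_image({lab: 30.0 for lab in range(1, 13)})
        for lab in range(1, 13):
            assert (img.ff_map[img.label_map == lab] == 30.0).all()

    def test_overlapping_layout_rejected(self):
        layout = {1: (50, 50, 20, 20), 2: (55, 55, 20, 20)}
        with pytest.raises(ValueError, match="overlap"):
            render_visit_image({1: 10.0, 2: 20.0}, layout=layout)

    def test_artifact_shifts_naive_mean_by_mixture_arithmetic(self):
        """A +60 %ff patch over 20 % of an ROI lifts its naive mean by
        ~12 %ff (0.2 x 60)."""
        img = render_visit_image(
            {lab: 20.0 for lab in range(1, 13)},
            artifacts=[{"label": 3, "fraction": 0.2, "delta": 60.0}])
        roi = img.label_map == 3
        assert img.ff_map[roi].mean() - 20.0 == pytest.approx(12.0, abs=0.3)
        assert img.artifact_mask[roi].mean() == pytest.approx(0.2, abs=0.01)
        assert not img.artifact_mask[~roi].any()

    def test_requested_mean_outside_range_rejected(self):
        with pytest.raises(ValueError):
            render_visit_image({lab: 0.0 for lab in range(1, 13)})
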