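"""Trajectory model: evaluation, linearity, trial simulation, refitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bonebridge import (
    Subject,
    TrajectoryCoefficients,
    TreatmentScenario,
    TScoreReference,
    apply_treatment,
    bmd_to_tscore,
    delta_bmd,
    fit_trajectory,
    simulate_trial,
    tscore_to_bmd,
)

DEFAULTS = TrajectoryCoefficients()


class TestDeltaBmd:
    @pytest.mark.parametrize(
        "regimen,t,r,expected",
        [
            ("QD150", 1.0, 0.0, -0.0051),
            ("QD150", 0.0, 5.0 / 2.5, 0.0),  # no treatment, no effect
            ("BID200", 0.0, 1.0, 0.0),
            ("QD150", 1.0, 0.5, -0.00525),
            ("BID200", 0.25, 0.5, -0.0049375),
            ("BID200", 1.0, 0.0, -0.0051 - 0.0188),
        ],
    )
    def test_hand_evaluated_scenarios(self, regimen, t, r, expected):
        d = delta_bmd(DEFAULTS, TreatmentScenario(regimen, t, r))
        assert d == pytest.approx(expected, abs=1e-12)

    @given(
        t=st.floats(0.01, 2.0),
        r=st.floats(0.0, 3.0),
        regimen=st.sampled_from(["QD150", "BID200"]),
    )
    @settings(max_examples=60, derandomize=True)
    def test_linearity_in_durations(self, t, r, regimen):
        """Doubling t at fixed r doubles the t-linear part; linear in r at fixed t."""
        d = delta_bmd(DEFAULTS, TreatmentScenario(regimen, t, r))
        d0 = delta_bmd(DEFAULTS, TreatmentScenario(regimen, t, 0.0))
        d2r = delta_bmd(DEFAULTS, TreatmentScenario(regimen, t, 2 * r))
        assert d2r - d == pytest.approx(d - d0, rel=1e-9, abs=1e-15)
        half = delta_bmd(DEFAULTS, TreatmentScenario(regimen, t / 2, r))
        assert 2 * half == pytest.approx(d, rel=1e-9, abs=1e-15)

    def test_paper_scenarios_similar(self):
        """Both base-case regimens lose 0.004-0.006 g/cm^2 and differ < 0.001."""
        d_qd = delta_bmd(DEFAULTS, TreatmentScenario.qd150())
        d_bid = delta_bmd(DEFAULTS, TreatmentScenario.bid200())
        assert 0.004 < -d_qd < 0.006
        assert 0.004 < -d_bid < 0.006
        assert abs(d_qd - d_bid) < 0.001

    @pytest.mark.parametrize("t,r", [(-0.1, 0.0), (0.5, -1.0), (3.0, 0.0)])
    def test_invalid_durations_rejected(self, t, r):
        with pytest.raises(ValueError):
            TreatmentScenario("QD150", t, r)


class TestApplyTreatment:
    def test_worked_example_reference_bmd(self):
        """Average BMD of the oldest stratum under the 12+6-month course."""
        s = Subject(id=1, age=75, race="white", bmi=28.0, fn_bmd=0.664)
        out = apply_treatment(s, DEFAULTS, TreatmentScenario.qd150())
        assert out.fn_bmd == pytest.approx(0.664 - 0.00525, abs=1e-12)

    def test_non_bmd_fields_preserved(self, small_cohort):
        out = apply_treatment(small_cohort, DEFAULTS, TreatmentScenario.qd150())
        other = [c for c in small_cohort.columns if c != "fn_bmd"]
        pd.testing.assert_frame_equal(out[other], small_cohort[other])
        assert (out["fn_bmd"] < small_cohort["fn_bmd"]).all()

    def test_null_scenario_is_identity(self, small_cohort):
        out = apply_treatment(
            small_cohort, DEFAULTS, TreatmentScenario("QD150", 0.0, 1.0)
        )
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_degenerate_bmd_rejected(self):
        s = Subject(id=1, age=60, race="white", bmi=25.0, fn_bmd=0.004)
        with pytest.raises(ValueError, match="<= 0"):
            apply_treatment(s, DEFAULTS, TreatmentScenario("QD150", 1.0, 0.0))


class TestTScore:
    def test_reference_mean_maps_to_zero(self):
        assert bmd_to_tscore(0.858) == pytest.approx(0.0)

    def test_minus_one_sd(self):
        assert bmd_to_tscore(0.738) == pytest.approx(-1.0)

    @given(st.floats(0.1, 1.9))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, bmd):
        assert tscore_to_bmd(bmd_to_tscore(bmd)) == pytest.approx(bmd, rel=1e-12)

    def test_invalid_reference_sd(self):
        with pytest.raises(ValueError):
            TScoreReference(young_adult_mean=0.858, young_adult_sd=0.0)


class TestSimulateTrial:
    def test_noise_free_visit_is_fixed_effect_sum(self):
        rec = simulate_trial(
            DEFAULTS, 1, {"QD": 1.0}, [12], subject_sd=0.0, residual_sd=0.0,
            baseline_mean=0.8, seed=0,
        )
        assert len(rec) == 1
        assert rec["treatment_years"].iloc[0] == 1.0
        assert rec["recovery_years"].iloc[0] == 0.0
        assert rec["bmd"].iloc[0] == pytest.approx(0.7949, abs=1e-12)

    def test_zero_subjects_gives_empty_frame(self):
        rec = simulate_trial(DEFAULTS, 0, seed=0)
        assert len(rec) == 0
        assert "bmd" in rec.columns

    def test_deterministic_given_seed(self):
        a = simulate_trial(DEFAULTS, 20, seed=4)
        b = simulate_trial(DEFAULTS, 20, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_visit_grid_rejected(self):
        with pytest.raises(ValueError, match="visit"):
            simulate_trial(DEFAULTS, 5, visit_grid=[], seed=0)

    def test_placebo_arms_untreated_before_switch(self):
        rec = simulate_trial(DEFAULTS, 50, {"PBO_QD": 1.0}, [0, 3, 6, 9, 12], seed=1)
        early = rec[rec["treatment_years"] == 0]
        assert set(early.groupby("subject_id").size()) == {3}  # months 0, 3, 6


class TestFitTrajectory:
    def test_noise_free_records_identify_exactly(self):
        rec = simulate_trial(DEFAULTS, 30, subject_sd=0.0, residual_sd=0.0, seed=3)
        fit = fit_trajectory(rec)
        np.testing.assert_allclose(
            fit.coefficients.as_array(), DEFAULTS.as_array(), atol=1e-10
        )

    @pytest.mark.parametrize("n", [150, 764])
    def test_parameter_recovery_within_3_se(self, n):
        rec = simulate_trial(
            DEFAULTS, n, subject_sd=0.11, residual_sd=0.02, seed=20240901
        )
        fit = fit_trajectory(rec)
        z = (fit.coefficients.as_array() - DEFAULTS.as_array()) / fit.se
        assert np.all(np.abs(z) < 3)

    def test_standard_errors_shrink_with_n(self):
        se = {}
        for n in (150, 1200):
            rec = simulate_trial(DEFAULTS, n, seed=6)
            se[n] = fit_trajectory(rec).se
        assert np.all(se[1200] < se[150])

    def test_single_state_not_identifiable(self):
        rec = pd.DataFrame(
            {
                "subject_id": [1, 2, 3, 4],
                "regimen": ["QD150", "QD150", "BID200", "BID200"],
                "treatment_years": 1.0,
                "recovery_years": 0.0,
                "bmd": [0.8, 0.81, 0.79, 0.8],
            }
        )
        with pytest.raises(ValueError, match="single"):
            fit_trajectory(rec)

    def test_missing_regimen_rejected(self):
        rec = simulate_trial(DEFAULTS, 20, {"QD": 1.0}, seed=2)
        with pytest.raises(ValueError, match="BID200"):
            fit_trajectory(rec)

    def test_agrees_with_mixed_effects_oracle(self):
        """Within-subject estimator vs a random-intercept mixed model (REML)."""
        smf = pytest.importorskip("statsmodels.formula.api")
        rec = simulate_trial(DEFAULTS, 400, subject_sd=0.1, residual_sd=0.02, seed=12)
        fit = fit_trajectory(rec)
        rec = rec.assign(bid=(rec["regimen"] == "BID200").astype(float))
        oracle = smf.mixedlm(
            "bmd ~ treatment_years + treatment_years:recovery_years"
            " + treatment_years:bid + treatment_years:recovery_years:bid",
            rec,
            groups=rec["subject_id"],
        ).fit()
        ours = fit.coefficients.as_array()
        theirs = oracle.params[
            [
                "treatment_years",
                "treatment_years:recovery_years",
                "treatment_years:bid",
                "treatment_years:recovery_years:bid",
            ]
        ].to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=2 * fit.se.max())
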