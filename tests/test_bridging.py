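"""Bridging simulation: paired risks, strata, NNH, sensitivities, thresholds."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bonebridge import (
    TrajectoryCoefficients,
    TreatmentScenario,
    age_at_threshold,
    compute_nnh,
    mixed_dosing_sensitivity,
    ra_sensitivity,
    run_scenario,
    summarize_strata,
)
from bonebridge.bridging import BMD_BANDS, stratum_nnh

QD = TreatmentScenario.qd150()
BID = TreatmentScenario.bid200()


@pytest.fixture(scope="module")
def paired(small_cohort, coeffs, default_params):
    return run_scenario(small_cohort, coeffs, QD, default_params)


class TestRunScenario:
    def test_null_scenario_gives_zero_deltas(self, small_cohort, coeffs, default_params):
        paired = run_scenario(
            small_cohort, coeffs, TreatmentScenario("QD150", 0.0, 0.5), default_params
        )
        assert (paired["delta_hip"] == 0).all()
        assert (paired["delta_mof"] == 0).all()

    def test_harm_non_negative_for_bmd_loss(self, paired):
        """A BMD-lowering scenario cannot reduce any subject's risk."""
        assert (paired["delta_hip"] >= 0).all()
        assert (paired["delta_mof"] >= 0).all()

    def test_treated_threshold_set_contains_untreated(self, paired):
        assert not (paired["untreated_meets"] & ~paired["treated_meets"]).any()

    def test_deltas_are_exact_differences(self, paired):
        np.testing.assert_array_equal(
            paired["delta_hip"], paired["treated_hip"] - paired["untreated_hip"]
        )

    def test_single_subject_constant_hazard_analytic(
        self, coeffs, constant_hazard_params
    ):
        """With flat hazards the paired risks have a closed form via the
        gradient factor 2^(dBMD/SD)."""
        params = dataclasses.replace(
            constant_hazard_params,
            hip=dataclasses.replace(constant_hazard_params.hip, grad_per_sd=2.0),
        )
        cohort = pd.DataFrame(
            [
                dict(
                    id=1, age=70, race="white", bmi=25.0, fn_bmd=0.858,
                    prior_fracture=False, parental_fracture=False,
                    current_smoker=False, glucocorticoid_use=False,
                    rheumatoid_arthritis=False, heavy_alcohol=False,
                )
            ]
        )
        paired = run_scenario(cohort, coeffs, QD, params)
        c = 0.003  # flat hip hazard at T-score 0
        d_sd = 0.00525 / 0.120  # BMD loss in reference-SD units
        expected_untreated = 100 * (1 - np.exp(-10 * c))
        expected_treated = 100 * (1 - np.exp(-10 * c * 2**d_sd))
        assert paired["untreated_hip"].iloc[0] == pytest.approx(
            expected_untreated, abs=1e-4
        )
        assert paired["treated_hip"].iloc[0] == pytest.approx(expected_treated, abs=1e-4)


class TestSummarizeStrata:
    def test_grid_is_strata_times_bands(self, paired):
        s = summarize_strata(paired)
        assert len(s) == 3 * len(BMD_BANDS)
        assert set(s["bmd_band"]) == set(BMD_BANDS)

    def test_medians_match_brute_force(self, paired):
        s = summarize_strata(paired)
        ages = paired["age"].to_numpy()
        sub = np.sort(
            paired.loc[(ages >= 60) & (ages <= 69), "untreated_hip"].to_numpy()
        )
        n = len(sub)
        brute = sub[n // 2] if n % 2 else (sub[n // 2 - 1] + sub[n // 2]) / 2
        row = s[(s.age_stratum == "60-69") & (s.bmd_band == "all")]
        assert row["hip_untreated_median"].iloc[0] == pytest.approx(brute)

    def test_identical_subjects_leave_outer_bands_empty(self, coeffs, default_params):
        row = dict(
            id=1, age=65, race="white", bmi=25.0, fn_bmd=0.7,
            prior_fracture=False, parental_fracture=False, current_smoker=False,
            glucocorticoid_use=False, rheumatoid_arthritis=False, heavy_alcohol=False,
        )
        cohort = pd.DataFrame([dict(row, id=i) for i in range(4)])
        paired = run_scenario(cohort, coeffs, QD, default_params)
        s = summarize_strata(paired)
        mid = s[(s.age_stratum == "60-69") & (s.bmd_band == "p25-p75")]
        outer = s[(s.age_stratum == "60-69") & (s.bmd_band.isin(["<p25", ">p75"]))]
        assert mid["n"].iloc[0] == 4
        assert (outer["n"] == 0).all()
        # medians equal means for identical subjects
        assert mid["hip_untreated_median"].iloc[0] == pytest.approx(
            mid["hip_untreated_mean"].iloc[0]
        )

    def test_empty_stratum_row_has_null_statistics(self, coeffs, default_params):
        row = dict(
            id=1, age=55, race="white", bmi=25.0, fn_bmd=0.7,
            prior_fracture=False, parental_fracture=False, current_smoker=False,
            glucocorticoid_use=False, rheumatoid_arthritis=False, heavy_alcohol=False,
        )
        paired = run_scenario(pd.DataFrame([row]), coeffs, QD, default_params)
        s = summarize_strata(paired)
        old = s[(s.age_stratum == "70-79") & (s.bmd_band == "all")]
        assert old["n"].iloc[0] == 0
        assert np.isnan(old["hip_untreated_median"].iloc[0])

    def test_threshold_counts_bounded_by_n(self, paired):
        s = summarize_strata(paired)
        ok = s.dropna(subset=["n_untreated_meets"])
        assert (ok["n_untreated_meets"] <= ok["n"]).all()
        assert (ok["n_treated_meets"] >= ok["n_untreated_meets"]).all()


class TestNNH:
    def test_reciprocal_of_unrounded_difference(self):
        raw, rounded = compute_nnh(4.25, 4.50)
        assert raw == pytest.approx(1 / 0.0025)
        assert rounded == 400

    def test_rounding_to_nearest_integer(self):
        raw, rounded = compute_nnh(4.50, 4.50 + 0.1556)
        assert rounded == 643

    def test_no_harm_not_defined(self):
        raw, rounded = compute_nnh(5.0, 5.0)
        assert np.isnan(raw) and rounded is None

    def test_stratum_nnh_matches_oracle(self, paired):
        out = stratum_nnh(paired, (70, 79))
        ages = paired["age"].to_numpy()
        sub = paired[(ages >= 70) & (ages <= 79)]
        for outcome in ("hip", "mof"):
            diff = (
                sub[f"treated_{outcome}"].mean() - sub[f"untreated_{outcome}"].mean()
            ) / 100.0
            assert out[outcome]["raw"] == pytest.approx(1.0 / diff)
            assert out[outcome]["rounded"] == round(1.0 / diff)


class TestMixedDosing:
    def test_degenerate_fractions_reduce_to_pure_scenario(
        self, small_cohort, coeffs, default_params, paired
    ):
        mixed = mixed_dosing_sensitivity(
            small_cohort, coeffs, default_params, fractions=(1.0, 0.0), seed=3
        )
        pure = summarize_strata(paired)
        pd.testing.assert_frame_equal(mixed, pure)

    def test_invalid_fractions_rejected(self, small_cohort, coeffs, default_params):
        with pytest.raises(ValueError, match="fractions"):
            mixed_dosing_sensitivity(
                small_cohort, coeffs, default_params, fractions=(0.7, 0.7)
            )

    def test_median_deltas_bounded_by_pure_scenarios(
        self, small_cohort, coeffs, default_params
    ):
        """Each stratum's mixed-dosing median delta lies within (or within
        Monte-Carlo noise of) the interval spanned by the two pure scenarios."""
        pure = {
            name: summarize_strata(run_scenario(small_cohort, coeffs, s, default_params))
            for name, s in (("qd", QD), ("bid", BID))
        }
        mixed = mixed_dosing_sensitivity(
            small_cohort, coeffs, default_params, fractions=(0.5, 0.5), seed=5
        )
        for stratum in ("50-59", "60-69", "70-79"):
            sel = lambda s: s[(s.age_stratum == stratum) & (s.bmd_band == "all")]
            lo = min(
                sel(pure["qd"])["hip_median_diff"].iloc[0],
                sel(pure["bid"])["hip_median_diff"].iloc[0],
            )
            hi = max(
                sel(pure["qd"])["hip_median_diff"].iloc[0],
                sel(pure["bid"])["hip_median_diff"].iloc[0],
            )
            m = sel(mixed)["hip_median_diff"].iloc[0]
            tol = 0.25 * (hi - lo) + 1e-6
            assert lo - tol <= m <= hi + tol

    def test_two_assignment_seeds_differ_only_within_noise(
        self, small_cohort, coeffs, default_params
    ):
        a = mixed_dosing_sensitivity(small_cohort, coeffs, default_params, seed=1)
        b = mixed_dosing_sensitivity(small_cohort, coeffs, default_params, seed=2)
        diff = (a["hip_median_diff"] - b["hip_median_diff"]).abs().max()
        # resampling noise is bounded by the small QD-vs-BID scenario gap
        assert diff < 0.05


class TestRASensitivity:
    def test_zero_prevalence_cohort_unchanged(self, coeffs, default_params, small_cohort):
        cohort = small_cohort.copy()
        cohort["rheumatoid_arthritis"] = False
        out = ra_sensitivity(cohort, coeffs, QD, default_params)
        pd.testing.assert_frame_equal(
            out["original"]["paired"], out["no_ra"]["paired"]
        )

    def test_absolute_risks_weakly_decrease(self, small_cohort, coeffs, default_params):
        out = ra_sensitivity(small_cohort, coeffs, QD, default_params)
        a = out["original"]["paired"]
        b = out["no_ra"]["paired"]
        assert (b["untreated_hip"] <= a["untreated_hip"] + 1e-12).all()
        assert (b["untreated_mof"] <= a["untreated_mof"] + 1e-12).all()

    def test_single_ra_subject_risks_strictly_decrease(self, coeffs, default_params):
        row = dict(
            id=1, age=70, race="white", bmi=25.0, fn_bmd=0.6,
            prior_fracture=False, parental_fracture=False, current_smoker=False,
            glucocorticoid_use=False, rheumatoid_arthritis=True, heavy_alcohol=False,
        )
        out = ra_sensitivity(pd.DataFrame([row]), coeffs, QD, default_params)
        assert (
            out["no_ra"]["paired"]["untreated_hip"].iloc[0]
            < out["original"]["paired"]["untreated_hip"].iloc[0]
        )


class TestAgeAtThreshold:
    def test_trivial_threshold_reached_at_grid_minimum(self, default_params):
        assert age_at_threshold(0.664, default_params, threshold_pct=1e-4) == 50.0

    def test_lower_bmd_crosses_earlier(self, default_params):
        a = age_at_threshold(0.664, default_params)
        b = age_at_threshold(0.644, default_params)
        c = age_at_threshold(0.624, default_params)
        assert c < b < a

    def test_unreachable_threshold_rejected(self, default_params):
        with pytest.raises(ValueError, match="not reached"):
            age_at_threshold(1.5, default_params, threshold_pct=99.0)
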