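"""Regression, decomposition, beta sweep, ANCOVA, and delta-SBE summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bexcess import (
    DegenerateDesignError,
    StudyDesign,
    ancova,
    base_excess,
    beta_sweep,
    fit_sbe_slope,
    generate_multistudy,
    generate_study,
    max_delta_sbe,
    slope_decomposition,
    solve_ph_for_target_sbe,
)
from bexcess.simulate import OBSERVATION_COLUMNS, TitrationDataset

from conftest import noiseless_design


def frame_from_xy(pco2, sbe):
    """Observation table whose SBE at beta=0 equals ``sbe`` exactly.

    Sets ph = 7.40 so the pH term vanishes and hco3 = 24.8 + sbe, making
    base_excess(hco3, ph, any_beta) = sbe.  Lets hand-picked (x, y) points
    drive the regression directly.
    """
    pco2 = np.asarray(pco2, dtype=float)
    sbe = np.asarray(sbe, dtype=float)
    return pd.DataFrame(
        {
            "study_id": "constructed",
            "subject_id": [f"s{i}" for i in range(pco2.size)],
            "exposure_id": "e01",
            "pco2_mmhg": pco2,
            "ph": 7.40,
            "hco3_mmol_l": 24.8 + sbe,
        }
    )[OBSERVATION_COLUMNS]


class TestFitSbeSlope:
    def test_exact_collinear_fit(self):
        """Three collinear points give the exact slope with zero residuals."""
        frame = frame_from_xy([40.0, 50.0, 60.0], [0.0, -0.25, -0.5])
        fit = fit_sbe_slope(frame, 16.2)
        assert fit.slope == pytest.approx(-0.025, abs=1e-12)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance_of_slope(self, volunteer_dataset):
        frame = volunteer_dataset.frame.copy()
        shifted = frame.copy()
        shifted["hco3_mmol_l"] += 3.0  # shifts SBE by +3 at every beta
        f0 = fit_sbe_slope(frame, 16.2)
        f1 = fit_sbe_slope(shifted, 16.2)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-12)
        assert f1.intercept == pytest.approx(f0.intercept + 3.0, abs=1e-9)

    def test_slope_difference_follows_decomposition(self, volunteer_dataset):
        """slope(b1) - slope(b2) = b*(b1 - b2) with b from the decomposition."""
        d = slope_decomposition(volunteer_dataset)
        s1 = fit_sbe_slope(volunteer_dataset, 16.2).slope
        s2 = fit_sbe_slope(volunteer_dataset, 9.0).slope
        assert s1 - s2 == pytest.approx(d.b * (16.2 - 9.0), abs=1e-12)

    def test_matches_statsmodels_reference(self, volunteer_dataset):
        frame = volunteer_dataset.frame
        y = base_excess(frame["hco3_mmol_l"], frame["ph"], 16.2)
        res = sm.OLS(np.asarray(y), sm.add_constant(frame["pco2_mmhg"])).fit()
        fit = fit_sbe_slope(volunteer_dataset, 16.2)
        assert fit.slope == pytest.approx(res.params.iloc[1], rel=1e-12)
        assert fit.p_value == pytest.approx(res.pvalues.iloc[1], rel=1e-12)

    def test_cluster_robust_changes_se_not_slope(self, volunteer_dataset):
        plain = fit_sbe_slope(volunteer_dataset, 16.2)
        robust = fit_sbe_slope(volunteer_dataset, 16.2, cluster_robust=True)
        assert robust.slope == pytest.approx(plain.slope, rel=1e-12)
        assert robust.slope_se != plain.slope_se

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_sbe_slope(frame_from_xy([40.0, 40.0, 40.0], [0, 1, 2]), 16.2)
        with pytest.raises(DegenerateDesignError):
            fit_sbe_slope(frame_from_xy([40.0, 50.0], [0, 1]), 16.2)


class TestSlopeDecomposition:
    def test_noiseless_data_crosses_zero_at_beta_true(self, noiseless_dataset):
        d = slope_decomposition(noiseless_dataset)
        assert d.a + 12.1 * d.b == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_matches_sweep_pointwise(self, volunteer_dataset):
        """Brute-force slope(beta) equals a + b*beta across the whole grid."""
        d = slope_decomposition(volunteer_dataset)
        sweep = beta_sweep(volunteer_dataset, (5.0, 20.0, 1001))
        assert np.max(np.abs(sweep.slopes - d.slope_at(sweep.grid))) < 1e-10

    def test_component_slopes_match_statsmodels(self, volunteer_dataset):
        frame = volunteer_dataset.frame
        x = sm.add_constant(frame["pco2_mmhg"].to_numpy())
        a_ref = sm.OLS(frame["hco3_mmol_l"].to_numpy() - 24.8, x).fit()
        b_ref = sm.OLS(frame["ph"].to_numpy() - 7.40, x).fit()
        d = slope_decomposition(volunteer_dataset)
        assert d.a == pytest.approx(a_ref.params[1], rel=1e-12)
        assert d.b == pytest.approx(b_ref.params[1], rel=1e-12)
        assert d.var_a == pytest.approx(a_ref.bse[1] ** 2, rel=1e-10)
        assert d.var_b == pytest.approx(b_ref.bse[1] ** 2, rel=1e-10)


class TestBetaSweep:
    def test_noiseless_recovery_to_grid_resolution(self, noiseless_dataset):
        sweep = beta_sweep(noiseless_dataset)
        step = 15.0 / 9999
        assert abs(sweep.beta_star - 12.1) <= step

    def test_beta_star_matches_analytic_zero_crossing(self, volunteer_dataset):
        sweep = beta_sweep(volunteer_dataset)
        step = 15.0 / 9999
        assert abs(sweep.beta_star - sweep.beta_analytic) <= step

    def test_slope_ci_matches_statsmodels_at_sampled_betas(
        self, volunteer_dataset
    ):
        """Per-beta OLS via statsmodels reproduces the vectorized sweep CI."""
        sweep = beta_sweep(volunteer_dataset, (5.0, 20.0, 16))
        frame = volunteer_dataset.frame
        x = sm.add_constant(frame["pco2_mmhg"].to_numpy())
        for i, b in enumerate(sweep.grid):
            y = np.asarray(base_excess(frame["hco3_mmol_l"], frame["ph"], b))
            res = sm.OLS(y, x).fit()
            assert sweep.slopes[i] == pytest.approx(res.params[1], abs=1e-12)
            lo, hi = res.conf_int(alpha=0.05)[1]
            inside = lo <= 0.0 <= hi
            assert inside == (sweep.ci_low <= b <= sweep.ci_high)

    def test_schlichtig_scaling_preserves_beta_star(self, volunteer_dataset):
        """Scaling the response by 0.9287 does not move the zero crossing."""
        sweep = beta_sweep(volunteer_dataset)
        frame = volunteer_dataset.frame.copy()
        # scale both deviation terms: hco3' - 24.8 = 0.9287 (hco3 - 24.8),
        # ph' - 7.40 = 0.9287 (ph - 7.40); then BE'(beta) = 0.9287 BE(beta)
        frame["hco3_mmol_l"] = 24.8 + 0.9287 * (frame["hco3_mmol_l"] - 24.8)
        frame["ph"] = 7.40 + 0.9287 * (frame["ph"] - 7.40)
        scaled = beta_sweep(frame)
        assert scaled.beta_star == sweep.beta_star
        assert scaled.ci_low == sweep.ci_low
        assert scaled.ci_high == sweep.ci_high

    def test_pco2_translation_moves_nothing_but_intercepts(
        self, volunteer_dataset
    ):
        frame = volunteer_dataset.frame.copy()
        frame["pco2_mmhg"] += 25.0
        assert beta_sweep(frame).beta_star == beta_sweep(
            volunteer_dataset
        ).beta_star

    def test_ci_widens_with_noise(self):
        widths = []
        for ph_sd in (0.002, 0.006, 0.018):
            reps = []
            for seed in range(20):
                ds = generate_study(
                    StudyDesign(study_id="w", ph_noise_sd=ph_sd, seed=seed)
                )
                sw = beta_sweep(ds)
                if not sw.ci_degenerate:
                    reps.append(sw.ci_high - sw.ci_low)
            widths.append(np.mean(reps))
        assert widths[0] < widths[1] < widths[2]

    def test_delta_method_ci_brackets_analytic_estimate(self, volunteer_dataset):
        sweep = beta_sweep(volunteer_dataset)
        assert sweep.delta_ci_low < sweep.beta_analytic < sweep.delta_ci_high

    def test_nonidentifiable_flag_when_ph_flat(self):
        frame = frame_from_xy([40.0, 50.0, 60.0, 70.0], [0.1, -0.2, 0.05, 0.0])
        sweep = beta_sweep(frame)  # ph constant -> b = 0
        assert not sweep.identifiable


class TestAncova:
    def two_identical_studies(self):
        designs = [
            noiseless_design(study_id="a"),
            noiseless_design(study_id="b"),
        ]
        return generate_multistudy(designs, shared_seed=1)

    def test_identical_studies_have_null_interaction(self):
        ds = self.two_identical_studies()
        res = ancova(ds, 16.2)
        slopes = [f.slope for f in res.per_study_fits.values()]
        assert slopes[0] == pytest.approx(slopes[1], abs=1e-9)
        assert res.slope_f == pytest.approx(0.0, abs=1e-6)

    def test_baseline_shift_moves_intercepts_not_slopes(self):
        designs = [
            noiseless_design(study_id="a", baseline_sbe_mean=0.0),
            noiseless_design(study_id="b", baseline_sbe_mean=3.0),
        ]
        res = ancova(generate_multistudy(designs, shared_seed=1), 16.2)
        # slopes agree up to the small buffer-curve curvature both share
        slopes = [f.slope for f in res.per_study_fits.values()]
        assert slopes[0] == pytest.approx(slopes[1], abs=2e-3)
        assert res.slope_p > 0.05
        assert res.intercept_p < 1e-10

    def test_distinct_buffer_powers_detected(self):
        designs = [
            StudyDesign(study_id="a", beta_true_mean=10.0),
            StudyDesign(study_id="b", beta_true_mean=14.0, baseline_sbe_mean=2.0),
        ]
        res = ancova(generate_multistudy(designs, shared_seed=3), 16.2)
        assert res.slope_p < 0.05
        assert res.intercept_p < 0.05

    def test_single_study_rejected(self, volunteer_dataset):
        with pytest.raises(DegenerateDesignError, match="2 studies"):
            ancova(volunteer_dataset, 16.2)

    def test_per_study_fits_cover_all_studies(self):
        ds = self.two_identical_studies()
        res = ancova(ds, 16.2)
        assert set(res.per_study_fits) == {"a", "b"}


class TestMaxDeltaSbe:
    def test_all_zero_at_beta_true(self, noiseless_dataset):
        deltas = max_delta_sbe(noiseless_dataset, 12.1)
        assert deltas.cohort_min == pytest.approx(0.0, abs=1e-6)
        assert deltas.cohort_max == pytest.approx(0.0, abs=1e-6)

    def test_negative_drift_at_overestimated_beta(self, noiseless_dataset):
        """Evaluating at beta > beta_true forces SBE down the CO2 ramp."""
        deltas = max_delta_sbe(noiseless_dataset, 16.2)
        per = deltas.per_subject
        assert (per["delta_extreme"] < 0).all()
        d = slope_decomposition(noiseless_dataset)
        assert d.b < 0  # sign of the drift comes from b < 0 and beta > beta*
        # exact endpoint delta: every subject shares beta_true=12.1, sbe=0
        ph40 = solve_ph_for_target_sbe(40.0, 0.0, 12.1)
        ph85 = solve_ph_for_target_sbe(85.0, 0.0, 12.1)
        assert deltas.cohort_min == pytest.approx(
            (16.2 - 12.1) * (ph85 - ph40), abs=1e-8
        )

    def test_duplicated_exposure_leaves_extreme_unchanged(self, noiseless_dataset):
        frame = noiseless_dataset.frame.copy()
        dup = frame.iloc[[-1]].assign(exposure_id="e99")
        doubled = pd.concat([frame, dup], ignore_index=True)
        a = max_delta_sbe(noiseless_dataset, 16.2)
        b = max_delta_sbe(doubled, 16.2)
        pd.testing.assert_series_equal(
            a.per_subject["delta_extreme"], b.per_subject["delta_extreme"]
        )

    def test_single_exposure_subject_excluded_with_warning(self):
        frame = frame_from_xy([40.0, 50.0, 60.0], [0.0, -0.3, -0.6])
        frame["subject_id"] = ["s1", "s1", "s2"]
        with pytest.warns(UserWarning, match="single exposure"):
            deltas = max_delta_sbe(frame, 16.2)
        assert deltas.n_subjects == 1
        assert deltas.n_excluded == 1


def test_dataset_subset_roundtrip(volunteer_dataset):
    sub = volunteer_dataset.subset("volunteers")
    assert isinstance(sub, TitrationDataset)
    assert len(sub) == len(volunteer_dataset)


def test_design_replace_helper():
    d = dataclasses.replace(StudyDesign(study_id="x"), seed=9)
    assert d.seed == 9
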