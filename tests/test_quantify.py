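"""Strain-ratio computation, aggregation and mechanical-testing fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cordelast as ce
from cordelast.elasto import Elastogram, TrackingParams
from cordelast.quantify import MIN_ROI_PIXELS, ROIMasks


def _uniform_elastogram(value=0.01, shape=(60, 40)):
    return Elastogram(
        strain=np.full(shape, value), quality_mask=np.ones(shape, bool),
        ncc=np.ones(shape), grid_z_mm=np.arange(shape[0]) * 0.2,
        grid_x_mm=np.arange(shape[1]) * 0.3, params=TrackingParams(),
    )


def _split_masks(shape=(60, 40)):
    cord = np.zeros(shape, bool)
    ref = np.zeros(shape, bool)
    cord[10:20, 5:15] = True
    ref[30:50, 5:35] = True
    return ROIMasks(cord_mask=cord, reference_mask=ref)


class TestStrainRatio:
    def test_uniform_strain_gives_unit_ratio(self):
        sr = ce.compute_strain_ratio(_uniform_elastogram(), _split_masks())
        assert sr == pytest.approx(1.0, rel=1e-12)

    def test_ratio_invariant_under_global_scaling(self):
        el = _uniform_elastogram()
        rng = np.random.default_rng(3)
        el.strain = el.strain * (1 + 0.3 * rng.standard_normal(el.strain.shape))
        masks = _split_masks()
        sr1 = ce.compute_strain_ratio(el, masks)
        el.strain = el.strain * 7.3
        assert ce.compute_strain_ratio(el, masks) == pytest.approx(sr1, rel=1e-12)

    def test_overlapping_masks_rejected(self):
        m = np.zeros((10, 10), bool)
        m[2:5] = True
        with pytest.raises(ValueError, match="disjoint"):
            ROIMasks(cord_mask=m, reference_mask=m)

    def test_insufficient_pixels_error_names_the_mask(self):
        el = _uniform_elastogram()
        masks = _split_masks()
        el.quality_mask[masks.cord_mask] = False
        with pytest.raises(ce.ROIError, match="cord"):
            ce.compute_strain_ratio(el, masks)

    def test_nonpositive_reference_mean_rejected(self):
        el = _uniform_elastogram(value=-0.01)
        with pytest.raises(ce.UndefinedRatioError):
            ce.compute_strain_ratio(el, _split_masks())

    def test_minimum_pixel_contract(self):
        assert MIN_ROI_PIXELS == 25

    def test_masks_erode_with_margin(self, small_spec):
        gz = np.arange(0, 15, 0.2)
        gx = np.arange(0, 12, 0.3)
        raw = ce.roi_masks_from_spec(small_spec, gz, gx)
        eroded = ce.roi_masks_from_spec(small_spec, gz, gx, margin_mm=1.0,
                                        cord_lateral_margin_mm=0.8)
        assert eroded.cord_mask.sum() < raw.cord_mask.sum()
        assert not np.any(eroded.cord_mask & ~raw.cord_mask)

    def test_five_fold_contrast_phantom_full_pipeline(self):
        """End-to-end: E_cord = 5 E_soft must read out as SR = 0.2 ± 0.05."""
        ph = ce.build_calibrated_phantom(0.2, seed=51)
        rf = ce.RFConfig(noise_snr_db=30.0)
        scat = ce.generate_scatterers(ph.spec, density=10.0,
                                      cell_area_mm2=ce.resolution_cell_area_mm2(rf), seed=52)
        pre = ce.synthesize_frame(scat, rf, seed=53)
        post = ce.deform_and_synthesize(scat, ph.truth, rf, seed=54)
        el = ce.run_elastography(pre, post)
        masks = ce.roi_masks_for_tracking(ph.spec, el, rf_config=rf)
        assert ce.compute_strain_ratio(el, masks) == pytest.approx(0.2, abs=0.05)


class TestAggregation:
    def test_hand_computed_group_summary(self):
        recs = [ce.StrainRatioRecord(animal_id=f"a{i}", group="g",
                                     per_acquisition=[[v]])
                for i, v in enumerate((0.1, 0.2, 0.3))]
        (summary,) = ce.aggregate_cohort(recs)
        assert summary.mean == pytest.approx(0.2)
        assert summary.sd == pytest.approx(0.1)
        assert summary.n == 3

    def test_repeated_identical_values_have_zero_sd(self):
        recs = [ce.StrainRatioRecord(animal_id=f"a{i}", group="g",
                                     per_acquisition=[[0.25, 0.25], [0.25]])
                for i in range(2)]
        (summary,) = ce.aggregate_cohort(recs)
        assert summary.sd == 0.0

    def test_record_aggregates_arithmetically_by_level(self):
        rec = ce.StrainRatioRecord(animal_id="a", group="g",
                                   per_acquisition=[[0.1, 0.3], [0.4]])
        np.testing.assert_allclose(rec.per_neighborhood, [0.2, 0.4])
        assert rec.per_animal == pytest.approx(0.3)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ce.aggregate_cohort([])
        with pytest.raises(ValueError):
            ce.StrainRatioRecord(animal_id="a", group="g", per_acquisition=[[-0.1]])


class TestEngineeringCurve:
    def test_linear_spring_has_constant_stiffness_ratio(self):
        d = np.linspace(0, 2.1, 50)
        k = 0.02    # N/mm
        curve = ce.engineering_curve(k * d, d, area0_mm2=7.0, length0_mm=3.0)
        ratio = curve.stress_kpa[1:] / curve.strain[1:]
        np.testing.assert_allclose(ratio, k * 3.0 / 7.0 * 1000.0, rtol=1e-12)

    def test_three_mm_sample_reaches_seventy_percent(self):
        d = np.linspace(0, 2.1, 10)
        curve = ce.engineering_curve(np.linspace(0, 1, 10), d, 7.0, 3.0)
        assert curve.strain.max() == pytest.approx(0.70)

    def test_doubling_area_halves_stress(self):
        d = np.linspace(0, 1, 20)
        f = np.linspace(0, 0.5, 20)
        c1 = ce.engineering_curve(f, d, 5.0, 3.0)
        c2 = ce.engineering_curve(f, d, 10.0, 3.0)
        np.testing.assert_allclose(c2.stress_kpa, c1.stress_kpa / 2.0)

    def test_non_monotone_strain_rejected(self):
        d = np.array([0.0, 0.5, 0.4, 0.8])
        with pytest.raises(ValueError, match="non-decreasing"):
            ce.engineering_curve(np.ones(4), d, 7.0, 3.0)


class TestModulusFit:
    def test_exact_linear_curve(self):
        eps = np.linspace(0, 0.7, 200)
        curve = ce.engineering_curve(2.0 * eps * 7.0 / 1000.0, eps * 3.0, 7.0, 3.0)
        est = ce.fit_modulus(curve)
        assert est.e_kpa == pytest.approx(2.0, rel=1e-9)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_curve_converges_to_known_slope(self):
        # sigma = eps + 10 eps^2: OLS slope of eps^2 on eps over [0.1, 0.2]
        # is 0.3, so the fitted modulus tends to 1 + 10*0.3 = 4
        eps = np.linspace(0, 0.7, 1000)
        sigma = eps + 10 * eps ** 2
        curve = ce.engineering_curve(sigma * 7.0 / 1000.0, eps * 3.0, 7.0, 3.0)
        assert ce.fit_modulus(curve).e_kpa == pytest.approx(4.0, rel=0.01)

    def test_constant_stress_offset_leaves_slope_unchanged(self):
        eps = np.linspace(0, 0.7, 300)
        sigma = 3.0 * eps
        c1 = ce.engineering_curve(sigma * 7 / 1000, eps * 3.0, 7.0, 3.0)
        c2 = ce.engineering_curve((sigma + 5.0) * 7 / 1000, eps * 3.0, 7.0, 3.0)
        assert ce.fit_modulus(c2).e_kpa == pytest.approx(ce.fit_modulus(c1).e_kpa, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        eps = np.sort(rng.uniform(0, 0.7, 60))
        sigma = rng.uniform(0, 20, 60).cumsum() / 60
        curve = ce.engineering_curve(sigma * 7 / 1000, eps * 3.0, 7.0, 3.0)
        sel = (eps >= 0.1 - 1e-9) & (eps <= 0.2 + 1e-9)
        if sel.sum() < 3:
            return
        x, y = eps[sel], sigma[sel]
        n = x.size
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        assert ce.fit_modulus(curve).e_kpa == pytest.approx(slope, rel=1e-10)

    def test_too_few_points_in_range_rejected(self):
        eps = np.array([0.0, 0.5, 0.7])
        curve = ce.engineering_curve(eps * 7 / 1000, eps * 3.0, 7.0, 3.0)
        with pytest.raises(ValueError):
            ce.fit_modulus(curve)


class TestHyperbolaFit:
    def test_exact_hyperbola_recovered_with_zero_residual(self):
        sr = np.array([0.1, 0.2, 0.4, 0.5])
        fit = ce.fit_hyperbola(sr, 3.0 / sr)
        assert fit.c_kpa == pytest.approx(3.0, rel=1e-12)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_two_points_on_common_hyperbola(self):
        fit = ce.fit_hyperbola([0.2, 0.4], [10.0, 5.0])
        assert fit.c_kpa == pytest.approx(2.0, rel=1e-12)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_noisy_points_match_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        sr = rng.uniform(0.1, 0.5, 20)
        e = 2.0 / sr + rng.normal(0, 0.4, 20)
        fit = ce.fit_hyperbola(sr, e)
        grid = np.linspace(1.0, 3.0, 200_001)
        ss = ((e[None, :] - grid[:, None] / sr[None, :]) ** 2).sum(axis=1)
        c_grid = grid[int(np.argmin(ss))]
        assert fit.c_kpa == pytest.approx(c_grid, rel=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ce.fit_hyperbola([0.2], [10.0])
        with pytest.raises(ValueError):
            ce.fit_hyperbola([0.2, -0.1], [10.0, 5.0])
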