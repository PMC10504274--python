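"""Phantom construction, compression mechanics and cohort generation."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import cordelast as ce
from cordelast.phantom import CORD, SOFT, VOID


class TestModulusMap:
    def test_homogeneous_cord_shares_one_modulus(self):
        spec = ce.PhantomSpec(lesion_fraction=0.0)
        mmap = ce.build_modulus_map(spec)
        cord_vals = np.unique(mmap.e_kpa[mmap.labels == CORD])
        assert cord_vals.size == 1 and cord_vals[0] == spec.e_cord_kpa

    def test_full_lesion_fraction_replaces_every_cord_pixel(self):
        spec = ce.PhantomSpec(lesion_fraction=1.0)
        mmap = ce.build_modulus_map(spec)
        assert np.all(mmap.e_kpa[mmap.labels == CORD] == spec.lesion_modulus_kpa)

    def test_lesion_pixel_count_matches_fraction(self):
        spec = ce.PhantomSpec(lesion_fraction=0.3, seed=42)
        mmap = ce.build_modulus_map(spec)
        n_cord = int((mmap.labels == CORD).sum())
        n_lesion = int((mmap.e_kpa == spec.lesion_modulus_kpa).sum())
        assert abs(n_lesion - round(0.3 * n_cord)) <= 1

    def test_labels_partition_window_and_void(self):
        spec = ce.PhantomSpec()
        mmap = ce.build_modulus_map(spec)
        x_lo, x_hi = spec.window_x_mm
        outside = (mmap.x_mm < x_lo) | (mmap.x_mm > x_hi)
        assert np.all(mmap.labels[:, outside] == VOID)
        assert np.all(mmap.labels[:, ~outside] != VOID)
        assert {SOFT, CORD, VOID} >= set(np.unique(mmap.labels))

    def test_deterministic_given_seed(self):
        a = ce.build_modulus_map(ce.PhantomSpec(lesion_fraction=0.3, seed=7))
        b = ce.build_modulus_map(ce.PhantomSpec(lesion_fraction=0.3, seed=7))
        np.testing.assert_array_equal(a.e_kpa, b.e_kpa)

    def test_cord_outside_window_raises(self):
        with pytest.raises(ce.GeometryError):
            ce.build_modulus_map(ce.PhantomSpec(cord_center_mm=(10.0, 9.5)))
        with pytest.raises(ce.GeometryError):
            ce.build_modulus_map(ce.PhantomSpec(cord_center_mm=(1.0, 19.0)))


class TestSolveCompression:
    def test_homogeneous_medium_strains_uniformly(self):
        spec = ce.PhantomSpec(e_cord_kpa=25.0)   # same as background
        truth = ce.solve_compression(ce.build_modulus_map(spec))
        window = ce.build_modulus_map(spec).window_mask
        np.testing.assert_allclose(truth.strain[window], spec.applied_strain, rtol=1e-12)
        assert truth.true_strain_ratio == pytest.approx(1.0, abs=1e-12)

    def test_five_fold_contrast_gives_point_two_ratio(self):
        spec = ce.PhantomSpec(e_soft_kpa=25.0, e_cord_kpa=125.0)
        truth = ce.solve_compression(ce.build_modulus_map(spec))
        assert truth.true_strain_ratio == pytest.approx(0.2, abs=1e-6)

    def test_window_average_strain_equals_applied(self):
        spec = ce.PhantomSpec(e_cord_kpa=200.0, lesion_fraction=0.2)
        mmap = ce.build_modulus_map(spec)
        truth = ce.solve_compression(mmap)
        assert truth.strain[mmap.window_mask].mean() == pytest.approx(
            spec.applied_strain, abs=1e-9)

    def test_modulus_scale_invariance_is_bit_exact(self):
        spec = ce.PhantomSpec(e_cord_kpa=100.0)
        mmap = ce.build_modulus_map(spec)
        t1 = ce.solve_compression(mmap)
        mmap.e_kpa = mmap.e_kpa * 2.0
        t2 = ce.solve_compression(mmap)
        np.testing.assert_array_equal(t1.strain, t2.strain)
        assert t1.true_strain_ratio == t2.true_strain_ratio

    def test_displacement_fixed_at_deep_boundary_and_monotone(self):
        spec = ce.PhantomSpec(e_cord_kpa=100.0)
        truth = ce.solve_compression(ce.build_modulus_map(spec))
        dz = spec.grid_dz_mm
        # deep boundary: only the half-pixel of the deepest cell remains
        assert np.all(np.abs(truth.displacement[-1]) <= truth.strain.max() * dz)
        assert np.all(np.diff(truth.displacement, axis=0) <= 1e-15)

    def test_shift_field_is_cumulative_strain_from_surface(self):
        spec = ce.PhantomSpec(e_cord_kpa=25.0)
        truth = ce.solve_compression(ce.build_modulus_map(spec))
        shift = truth.shift_toward_transducer()
        col = int(19.0 / spec.grid_dx_mm)     # a column inside the window
        expected = spec.applied_strain * truth.z_mm   # alpha * z for uniform strain
        np.testing.assert_allclose(shift[:, col], expected, rtol=1e-9)


class TestCohort:
    def test_degenerate_sd_pins_every_animal_to_the_mean(self):
        cfg = ce.CohortConfig(label="g", n_animals=4, sr_mean=0.25, sr_sd=0.0)
        animals = ce.sample_cohort(cfg)
        for ph in animals:
            assert ph.truth.true_strain_ratio == pytest.approx(0.25, rel=0.01)

    def test_sample_mean_converges_to_distribution_mean(self):
        cfg = ce.CohortConfig(label="np", n_animals=10_000, sr_mean=0.16, sr_sd=0.06)
        draws = ce.draw_target_ratios(cfg, master_seed=0)
        assert draws.mean() == pytest.approx(0.16, abs=0.005)

    def test_draw_moments_match_truncated_normal(self):
        cfg = ce.CohortConfig(label="p", n_animals=10_000, sr_mean=0.34, sr_sd=0.17)
        draws = ce.draw_target_ratios(cfg, master_seed=1)
        a = (cfg.sr_truncation - 0.34) / 0.17
        dist = truncnorm(a, np.inf, loc=0.34, scale=0.17)
        assert draws.mean() == pytest.approx(dist.mean(), rel=0.02)
        assert draws.std() == pytest.approx(dist.std(), rel=0.02)

    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = ce.CohortConfig(label="g", n_animals=3, sr_mean=0.3, sr_sd=0.1, seed=5)
        a = ce.sample_cohort(cfg)
        b = ce.sample_cohort(cfg)
        for x, y in zip(a, b):
            assert x.target_sr == y.target_sr
            np.testing.assert_array_equal(x.modulus_map.e_kpa, y.modulus_map.e_kpa)

    @pytest.mark.parametrize("lesion", [0.0, 0.3, 0.6])
    def test_calibration_hits_target_ratio(self, lesion):
        ph = ce.build_calibrated_phantom(0.34, lesion_fraction=lesion, seed=9)
        assert ph.truth.true_strain_ratio == pytest.approx(0.34, rel=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ce.CohortConfig(label="g", n_animals=0, sr_mean=0.2, sr_sd=0.1)
        with pytest.raises(ValueError):
            ce.CohortConfig(label="g", n_animals=2, sr_mean=0.015, sr_sd=0.1)


class TestScatterers:
    def test_count_scales_with_density(self, small_spec):
        a = ce.generate_scatterers(small_spec, density=5.0, seed=1)
        b = ce.generate_scatterers(small_spec, density=10.0, seed=1)
        assert abs(len(b) - 2 * len(a)) <= 1

    def test_positions_confined_to_window(self, small_spec):
        f = ce.generate_scatterers(small_spec, density=8.0, seed=2)
        x_lo, x_hi = small_spec.window_x_mm
        assert f.z_mm.min() >= 0 and f.z_mm.max() <= small_spec.depth_mm
        assert f.x_mm.min() >= x_lo and f.x_mm.max() <= x_hi

    def test_fixed_seed_reproduces_field(self, small_spec):
        a = ce.generate_scatterers(small_spec, density=8.0, seed=2)
        b = ce.generate_scatterers(small_spec, density=8.0, seed=2)
        np.testing.assert_array_equal(a.z_mm, b.z_mm)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)


class TestCompressionRecord:
    def test_record_reaches_seventy_percent_strain(self):
        force, disp, area0, length0 = ce.generate_compression_record(10.0)
        assert disp.max() == pytest.approx(2.1, rel=1e-12)      # 0.70 * 3 mm
        assert (disp / length0).max() == pytest.approx(0.70, rel=1e-12)

    def test_fitted_modulus_recovers_generator_target(self):
        force, disp, area0, length0 = ce.generate_compression_record(
            12.0, n_points=1000)
        curve = ce.engineering_curve(force, disp, area0, length0)
        est = ce.fit_modulus(curve)
        assert est.e_kpa == pytest.approx(12.0, rel=0.01)
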