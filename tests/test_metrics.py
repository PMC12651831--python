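import math

import numpy as np
import pytest

from bgrt.metrics import (
    activity_concentration,
    blurred_sphere_profile,
    build_structures,
    expand_mask,
    make_shell,
    normalized_target_signal,
    screening_check,
    segment_pet_avid,
    steepest_descent_radius,
    suv_stats,
)
from bgrt.phantom import AcquisitionModel, ActivityImage, simulate_scan


def sphere_mask(shape, center, radius_mm, voxel_mm=1.0):
    idx = np.indices(shape, dtype=float)
    dist2 = sum((idx[a] * voxel_mm - center[a]) ** 2 for a in range(3))
    return dist2 <= radius_mm**2


class TestExpandMask:
    def test_margin_grows_sphere_to_analytic_volume(self):
        # 0.25 mm voxels keep discretisation within the geometric tolerance
        mask = sphere_mask((96, 96, 96), (11.875,) * 3, 5.5, 0.25)
        grown = expand_mask(mask, 5.0, 0.25)
        vol_cc = grown.sum() * 0.25**3 / 1000.0
        assert vol_cc == pytest.approx(math.pi / 6 * 2.1**3, rel=0.02)

    def test_zero_margin_is_identity(self):
        mask = sphere_mask((32, 32, 32), (15.5, 15.5, 15.5), 6.0)
        np.testing.assert_array_equal(expand_mask(mask, 0.0, 1.0), mask)

    def test_single_voxel_dilation_matches_lattice_count(self):
        # oracle: enumerate integer offsets within 3 mm of the origin
        expected = sum(
            x * x + y * y + z * z <= 9
            for x in range(-3, 4)
            for y in range(-3, 4)
            for z in range(-3, 4)
        )
        mask = np.zeros((11, 11, 11), dtype=bool)
        mask[5, 5, 5] = True
        assert expand_mask(mask, 3.0, 1.0).sum() == expected == 123

    def test_anisotropic_spacing_rejected(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[4, 4, 4] = True
        with pytest.raises(ValueError, match="anisotropic"):
            expand_mask(mask, 2.0, (1.0, 1.0, 3.0))


class TestMakeShell:
    def test_annulus_volume_and_disjointness(self):
        btz = sphere_mask((100, 100, 100), (24.75,) * 3, 15.5, 0.5)
        shell = make_shell(btz, gap_mm=3.0, thickness_mm=5.0, voxel_mm=0.5)
        assert not (shell & btz).any()
        vol_cc = shell.sum() * 0.5**3 / 1000.0
        analytic = math.pi / 6 * (4.7**3 - 3.7**3)
        assert vol_cc == pytest.approx(analytic, rel=0.03)

    def test_empty_shell_rejected_on_tiny_grid(self):
        btz = sphere_mask((12, 12, 12), (5.5, 5.5, 5.5), 5.0)
        with pytest.raises(ValueError):
            make_shell(btz, gap_mm=6.0, thickness_mm=6.0)

    def test_structure_nesting_invariants(self):
        gtv = sphere_mask((72, 72, 72), (35.5, 35.5, 35.5), 6.5)
        s = build_structures(gtv, 1.0)
        assert not (s.gtv & ~s.ptv).any()
        assert not (s.ptv & ~s.btz).any()
        assert not (s.shell & s.btz).any()


class TestSegmentation:
    def test_unblurred_sphere_recovered_by_both_methods(self, sphere_image):
        img = sphere_image(16, 10)
        for method in ("fraction_of_max", "gradient"):
            seg = segment_pet_avid(img, method=method, denoise_fwhm_mm=0.0)
            assert seg.found
            assert seg.volume_cc == pytest.approx(2.145, rel=0.05), method

    def test_constant_image_reports_no_avid_lesion(self):
        img = ActivityImage(np.full((32, 32, 32), 5.0))
        seg = segment_pet_avid(img)
        assert not seg.found
        assert seg.volume_cc == 0.0
        assert not seg.mask.any()

    def test_gradient_boundary_matches_analytic_steepest_descent(self, sphere_image):
        # oracle: steepest-descent radius of the analytic blurred-sphere profile
        img = simulate_scan(
            sphere_image(13, 10), AcquisitionModel(psf_fwhm_mm=4.5, noise_cv=0.0)
        )
        seg = segment_pet_avid(img, method="gradient", denoise_fwhm_mm=2.0)
        sigma = math.hypot(4.5, 2.0) / (2 * math.sqrt(2 * math.log(2)))
        oracle = steepest_descent_radius(6.5, sigma)
        # discrete ray sampling on the voxel grid sits within ~a third of a
        # voxel of the continuous-profile optimum
        assert seg.apparent_radius_mm == pytest.approx(oracle, abs=0.35)

    def test_gradient_edge_correction_recovers_true_volume(self, sphere_image):
        img = simulate_scan(
            sphere_image(13, 10), AcquisitionModel(psf_fwhm_mm=4.5, noise_cv=0.0)
        )
        seg = segment_pet_avid(
            img, method="gradient", denoise_fwhm_mm=2.0, psf_fwhm_mm=4.5
        )
        assert seg.volume_cc == pytest.approx(1.15, rel=0.15)

    def test_analytic_profile_limits(self):
        # far inside the sphere the profile approaches 1; far outside, 0
        assert blurred_sphere_profile(0.1, 10.0, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert blurred_sphere_profile(30.0, 10.0, 1.0) == pytest.approx(0.0, abs=1e-6)


class TestSuvStats:
    def test_uniform_sphere_suv(self, sphere_image):
        img = sphere_image(16, 5)
        mask = img.values > 5.0
        suvmax, suvmean = suv_stats(img, mask, AcquisitionModel())
        assert suvmax == suvmean == pytest.approx(5.0)

    def test_suvmax_bounds_after_blur(self, sphere_image):
        img = simulate_scan(
            sphere_image(9, 20), AcquisitionModel(psf_fwhm_mm=4.5, noise_cv=0.0)
        )
        mask = img.values > 10.0
        suvmax, suvmean = suv_stats(img, mask, AcquisitionModel())
        assert 1.0 < suvmax < 20.0
        assert suvmax >= suvmean

    def test_empty_mask_rejected(self, sphere_image):
        img = sphere_image(16, 5)
        with pytest.raises(ValueError):
            suv_stats(img, np.zeros_like(img.values, dtype=bool), AcquisitionModel())


def _naive_ac_nts(values, btz, shell, hot_fraction=0.8):
    """Exhaustive voxel-sort reimplementation of AC and NTS."""
    btz_sorted = sorted(values[btz].tolist(), reverse=True)
    peak = btz_sorted[0]
    hot = [v for v in btz_sorted if v >= hot_fraction * peak]
    shell_vals = values[shell].tolist()
    shell_mean = sum(shell_vals) / len(shell_vals)
    ac = sum(hot) / len(hot) - shell_mean
    var = sum((v - shell_mean) ** 2 for v in shell_vals) / (len(shell_vals) - 1)
    return ac, ac / math.sqrt(var)


class TestScreeningStatistics:
    def _structs(self, img, gtv_radius, center=None):
        shape = img.values.shape
        if center is None:
            center = tuple((n - 1) / 2.0 for n in shape)
        gtv = sphere_mask(shape, center, gtv_radius, img.voxel_mm)
        return build_structures(gtv, img.voxel_mm)

    def test_blur_free_ac_equals_background_times_contrast(self, sphere_image):
        img = sphere_image(16, 5)
        structs = self._structs(img, 8.0)
        assert activity_concentration(img, structs) == pytest.approx(20.0, abs=1e-12)

    def test_constant_image_has_zero_ac(self):
        img = ActivityImage(np.full((64, 64, 64), 5.0))
        structs = self._structs(img, 6.0)
        assert activity_concentration(img, structs) == 0.0

    def test_blurred_ac_below_blur_free_ac(self, sphere_image):
        img = sphere_image(16, 5)
        structs = self._structs(img, 8.0)
        blurred = simulate_scan(img, AcquisitionModel(psf_fwhm_mm=6.5, noise_cv=0.0))
        assert activity_concentration(blurred, structs) < 20.0

    def test_ac_nondecreasing_in_sphere_diameter(self, sphere_image):
        acq = AcquisitionModel(psf_fwhm_mm=6.5, noise_cv=0.0)
        acs = []
        for d in (8, 11, 16, 20):
            img = simulate_scan(sphere_image(d, 10), acq)
            acs.append(activity_concentration(img, self._structs(img, d / 2.0)))
        assert np.all(np.diff(acs) > 0)

    def test_ac_and_nts_match_full_sort_oracle(self, sphere_image):
        rng_master = np.random.SeedSequence(77)
        for i, seq in enumerate(rng_master.spawn(20)):
            rng = np.random.default_rng(seq)
            d = float(rng.choice([9, 11, 13, 16, 20]))
            tbr = float(rng.choice([5, 10, 15, 20]))
            img = simulate_scan(
                sphere_image(d, tbr, grid_n=64),
                AcquisitionModel(psf_fwhm_mm=6.5, noise_cv=0.05),
                rng,
            )
            structs = self._structs(img, d / 2.0)
            ac = activity_concentration(img, structs)
            nts = normalized_target_signal(img, structs)
            ac_ref, nts_ref = _naive_ac_nts(img.values, structs.btz, structs.shell)
            assert ac == pytest.approx(ac_ref, abs=1e-9)
            assert nts == pytest.approx(nts_ref, abs=1e-9)

    def test_nts_undefined_without_shell_noise(self, sphere_image):
        img = sphere_image(16, 5)
        structs = self._structs(img, 8.0)
        with pytest.raises(ValueError, match="variance"):
            normalized_target_signal(img, structs)

    def test_nts_scale_invariant_ac_scales_linearly(self, sphere_image):
        rng = np.random.default_rng(5)
        img = simulate_scan(
            sphere_image(16, 10), AcquisitionModel(psf_fwhm_mm=6.5, noise_cv=0.05), rng
        )
        structs = self._structs(img, 8.0)
        doubled = ActivityImage(img.values * 2.0, img.voxel_mm)
        assert normalized_target_signal(doubled, structs) == pytest.approx(
            normalized_target_signal(img, structs), rel=1e-12
        )
        assert activity_concentration(doubled, structs) == pytest.approx(
            2.0 * activity_concentration(img, structs), rel=1e-12
        )


class TestScreeningCheck:
    def test_measured_planning_pass(self):
        # strongest 16 mm low-contrast planning measurement: AC 7.6, NTS 8.6
        assert screening_check(7.6, 8.6, "planning")

    def test_ac_floor_is_strict(self):
        assert not screening_check(5.0, 99.0, "planning")
        assert not screening_check(5.0, 99.0, "pretreatment")

    def test_stage_dependent_nts_floor(self):
        assert not screening_check(6.0, 2.5, "planning")
        assert screening_check(6.0, 2.5, "pretreatment")

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            screening_check(6.0, 3.0, "delivery")
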