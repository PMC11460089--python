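import dataclasses

import numpy as np
import pytest

from dlifkit.imaging_core import DynamicImage, TimeActivityCurve, build_frame_schedule
from dlifkit.kinetics import feng_aif, frame_average, patlak_fit
from dlifkit.phantom import default_aif
from dlifkit.voi_idif import (
    EmptyMaskError,
    FitError,
    IdifConfig,
    extract_idif,
    extract_tac,
    fit_idif,
    heart_search_box,
    lv_region,
    peak_voxel,
    sphere_voi,
    static_image,
    threshold_voi,
    VOIMask,
)
from conftest import organ_label, organ_mask


def _toy_image(values_per_frame, durations, shape=(4, 4, 4)):
    sched = build_frame_schedule([(1, d) for d in durations])
    vox = np.stack([np.full(shape, v, dtype=np.float32) for v in values_per_frame])
    return DynamicImage(vox, (0.5, 0.5, 0.5), sched)


class TestStaticImage:
    def test_constant_image(self):
        img = _toy_image([3.0, 3.0], [10, 10])
        np.testing.assert_allclose(static_image(img, (0.0, 1.0)), 3.0)

    def test_duration_weighted_mean(self):
        img = _toy_image([1.0, 3.0], [10, 30])
        np.testing.assert_allclose(static_image(img, (0.0, 1.0)), 2.5)

    def test_last_20_min_selects_late_300s_frames(self, schedule41, blurred_scan):
        mid = schedule41.midpoint_min
        sel = (mid >= 25.0) & (mid <= 45.0)
        assert sel.sum() == 4  # 300-s frames with midpoint >= 25 min
        assert np.all(schedule41.duration_s[sel] == 300)

    def test_empty_window_rejected(self):
        img = _toy_image([1.0, 2.0], [10, 10])
        with pytest.raises(Exception):
            static_image(img, (5.0, 6.0))


class TestSphereVoi:
    def test_tiny_radius_is_center_voxel(self):
        m = sphere_voi((2, 2, 2), 0.2, (0.5, 0.5, 0.5), (5, 5, 5))
        assert m.n_voxels == 1
        assert m.mask[2, 2, 2]

    def test_count_matches_enumeration(self):
        m = sphere_voi((8, 8, 8), 2.0, (0.5, 0.5, 0.5), (17, 17, 17))
        count = sum(
            (0.5 * (i - 8)) ** 2 + (0.5 * (j - 8)) ** 2 + (0.5 * (k - 8)) ** 2 <= 4.0
            for i in range(17)
            for j in range(17)
            for k in range(17)
        )
        assert m.n_voxels == count

    def test_reflection_symmetry(self):
        m = sphere_voi((8, 8, 8), 2.0, (0.5, 0.5, 0.5), (17, 17, 17)).mask
        np.testing.assert_array_equal(m, m[::-1, :, :])
        np.testing.assert_array_equal(m, m[:, ::-1, :])
        np.testing.assert_array_equal(m, m[:, :, ::-1])


class TestPeakVoxel:
    def test_single_hot_voxel(self):
        img = _toy_image([0.0, 0.0], [30, 30])
        vox = img.voxels.copy()
        vox[:, 1, 2, 3] = 5.0
        img = DynamicImage(vox, img.spacing_mm, img.schedule)
        assert peak_voxel(img, (0.0, 1.0)) == (1, 2, 3)

    def test_tie_breaks_to_lowest_flat_index(self):
        img = _toy_image([0.0], [30])
        vox = img.voxels.copy()
        vox[:, 0, 0, 1] = 5.0
        vox[:, 3, 3, 3] = 5.0
        img = DynamicImage(vox, img.spacing_mm, img.schedule)
        assert peak_voxel(img, (0.0, 1.0)) == (0, 0, 1)

    def test_phantom_peak_lies_in_blood(self, blurred_scan):
        idx = peak_voxel(blurred_scan.image, (20 / 60, 1.0))
        labels = {
            organ_label(blurred_scan, "blood_pool"),
            organ_label(blurred_scan, "vena_cava"),
            organ_label(blurred_scan, "myocardium"),  # wall adjacency after blur
        }
        assert blurred_scan.labels[idx] in labels

    def test_zero_window_rejected(self):
        img = _toy_image([0.0], [30])
        with pytest.raises(Exception):
            peak_voxel(img, (0.0, 1.0))


class TestThresholdVoi:
    def test_direct_rule(self):
        static = np.zeros((3, 3, 3))
        static[0, 0, 0] = 0.0
        static[1, 1, 1] = 5.0
        static[2, 2, 2] = 10.0
        box = (slice(0, 3),) * 3
        m = threshold_voi(static, box, 0.5, background=0.0)
        assert m.n_voxels == 2
        assert m.mask[1, 1, 1] and m.mask[2, 2, 2]

    def test_high_fraction_keeps_only_max(self):
        static = np.zeros((3, 3, 3))
        static[1, 1, 1] = 5.0
        static[2, 2, 2] = 10.0
        m = threshold_voi(static, (slice(0, 3),) * 3, 0.99)
        assert m.n_voxels == 1
        assert m.mask[2, 2, 2]

    def test_flat_box_rejected(self):
        static = np.zeros((3, 3, 3))
        with pytest.raises(EmptyMaskError):
            threshold_voi(static, (slice(0, 3),) * 3, 0.5)

    def test_phantom_myocardium_dice(self, blurred_scan):
        static = static_image(blurred_scan.image, (25.0, 45.0))
        box = heart_search_box(static)
        m = threshold_voi(static, box, 0.5)
        truth = organ_mask(blurred_scan, "myocardium")
        inter = (m.mask & truth).sum()
        dice = 2 * inter / (m.mask.sum() + truth.sum())
        assert dice >= 0.6


class TestLvRegion:
    def _shell(self):
        mask = np.zeros((13, 13, 13), dtype=bool)
        g = np.indices(mask.shape)
        d2 = ((g - 6) ** 2).sum(axis=0)
        return VOIMask("myocardium", (d2 <= 25) & (d2 > 9))

    def test_hollow_shell_interior(self):
        shell = self._shell()
        lv = lv_region(shell)
        g = np.indices(shell.mask.shape)
        d2 = ((g - 6) ** 2).sum(axis=0)
        np.testing.assert_array_equal(lv.mask, d2 <= 9)

    def test_solid_sphere_has_no_cavity(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        g = np.indices(mask.shape)
        mask[((g - 4) ** 2).sum(axis=0) <= 9] = True
        with pytest.raises(EmptyMaskError):
            lv_region(VOIMask("myocardium", mask))

    def test_margin_keeps_cavity_core(self):
        shell = self._shell()
        lv = lv_region(shell, margin_mm=1.0, spacing_mm=(0.5, 0.5, 0.5))
        full = lv_region(shell)
        assert lv.n_voxels < full.n_voxels
        assert np.all(full.mask[lv.mask])

    def test_phantom_cavity_contained_in_heart(self, blurred_scan):
        static = static_image(blurred_scan.image, (25.0, 45.0))
        box = heart_search_box(static)
        myo = threshold_voi(static, box, 0.5)
        lv = lv_region(myo, margin_mm=1.5, spacing_mm=blurred_scan.image.spacing_mm)
        allowed = organ_mask(blurred_scan, "blood_pool") | organ_mask(
            blurred_scan, "myocardium"
        )
        assert np.all(allowed[lv.mask])


class TestExtractTac:
    def test_uniform_image(self):
        img = _toy_image([2.0, 4.0], [10, 10])
        mask = VOIMask("m", np.ones((4, 4, 4), dtype=bool))
        np.testing.assert_allclose(extract_tac(img, mask).value_suv, [2.0, 4.0])

    def test_single_voxel_mask(self, coarse_scan):
        m = np.zeros(coarse_scan.image.spatial_shape, dtype=bool)
        m[8, 8, 8] = True
        tac = extract_tac(coarse_scan.image, VOIMask("v", m))
        np.testing.assert_allclose(tac.value_suv, coarse_scan.image.voxels[:, 8, 8, 8])

    def test_true_label_mask_recovers_forward_tac(self, clean_scan):
        bp = VOIMask("blood", organ_mask(clean_scan, "blood_pool"))
        tac = extract_tac(clean_scan.image, bp)
        np.testing.assert_allclose(
            tac.value_suv, clean_scan.organ_tacs["blood_pool"].value_suv, atol=2e-3
        )

    def test_commutes_with_global_scaling(self, coarse_scan):
        img = coarse_scan.image
        scaled = DynamicImage(img.voxels * 2.0, img.spacing_mm, img.schedule)
        m = VOIMask("body", organ_mask(coarse_scan, "body"))
        np.testing.assert_allclose(
            extract_tac(scaled, m).value_suv,
            2.0 * extract_tac(img, m).value_suv,
            rtol=1e-6,
        )


class TestFitIdif:
    def test_noiseless_parameter_recovery(self, schedule41):
        truth = default_aif()
        cp = frame_average(lambda t: feng_aif(truth, t), schedule41, kind="blood")
        fit = fit_idif(cp, cp, schedule41)
        p = fit.params
        assert p.A1 == pytest.approx(truth.A1, rel=0.02)
        assert p.A2 == pytest.approx(truth.A2, rel=0.02)
        assert p.A3 == pytest.approx(truth.A3, rel=0.02)
        assert p.lam1 == pytest.approx(truth.lam1, rel=0.05)
        assert p.lam2 == pytest.approx(truth.lam2, rel=0.05)
        assert p.lam3 == pytest.approx(truth.lam3, rel=0.05)

    def test_all_zero_tacs_raise(self, schedule41):
        zero = TimeActivityCurve(
            schedule41.midpoint_s, np.zeros(len(schedule41)), "blood"
        )
        with pytest.raises(FitError):
            fit_idif(zero, zero, schedule41)

    def test_fitted_peak_survives_psf(self, blurred_scan):
        fit = extract_idif(blurred_scan.image)
        true_peak = blurred_scan.cp.value_suv.max()
        assert fit.curve.value_suv.max() >= 0.9 * true_peak
        # and the fit never undershoots what the blurred VOI data show
        vc = sphere_voi(
            peak_voxel(blurred_scan.image, (20 / 60, 1.0)),
            0.6,
            blurred_scan.image.spacing_mm,
            blurred_scan.image.spatial_shape,
        )
        observed_peak = extract_tac(blurred_scan.image, vc).value_suv.max()
        assert fit.curve.value_suv.max() >= 0.95 * observed_peak


class TestFullChain:
    def test_idif_patlak_ki_close_to_truth(self, blurred_scan):
        fit = extract_idif(blurred_scan.image)
        brain = organ_mask(blurred_scan, "brain")
        tac = TimeActivityCurve(
            blurred_scan.image.schedule.midpoint_s,
            blurred_scan.image.voxels[:, brain].mean(axis=1),
        )
        ki_idif = patlak_fit(tac, fit.curve).Ki
        truth = blurred_scan.truth_ki.set_index("organ").Ki["brain"]
        assert ki_idif == pytest.approx(truth, rel=0.10)

    def test_chain_deterministic(self, blurred_scan):
        a = extract_idif(blurred_scan.image)
        b = extract_idif(blurred_scan.image)
        np.testing.assert_array_equal(a.curve.value_suv, b.curve.value_suv)
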