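import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from dlifkit.imaging_core import TimeActivityCurve, ValidationError, build_frame_schedule
from dlifkit.kinetics import (
    FengAifParams,
    KineticParams,
    feng_aif,
    frame_average,
    patlak_fit,
    patlak_voxelwise,
    tissue_2tc_irreversible,
)
from dlifkit.phantom import default_aif, default_schedule


class TestFengAif:
    def test_zero_at_onset(self):
        p = FengAifParams(100.0, 5.0, 2.0, -4.0, -0.2, -0.01, delay_min=0.5)
        assert feng_aif(p, np.array([0.5]))[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(feng_aif(p, np.array([0.0, 0.2, 0.4])) == 0.0)

    def test_reduced_forms(self):
        t = np.linspace(0, 10, 101)
        # A1=A2=A3 -> only first two terms; pure linear-times-exponential
        p = FengAifParams(1.0, 0.0, 0.0, -0.5, -0.3, -0.1)
        np.testing.assert_allclose(feng_aif(p, t), t * np.exp(-0.5 * t), atol=1e-12)

    def test_peak_matches_dense_grid_argmax(self):
        p = FengAifParams(851.1, 21.9, 20.8, -4.13, -0.12, -0.01)
        grid = np.linspace(0, 3, 300001)
        cp = feng_aif(p, grid)
        t_peak_oracle = grid[np.argmax(cp)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: -feng_aif(p, np.array([t]))[0], bounds=(0.0, 3.0), method="bounded"
        )
        assert res.x == pytest.approx(t_peak_oracle, abs=1e-3)

    def test_eigenvalue_ordering_enforced(self):
        with pytest.raises(ValidationError):
            FengAifParams(1.0, 1.0, 1.0, -0.1, -0.5, -0.01)

    def test_negative_curve_rejected(self):
        # large negative A2 pulls Cp below zero after the bolus
        p = FengAifParams(1.0, -50.0, 0.0, -4.0, -0.2, -0.01)
        with pytest.raises(ValidationError):
            feng_aif(p, np.linspace(0, 10, 100))


class TestTissueModel:
    def test_no_uptake_gives_pure_blood(self):
        p = default_aif()
        t = np.linspace(0, 45, 50)
        kp = KineticParams(K1=0.0, k2=0.3, k3=0.05, vB=0.25)
        np.testing.assert_allclose(
            tissue_2tc_irreversible(kp, lambda x: feng_aif(p, x), t),
            0.25 * feng_aif(p, t),
            rtol=1e-9,
            atol=1e-12,
        )

    def test_pure_accumulation_closed_form(self):
        # constant input, no efflux: Ct = K1 * c * t exactly
        kp = KineticParams(K1=0.12, k2=0.0, k3=0.0, vB=0.0)
        t = np.linspace(0, 30, 31)
        ct = tissue_2tc_irreversible(kp, lambda x: np.full_like(x, 2.0), t)
        np.testing.assert_allclose(ct, 0.12 * 2.0 * t, rtol=2e-3, atol=1e-3)

    def test_matches_stiff_ode_oracle(self):
        p = default_aif()
        kp = KineticParams(K1=0.1, k2=0.3, k3=0.05, vB=0.0)

        def rhs(t, y):
            cpv = feng_aif(p, np.array([t]))[0]
            return [kp.K1 * cpv - (kp.k2 + kp.k3) * y[0], kp.k3 * y[0]]

        t = np.linspace(1.0, 45, 89)
        sol = solve_ivp(rhs, [0, 45], [0, 0], t_eval=t, rtol=1e-8, atol=1e-10)
        ct_ode = sol.y.sum(axis=0)
        ct_conv = tissue_2tc_irreversible(kp, lambda x: feng_aif(p, x), t)
        assert np.max(np.abs(ct_conv - ct_ode) / np.abs(ct_ode)) < 5e-3

    def test_macro_parameter(self):
        assert KineticParams(0.1, 0.3, 0.05).Ki == pytest.approx(0.0142857, rel=1e-5)
        assert KineticParams(0.1, 0.0, 0.0).Ki == 0.1  # k2=0 limit


class TestFrameAverage:
    def test_constant_curve(self, schedule41):
        tac = frame_average(lambda t: np.full_like(t, 2.0), schedule41)
        np.testing.assert_allclose(tac.value_suv, 2.0)

    def test_linear_curve_mean(self):
        s = build_frame_schedule([(1, 10)])
        tac = frame_average(lambda t: t * 60.0, s)  # value = t in seconds
        assert tac.value_suv[0] == pytest.approx(5.0)

    def test_matches_dense_quadrature_oracle(self, schedule41):
        p = default_aif()
        tac = frame_average(lambda t: feng_aif(p, t), schedule41)
        oracle = np.empty(len(schedule41))
        for i, (t0, d) in enumerate(
            zip(schedule41.start_s, schedule41.duration_s)
        ):
            ts = np.linspace(t0, t0 + d, 1001) / 60.0
            oracle[i] = np.trapezoid(feng_aif(p, ts), ts) / (d / 60.0)
        np.testing.assert_allclose(tac.value_suv, oracle, rtol=1e-4, atol=1e-6)


class TestPatlakFit:
    def test_constant_input_closed_form(self, schedule41):
        t_min = schedule41.midpoint_min
        cp = TimeActivityCurve(schedule41.midpoint_s, np.ones(len(schedule41)), "blood")
        ct = TimeActivityCurve(schedule41.midpoint_s, 0.05 * t_min + 0.3)
        res = patlak_fit(ct, cp, t_star_min=10)
        # slope is exact; the initial-triangle integral offsets the
        # intercept by slope * t1/2 (~2 ms worth of integral)
        assert res.Ki == pytest.approx(0.05, rel=1e-12)
        assert res.intercept_V == pytest.approx(0.3, abs=5e-3)

    def test_pure_blood_signal(self, schedule41):
        p = default_aif()
        cp = frame_average(lambda t: feng_aif(p, t), schedule41, kind="blood")
        ct = TimeActivityCurve(cp.t_s, 0.37 * cp.value_suv)
        res = patlak_fit(ct, cp, t_star_min=10)
        assert res.Ki == pytest.approx(0.0, abs=1e-12)
        assert res.intercept_V == pytest.approx(0.37, rel=1e-9)

    def test_recovers_2tc_macro_parameter(self, schedule41):
        p = default_aif()
        kp = KineticParams(K1=0.1, k2=0.3, k3=0.05)
        grid = np.arange(0, 45.02, 0.01)
        ct_grid = tissue_2tc_irreversible(kp, lambda t: feng_aif(p, t), grid)
        ct = frame_average(lambda t: np.interp(t, grid, ct_grid), schedule41)
        cp = frame_average(lambda t: feng_aif(p, t), schedule41, kind="blood")
        res = patlak_fit(ct, cp, t_star_min=15)
        assert res.Ki == pytest.approx(kp.Ki, rel=0.05)

    def test_k2_zero_slope_approaches_k1(self, schedule41):
        p = default_aif()
        kp = KineticParams(K1=0.08, k2=0.0, k3=0.1)
        grid = np.arange(0, 45.02, 0.01)
        ct_grid = tissue_2tc_irreversible(kp, lambda t: feng_aif(p, t), grid)
        ct = frame_average(lambda t: np.interp(t, grid, ct_grid), schedule41)
        cp = frame_average(lambda t: feng_aif(p, t), schedule41, kind="blood")
        res = patlak_fit(ct, cp, t_star_min=15)
        assert res.Ki == pytest.approx(0.08, rel=0.02)

    def test_too_few_points_raises(self, schedule41):
        from dlifkit.kinetics import FitError

        cp = TimeActivityCurve(schedule41.midpoint_s, np.ones(len(schedule41)), "blood")
        ct = TimeActivityCurve(schedule41.midpoint_s, np.ones(len(schedule41)))
        with pytest.raises(FitError):
            patlak_fit(ct, cp, t_star_min=44.9)

    @given(c=st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        schedule41 = default_schedule()
        p = default_aif()
        cp_v = frame_average(lambda t: feng_aif(p, t), schedule41).value_suv
        ct_v = 0.5 * cp_v + 0.01 * schedule41.midpoint_min * cp_v
        t_s = schedule41.midpoint_s
        base = patlak_fit(
            TimeActivityCurve(t_s, ct_v), TimeActivityCurve(t_s, cp_v, "blood")
        )
        both = patlak_fit(
            TimeActivityCurve(t_s, c * ct_v),
            TimeActivityCurve(t_s, c * cp_v, "blood"),
        )
        only_cp = patlak_fit(
            TimeActivityCurve(t_s, ct_v), TimeActivityCurve(t_s, c * cp_v, "blood")
        )
        assert both.Ki == pytest.approx(base.Ki, rel=1e-9)
        assert both.intercept_V == pytest.approx(base.intercept_V, rel=1e-9)
        assert only_cp.Ki == pytest.approx(base.Ki / c, rel=1e-9)


class TestPatlakVoxelwise:
    def test_uniform_image_matches_regional_fit(self, schedule41):
        p = default_aif()
        cp = frame_average(lambda t: feng_aif(p, t), schedule41, kind="blood")
        kp = KineticParams(K1=0.1, k2=0.3, k3=0.05)
        grid = np.arange(0, 45.02, 0.01)
        ct_grid = tissue_2tc_irreversible(kp, lambda t: feng_aif(p, t), grid)
        ct = frame_average(lambda t: np.interp(t, grid, ct_grid), schedule41)
        from dlifkit.imaging_core import DynamicImage

        vox = np.tile(ct.value_suv[:, None, None, None], (1, 3, 3, 3))
        img = DynamicImage(vox, (0.5,) * 3, schedule41)
        ki_map, v_map = patlak_voxelwise(img, cp, t_star_min=10)
        regional = patlak_fit(ct, cp, t_star_min=10)
        np.testing.assert_allclose(ki_map, regional.Ki, rtol=1e-5)
        np.testing.assert_allclose(v_map, regional.intercept_V, rtol=1e-5)

    def test_all_zero_voxel_is_nan(self, schedule41):
        p = default_aif()
        cp = frame_average(lambda t: feng_aif(p, t), schedule41, kind="blood")
        from dlifkit.imaging_core import DynamicImage

        vox = np.zeros((len(schedule41), 2, 2, 2), dtype=np.float32)
        vox[:, 0, 0, 0] = cp.value_suv
        img = DynamicImage(vox, (0.5,) * 3, schedule41)
        ki_map, _ = patlak_voxelwise(img, cp)
        assert np.isfinite(ki_map[0, 0, 0])
        assert np.isnan(ki_map[1, 1, 1])

    def test_empty_mask_rejected(self, schedule41):
        p = default_aif()
        cp = frame_average(lambda t: feng_aif(p, t), schedule41, kind="blood")
        from dlifkit.imaging_core import DynamicImage

        img = DynamicImage(
            np.ones((len(schedule41), 2, 2, 2), dtype=np.float32), (0.5,) * 3, schedule41
        )
        with pytest.raises(ValidationError):
            patlak_voxelwise(img, cp, mask=np.zeros((2, 2, 2), dtype=bool))
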