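"""Dipole kernel, TKD and TV inversion, L-curve, unit scaling."""

import numpy as np
import pytest
from scipy import fft as spfft
from scipy import ndimage

import qsmkit as qk
from qsmkit.inversion import _lcurve_corner
from qsmkit.phantom import Primitive, build_chi_volume


@pytest.fixture(scope="module")
def kernel32(meta32):
    return qk.dipole_kernel((32, 32, 32), meta32.voxel_size,
                            meta32.b0_direction)


@pytest.fixture(scope="module")
def sphere_field32(meta32):
    """Noiseless field of a chi = 0.1 ppm sphere, radius 6 mm, at 32^3."""
    spec = qk.PhantomSpec(
        grid_shape=(32, 32, 32),
        brain_region=Primitive("sphere", (0, 0, 0), (12.0,)),
        primitives=[Primitive("sphere", (0, 0, 0), (6.0,), chi_ppm=0.1)])
    chi, _ = build_chi_volume(spec)
    return chi, qk.forward_field(chi, meta32)


class TestDipoleKernel:
    def test_k_parallel_to_b0(self, kernel32):
        # k along B0: D = 1/3 - 1 = -2/3
        assert kernel32.values[0, 0, 1] == pytest.approx(-2.0 / 3.0)
        assert kernel32.values.min() == pytest.approx(-2.0 / 3.0)

    def test_k_perpendicular_to_b0(self, kernel32):
        assert kernel32.values[1, 0, 0] == pytest.approx(1.0 / 3.0)
        assert kernel32.values[0, 1, 0] == pytest.approx(1.0 / 3.0)
        assert kernel32.values.max() == pytest.approx(1.0 / 3.0)

    def test_magic_angle_zero_crossing(self):
        # D vanishes where cos^2(theta) = 1/3, i.e. theta = acos(sqrt(1/3))
        theta = np.arccos(np.sqrt(1.0 / 3.0))
        assert np.degrees(theta) == pytest.approx(54.7356, abs=1e-3)
        b0 = (0.0, 0.0, 1.0)
        k = np.array([np.sin(theta), 0.0, np.cos(theta)])
        D = 1.0 / 3.0 - (k @ b0) ** 2 / (k @ k)
        assert abs(D) < 1e-9

    def test_symmetry_under_k_negation(self, kernel32):
        D = kernel32.values
        Dneg = D.copy()
        for a in range(3):
            Dneg = np.roll(np.flip(Dneg, axis=a), 1, axis=a)
        assert np.allclose(D, Dneg, atol=1e-12)

    @pytest.mark.parametrize("b0,k_par,k_perp", [
        ((1, 0, 0), (1, 0, 0), (0, 0, 1)),
        ((0, 1, 0), (0, 1, 0), (1, 0, 0)),
        ((0.6, 0.0, 0.8), (3, 0, 4), (4, 0, -3)),
    ])
    def test_magic_cone_follows_b0_direction(self, b0, k_par, k_perp):
        # rotating the main-field axis rotates the extremes of D with it
        D = qk.dipole_kernel((16, 16, 16), (1, 1, 1), b0).values
        assert D[k_par] == pytest.approx(-2.0 / 3.0)
        assert D[k_perp] == pytest.approx(1.0 / 3.0)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            qk.dipole_kernel((8, 8, 8), (1, 1, 1), (0, 0, 0))


class TestScaleToPpm:
    def test_zero_maps_to_zero(self):
        assert qk.scale_to_ppm(0.0, 3.0, 5e-3) == 0.0

    def test_printed_formula_value(self):
        # 1 rad at 3 T over 5 ms -> 0.2492 ppm
        assert qk.scale_to_ppm(1.0, 3.0, 5e-3) == pytest.approx(0.2492,
                                                                abs=5e-5)

    def test_linearity(self):
        assert qk.scale_to_ppm(2.0, 3.0, 5e-3) == pytest.approx(
            2 * qk.scale_to_ppm(1.0, 3.0, 5e-3))

    @pytest.mark.parametrize("b0,dte", [(0.0, 5e-3), (-1.0, 5e-3),
                                        (3.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, b0, dte):
        with pytest.raises(ValueError):
            qk.scale_to_ppm(1.0, b0, dte)


class TestTkdInvert:
    def test_zero_field_gives_zero_chi(self, kernel32, meta32):
        out = qk.tkd_invert(np.zeros((32, 32, 32)), kernel32, meta32)
        assert not out.chi.any()

    def test_point_source_recovered(self, kernel32, meta32):
        chi = np.zeros((32, 32, 32))
        chi[16, 16, 16] = 1.0
        field = qk.forward_field(chi, meta32)
        rec = qk.tkd_invert(field, kernel32, meta32)
        peak = np.unravel_index(np.argmax(np.abs(rec.chi)), rec.chi.shape)
        assert peak == (16, 16, 16)
        assert rec.chi[peak] == pytest.approx(1.0, rel=0.25)

    def test_higher_threshold_smooths(self, kernel32, meta32):
        rng = np.random.default_rng(0)
        chi = np.zeros((32, 32, 32))
        chi[16, 16, 16] = 1.0
        field = qk.forward_field(chi, meta32) + \
            0.01 * rng.normal(size=(32, 32, 32))
        tv_low = qk.total_variation(
            qk.tkd_invert(field, kernel32, meta32, threshold=0.2).chi)
        tv_high = qk.total_variation(
            qk.tkd_invert(field, kernel32, meta32, threshold=0.65).chi)
        assert tv_high < tv_low

    def test_threshold_range_enforced(self, kernel32, meta32):
        with pytest.raises(ValueError, match="2/3"):
            qk.tkd_invert(np.zeros((32, 32, 32)), kernel32, meta32,
                          threshold=0.7)


class TestTvInvert:
    def test_zero_field_gives_zero_chi(self, kernel32, meta32):
        out = qk.tv_invert(np.zeros((32, 32, 32)), kernel32, meta32)
        assert np.allclose(out.chi, 0.0, atol=1e-12)

    def test_noiseless_sphere_mean_recovered(self, sphere_field32, kernel32,
                                             meta32):
        chi_true, field = sphere_field32
        rec = qk.tv_invert(field, kernel32, meta32)
        inner = ndimage.binary_erosion(chi_true > 0.05, iterations=1)
        assert rec.chi[inner].mean() == pytest.approx(0.1, rel=0.10)

    def test_tv_monotone_in_lambda(self, sphere_field32, kernel32, meta32):
        _, field = sphere_field32
        noisy = field + 0.05 * np.random.default_rng(1).normal(
            size=field.shape)
        tv1 = qk.total_variation(
            qk.tv_invert(noisy, kernel32, meta32, lambda_reg=0.0005).chi)
        tv2 = qk.total_variation(
            qk.tv_invert(noisy, kernel32, meta32, lambda_reg=0.001).chi)
        assert tv2 <= tv1 * (1 + 1e-6)

    def test_data_term_beats_tkd(self, sphere_field32, kernel32, meta32):
        # TV solves the stated fidelity problem: its weighted residual on
        # noiseless data cannot exceed the TKD baseline's
        _, field = sphere_field32
        tv = qk.tv_invert(field, kernel32, meta32)
        tkd = qk.tkd_invert(field, kernel32, meta32)
        f_ppm = qk.hz_to_ppm(field, meta32.field_strength)

        def resid(c):
            return np.linalg.norm(
                f_ppm - spfft.ifftn(kernel32.values * spfft.fftn(c)).real)

        assert resid(tv.chi) <= resid(tkd.chi)

    def test_deterministic(self, sphere_field32, kernel32, meta32):
        _, field = sphere_field32
        a = qk.tv_invert(field, kernel32, meta32)
        b = qk.tv_invert(field, kernel32, meta32)
        assert np.array_equal(a.chi, b.chi)

    def test_oblique_b0_round_trip(self, meta32):
        # simulating and inverting with the same tilted axis recovers the
        # sphere; inverting with the wrong axis-aligned kernel does not
        b = np.array([0.3, 0.1, 0.94])
        b /= np.linalg.norm(b)
        meta_t = qk.default_meta(grid_shape=(32, 32, 32),
                                 b0_direction=tuple(b))
        spec = qk.PhantomSpec(
            grid_shape=(32, 32, 32),
            brain_region=Primitive("sphere", (0, 0, 0), (12.0,)),
            primitives=[Primitive("sphere", (0, 0, 0), (6.0,),
                                  chi_ppm=0.1)])
        chi_true, _ = build_chi_volume(spec)
        field = qk.forward_field(chi_true, meta_t)
        k_ok = qk.dipole_kernel((32, 32, 32), meta_t.voxel_size, tuple(b))
        k_bad = qk.dipole_kernel((32, 32, 32), meta_t.voxel_size, (0, 0, 1))
        rec_ok = qk.tv_invert(field, k_ok, meta_t)
        rec_bad = qk.tv_invert(field, k_bad, meta_t)
        demeaned = chi_true - chi_true.mean()
        rms_ok = np.sqrt(np.mean((rec_ok.chi - demeaned) ** 2))
        rms_bad = np.sqrt(np.mean((rec_bad.chi - demeaned) ** 2))
        assert rms_ok < 0.5 * rms_bad

    def test_nonpositive_lambda_rejected(self, kernel32, meta32):
        with pytest.raises(ValueError, match="lambda"):
            qk.tv_invert(np.zeros((32, 32, 32)), kernel32, meta32,
                         lambda_reg=0.0)


class TestLcurve:
    def test_synthetic_corner_found(self):
        # analytic L with an exact corner at the third of five points
        lams = [1e-4, 3e-4, 1e-3, 3e-3, 1e-2]
        resid = [1.0, 1.001, 1.002, 10.0, 100.0]
        regn = [100.0, 10.0, 1.002, 1.001, 1.0]
        sel, curv = _lcurve_corner(resid, regn, lams)
        assert sel == 1e-3
        assert np.isnan(curv[0]) and np.isnan(curv[-1])

    def test_three_point_grid_returns_middle_with_warning(self):
        with pytest.warns(UserWarning, match="interior"):
            sel, _ = _lcurve_corner([1.0, 2.0, 4.0], [4.0, 2.0, 1.0],
                                    [1e-4, 1e-3, 1e-2])
        assert sel == 1e-3

    def test_phantom_sweep_near_rmse_optimum(self, sphere_field32, meta32,
                                             kernel32):
        # the L-curve corner must land within one grid step of the
        # ground-truth-RMSE-optimal lambda
        chi_true, field = sphere_field32
        noisy = field + 0.2 * np.random.default_rng(2).normal(
            size=field.shape)
        grid = list(np.geomspace(1e-5, 1e-2, 7))
        sel, table = qk.lcurve_select(noisy, kernel32, meta32,
                                      lambda_grid=grid, max_iter=50)
        demeaned = chi_true - chi_true.mean()
        rmses = []
        for lam in grid:
            rec = qk.tv_invert(noisy, kernel32, meta32, lambda_reg=lam,
                               max_iter=50)
            rmses.append(np.sqrt(np.mean((rec.chi - demeaned) ** 2)))
        i_opt = int(np.argmin(rmses))
        i_sel = grid.index(sel)
        assert abs(i_sel - i_opt) <= 1

    def test_short_grid_rejected(self, kernel32, meta32):
        with pytest.raises(ValueError, match=">=3"):
            qk.lcurve_select(np.zeros((32, 32, 32)), kernel32, meta32,
                             lambda_grid=[1e-3, 1e-2])
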