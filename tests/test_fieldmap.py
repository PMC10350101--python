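"""Multi-echo field fitting, exact spatial unwrapping, echo combination."""

import numpy as np
import pytest

import qsmkit as qk


def _synthetic_dataset(f_hz, phi0=0.0, shape=(6, 6, 6), te=None, mag=1.0):
    """Noiseless dataset with spatially uniform field and offset."""
    meta = qk.default_meta(grid_shape=shape) if te is None else \
        qk.AcquisitionMeta(field_strength=3.0, te_list=te, tr=0.05,
                           flip_angle=15, voxel_size=(1, 1, 1))
    te_arr = np.asarray(meta.te_list)
    phases = np.stack([
        qk.wrap_phase(np.full(shape, 2 * np.pi * f_hz * t + phi0))
        for t in te_arr])
    mags = np.full((len(te_arr),) + shape, mag)
    return qk.MultiEchoDataset(magnitude=mags, phase=phases, meta=meta)


class TestFitComplexMultiecho:
    def test_noiseless_field_and_offset_recovery(self, noiseless32, meta32):
        _, data, truth = noiseless32
        fit = qk.fit_complex_multiecho(data)
        bm = truth.brain_mask
        unaliased = bm & (np.abs(truth.total_field) <
                          0.5 / meta32.delta_te - 1.0)
        assert np.abs(fit.field - truth.total_field)[unaliased].max() < 1e-6
        assert np.abs(qk.wrap_phase(fit.phi0 - truth.phi0))[unaliased].max() \
            < 1e-6

    def test_all_zero_phase_gives_zero_field_and_offset(self):
        data = _synthetic_dataset(0.0)
        fit = qk.fit_complex_multiecho(data)
        assert np.allclose(fit.field, 0.0, atol=1e-12)
        assert np.allclose(fit.phi0, 0.0, atol=1e-12)

    def test_temporal_aliasing_at_inverse_echo_spacing(self):
        # f = 1/dTE is indistinguishable from 0 Hz on a uniform echo train
        meta = qk.default_meta(grid_shape=(4, 4, 4))
        f_alias = 1.0 / meta.delta_te
        data = _synthetic_dataset(f_alias, shape=(4, 4, 4))
        fit = qk.fit_complex_multiecho(data)
        assert np.allclose(fit.field, 0.0, atol=1e-6)

    def test_fewer_than_three_echoes_rejected(self):
        data = _synthetic_dataset(5.0, te=(5e-3, 11e-3))
        with pytest.raises(ValueError, match="weighted"):
            qk.fit_complex_multiecho(data)

    def test_zero_magnitude_voxel_flagged_unreliable(self, noiseless32):
        _, data, _ = noiseless32
        mags = data.magnitude.copy()
        mags[:, 2, 3, 4] = 0.0
        data2 = qk.MultiEchoDataset(magnitude=mags, phase=data.phase,
                                    meta=data.meta)
        fit = qk.fit_complex_multiecho(data2)
        assert fit.quality[2, 3, 4] == 0.0
        assert fit.field[2, 3, 4] == 0.0
        assert np.all(fit.quality >= 0) and np.all(fit.quality <= 1)
        assert np.all(fit.noise >= 0)


class TestUnwrapSpatial:
    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 8), 0.7)
        mask = np.ones(vol.shape, dtype=bool)
        out = qk.unwrap_spatial(vol, np.ones_like(vol), mask)
        assert np.allclose(out, vol)

    def test_gaussian_bump_recovered_modulo_global_offset(self):
        # smooth 6*pi bump: unwrap must equal truth up to one global 2*pi*k
        n = 24
        ax = np.arange(n) - n / 2 + 0.5
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        truth = 6 * np.pi * np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * 6 ** 2))
        wrapped = qk.wrap_phase(truth)
        mask = np.ones(truth.shape, dtype=bool)
        out = qk.unwrap_spatial(wrapped, np.ones_like(truth), mask)
        diff = out - truth
        assert np.ptp(diff) < 1e-9
        offset = diff.flat[0]
        assert offset / (2 * np.pi) == pytest.approx(round(offset /
                                                           (2 * np.pi)),
                                                     abs=1e-9)

    def test_output_differs_from_input_by_integer_wraps(self):
        rng = np.random.default_rng(2)
        smooth = rng.normal(size=(10, 10, 10))
        from scipy.ndimage import gaussian_filter
        truth = 8.0 * gaussian_filter(smooth, 2.0)
        wrapped = qk.wrap_phase(truth)
        mask = np.ones(truth.shape, dtype=bool)
        out = qk.unwrap_spatial(wrapped, np.ones_like(truth), mask)
        k = (out - wrapped) / (2 * np.pi)
        assert np.allclose(k, np.round(k), atol=1e-9)

    def test_agrees_with_reliability_sort_reference(self):
        # independent cross-check: path-following unwrapper from scikit-image
        from skimage.restoration import unwrap_phase as sk_unwrap

        rng = np.random.default_rng(4)
        from scipy.ndimage import gaussian_filter
        truth = 9.0 * gaussian_filter(rng.normal(size=(12, 12, 12)), 2.5)
        wrapped = qk.wrap_phase(truth)
        mask = np.ones(truth.shape, dtype=bool)
        ours = qk.unwrap_spatial(wrapped, np.ones_like(truth), mask)
        ref = np.asarray(sk_unwrap(wrapped))
        diff = ours - ref
        assert np.ptp(diff) < 1e-9          # equal up to one global 2*pi*k
        assert diff.flat[0] / (2 * np.pi) == pytest.approx(
            round(diff.flat[0] / (2 * np.pi)), abs=1e-9)

    def test_disconnected_components_reported(self):
        vol = np.zeros((10, 10, 10))
        mask = np.zeros(vol.shape, dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 6:9, 6:9] = True
        with pytest.warns(UserWarning, match="2 disconnected"):
            out = qk.unwrap_spatial(vol, np.ones_like(vol), mask)
        assert np.allclose(out[mask], 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qk.unwrap_spatial(np.zeros((4, 4, 4)), np.ones((4, 4, 4)),
                              np.zeros((4, 4, 4), dtype=bool))


class TestCombineWeightedAverage:
    def test_two_echo_offset_extrapolation_exact(self):
        # phi0 = phi1 - TE1 (phi2 - phi1) / (TE2 - TE1) on noiseless input
        f, phi0 = 7.0, 0.4
        meta = qk.default_meta(grid_shape=(5, 5, 5))
        te = np.asarray(meta.te_list)
        phases = np.stack([np.full((5, 5, 5), 2 * np.pi * f * t + phi0)
                           for t in te])
        from qsmkit.fieldmap import estimate_phi0_two_echo
        est = estimate_phi0_two_echo(phases, te)
        assert np.allclose(est, phi0, atol=1e-12)

    def test_agrees_with_complex_fit_on_noiseless_phantom(self, noiseless32,
                                                          meta32):
        _, data, truth = noiseless32
        fit = qk.fit_complex_multiecho(data)
        unwrapped = qk.template_unwrap_echoes(data, fit.quality,
                                              truth.brain_mask)
        res = qk.combine_weighted_average(data, unwrapped)
        unaliased = truth.brain_mask & (np.abs(truth.total_field) <
                                        0.5 / meta32.delta_te - 1.0)
        assert np.abs(res.field - fit.field)[unaliased].max() < 1e-6

    def test_equal_weights_equal_ols_slope(self):
        # on noiseless linear phase both estimators give the exact slope
        f, phi0 = 12.5, -0.3
        data = _synthetic_dataset(f, phi0=phi0, shape=(4, 4, 4))
        te = np.asarray(data.meta.te_list)
        truth_phase = np.stack([
            np.full((4, 4, 4), 2 * np.pi * f * t + phi0) for t in te])
        res = qk.combine_weighted_average(data, truth_phase,
                                          weight_scheme="uniform")
        slope = np.polyfit(te, truth_phase.reshape(len(te), -1), 1)[0] \
            / (2 * np.pi)
        assert np.allclose(res.field.ravel(), slope, atol=1e-9)
        assert np.allclose(res.field, f, atol=1e-9)

    def test_single_echo_rejected(self):
        data = _synthetic_dataset(5.0, te=(5e-3,))
        with pytest.raises(ValueError, match=">= 2 echoes"):
            qk.combine_weighted_average(data, data.phase)


class TestMultiEchoSnrBenefit:
    def test_five_echo_combination_beats_single_echo(self, meta32):
        # echo averaging must lower the field-error spread at SNR 50,
        # strictly, for every seed tested
        for seed in (1, 2, 3):
            spec = qk.default_phantom_spec(grid_shape=(32, 32, 32), snr=50,
                                           seed=seed)
            data, truth = qk.simulate_multiecho(spec, meta32)
            fit = qk.fit_complex_multiecho(data)
            unwrapped = qk.template_unwrap_echoes(data, fit.quality,
                                                  truth.brain_mask)
            multi = qk.combine_weighted_average(data, unwrapped)
            inner = truth.brain_mask & (np.abs(truth.total_field) <
                                        0.4 / meta32.delta_te)
            te1 = meta32.te_list[0]
            single = (unwrapped[0] - truth.phi0) / (2 * np.pi * te1)
            sd_multi = np.std((multi.field - truth.total_field)[inner])
            sd_single = np.std((single - truth.total_field)[inner])
            assert sd_multi < sd_single


class TestNlfitUnwrappedField:
    def test_resolves_temporal_aliasing_inside_mask(self, noiseless32,
                                                    meta32):
        _, data, truth = noiseless32
        res = qk.nlfit_unwrapped_field(data, truth.brain_mask)
        err = np.abs(res.field - truth.total_field)[truth.brain_mask]
        assert err.max() < 1e-4
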