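import numpy as np
import pytest

from fastdki.dki import (DWIStudy, KurtosisTissueModel, QCBounds,
                         axis_diffusivity, fit_parameter_maps, forward_signal,
                         isotropic_kurtosis_tensor, mean_diffusivity,
                         mean_kurtosis_tensor, mkt_from_tensor)
from fastdki.preprocess import rician_floor_correct
from fastdki.scheme import DiffusionScheme, build_139_scheme, quadrature_weights
from helpers import dense_dki_design, dense_oracle_fit, random_kurtosis_model


def _fit_139(model, scheme):
    """Closed-form 1-3-9 estimate from noise-free forward signals."""
    sig = forward_signal(model, scheme)
    h1 = np.log(sig[1:4] / sig[0])
    h2 = np.log(sig[4:] / sig[0])
    d = axis_diffusivity(h1, h2[scheme.axis_indices_in_shell2], scheme.b1, scheme.b2)
    md = mean_diffusivity(*d)
    return md, mean_kurtosis_tensor(h2, md, scheme)


class TestForwardSignal:
    def test_isotropic_monoexponential(self, scheme):
        m = KurtosisTissueModel.isotropic(1.0, 0.0)
        sig = forward_signal(m, scheme)
        assert sig[0] == 1.0
        np.testing.assert_allclose(sig[1:4], np.exp(-1.0), rtol=1e-12)

    def test_kurtosis_term_high_shell(self, scheme):
        m = KurtosisTissueModel.isotropic(1.0, 1.0)
        sig = forward_signal(m, scheme)
        expected = -2.5 + 2500.0 ** 2 * 1e-6 / 6.0  # = -1.45833...
        np.testing.assert_allclose(np.log(sig[4:]), expected, rtol=1e-12)

    def test_anisotropic_gaussian_attenuation(self, scheme, rng):
        a = rng.standard_normal((3, 3)) * 0.2
        d = a @ a.T + np.eye(3) * 0.8
        m = KurtosisTissueModel(D=d, W=np.zeros((3, 3, 3, 3)))
        sig = forward_signal(m, scheme)
        for k, n in enumerate(scheme.shell2_directions):
            expected = -scheme.b2 * 1e-3 * (n @ d @ n)
            np.testing.assert_allclose(np.log(sig[4 + k]), expected, atol=1e-12)

    def test_isotropic_tensor_has_constant_projection(self, rng):
        w = isotropic_kurtosis_tensor(0.7)
        for _ in range(20):
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            assert abs(np.einsum("ijlm,i,j,l,m->", w, n, n, n, n) - 0.7) < 1e-12
        assert abs(mkt_from_tensor(w) - 0.7) < 1e-12


class TestAxisDiffusivity:
    def test_gaussian_two_point(self):
        assert abs(axis_diffusivity(-1.0, -2.5, 1000, 2500) - 1.0) < 1e-12

    def test_roundtrip_with_kurtosis_term(self):
        # h(b) = -b*D + b^2*V/6 with D = 1e-3 mm^2/s, V = 1e-6 mm^4/s^2
        h1 = -1.0 + 1e6 * 1e-6 / 6.0
        h2 = -2.5 + 6.25e6 * 1e-6 / 6.0
        d, v = axis_diffusivity(h1, h2, 1000, 2500, return_v=True)
        assert abs(d - 1.0) < 1e-10
        assert abs(v - 1.0) < 1e-10

    def test_zero_attenuation(self):
        assert axis_diffusivity(0.0, 0.0, 1000, 2500) == 0.0

    def test_nonfinite_propagates(self):
        assert np.isnan(axis_diffusivity(np.nan, -2.5, 1000, 2500))

    def test_invalid_bvalues(self):
        with pytest.raises(ValueError):
            axis_diffusivity(-1.0, -2.5, 2500, 1000)


def test_mean_diffusivity_is_trace_third(rng):
    assert mean_diffusivity(1.0, 1.0, 1.0) == 1.0
    assert mean_diffusivity(0.5, 1.0, 1.5) == 1.0
    a = rng.standard_normal((3, 3)) * 0.3
    d = a @ a.T + np.eye(3)
    m = KurtosisTissueModel(D=d, W=np.zeros((3, 3, 3, 3)))
    sig = forward_signal(m, build_139_scheme())
    scheme = build_139_scheme()
    h1 = np.log(sig[1:4] / sig[0])
    h2 = np.log(sig[4:] / sig[0])[scheme.axis_indices_in_shell2]
    dx, dy, dz = axis_diffusivity(h1, h2, scheme.b1, scheme.b2)
    assert abs(mean_diffusivity(dx, dy, dz) - np.trace(d) / 3.0) < 1e-12


class TestMeanKurtosisTensor:
    def test_gaussian_signal_zero_kurtosis(self, scheme):
        md, mkt = _fit_139(KurtosisTissueModel.isotropic(0.9, 0.0), scheme)
        assert abs(mkt) < 1e-12

    def test_roundtrip_healthy_white_matter_values(self, scheme):
        md, mkt = _fit_139(KurtosisTissueModel.isotropic(0.747, 0.814), scheme)
        assert abs(md - 0.747) < 1e-12
        assert abs(mkt - 0.814) < 1e-12

    def test_anisotropic_equals_tensor_trace_fifth(self, scheme, rng):
        for _ in range(50):
            m = random_kurtosis_model(rng)
            md, mkt = _fit_139(m, scheme)
            assert abs(mkt - mkt_from_tensor(m.W)) < 1e-9

    def test_nonpositive_md_flagged(self, scheme):
        assert np.isnan(mean_kurtosis_tensor(np.full(9, -1.0), 0.0, scheme))


def test_139_matches_dense_21_parameter_oracle(scheme, rng):
    """1-3-9 MD and MKT agree with a dense 60-direction 3-shell LLS fit."""
    design, bvals, dirs = dense_dki_design(np.random.default_rng(123))
    for _ in range(100):
        m = random_kurtosis_model(rng)
        md, mkt = _fit_139(m, scheme)
        md_o, mkt_o = dense_oracle_fit(m, design, bvals, dirs)
        assert abs(md - md_o) < 1e-9
        assert abs(mkt - mkt_o) < 1e-9
        assert abs(md - m.md) < 1e-9
        assert abs(mkt - mkt_from_tensor(m.W)) < 1e-9


def test_rotation_invariance_isotropic(rng):
    """Estimates from a rotated direction set (recomputed weights) match."""
    from scipy.stats import special_ortho_group
    base = build_139_scheme()
    md0, mkt0 = _fit_139(KurtosisTissueModel.isotropic(0.8, 0.9), base)
    for seed in range(3):
        rot = special_ortho_group.rvs(3, random_state=np.random.RandomState(seed))
        axes = base.axis_directions @ rot.T
        shell2 = base.shell2_directions @ rot.T
        scheme = DiffusionScheme(
            b1=base.b1, b2=base.b2, axis_directions=axes,
            shell2_directions=shell2, shell2_weights=quadrature_weights(shell2))
        md, mkt = _fit_139(KurtosisTissueModel.isotropic(0.8, 0.9), scheme)
        assert abs(md - md0) < 1e-12
        assert abs(mkt - mkt0) < 1e-12


class TestFitParameterMaps:
    def _study(self, data, scheme, sigma=None):
        return DWIStudy(data=data, affine=np.eye(4), scheme=scheme, sigma=sigma)

    def test_noisefree_phantom_exact(self, scheme, rng):
        shape = (6, 5, 4)
        mds = rng.uniform(0.4, 1.5, shape)
        ks = rng.uniform(0.2, 1.2, shape)
        data = np.empty((*shape, 13))
        for idx in np.ndindex(shape):
            data[idx] = forward_signal(
                KurtosisTissueModel.isotropic(mds[idx], ks[idx]), scheme)
        maps = fit_parameter_maps(self._study(data, scheme), np.ones(shape, bool))
        assert maps.qc_mask.all()
        assert np.max(np.abs(maps.md_map - mds)) < 1e-10
        assert np.max(np.abs(maps.mkt_map - ks)) < 1e-10

    def test_all_zero_volume_flagged(self, scheme):
        data = np.zeros((3, 3, 3, 13))
        maps = fit_parameter_maps(self._study(data, scheme), np.ones((3, 3, 3), bool))
        assert not maps.qc_mask.any()
        assert np.isnan(maps.md_map).all()

    def test_single_voxel_healthy_control_roundtrip(self, scheme):
        data = forward_signal(
            KurtosisTissueModel.isotropic(0.747, 0.814), scheme).reshape(1, 1, 1, 13)
        maps = fit_parameter_maps(self._study(data, scheme), np.ones((1, 1, 1), bool))
        assert maps.qc_mask[0, 0, 0]
        assert abs(maps.md_map[0, 0, 0] - 0.747) < 1e-12
        assert abs(maps.mkt_map[0, 0, 0] - 0.814) < 1e-12

    def test_volume_count_mismatch_is_hard_error(self, scheme):
        with pytest.raises(ValueError):
            DWIStudy(data=np.ones((2, 2, 2, 12)), affine=np.eye(4), scheme=scheme)

    def test_mask_grid_mismatch(self, scheme):
        study = self._study(np.ones((2, 2, 2, 13)), scheme)
        with pytest.raises(ValueError):
            fit_parameter_maps(study, np.ones((3, 3, 3), bool))

    def test_out_of_bounds_estimates_flagged(self, scheme):
        # MD of 4e-3 mm^2/s exceeds the default physical ceiling of 3
        data = forward_signal(
            KurtosisTissueModel.isotropic(4.0, 0.0), scheme).reshape(1, 1, 1, 13)
        maps = fit_parameter_maps(self._study(data, scheme), np.ones((1, 1, 1), bool))
        assert not maps.qc_mask[0, 0, 0]
        maps = fit_parameter_maps(self._study(data, scheme),
                                  np.ones((1, 1, 1), bool), QCBounds(md_max=5.0))
        assert maps.qc_mask[0, 0, 0]

    def test_signal_above_s0_flagged(self, scheme):
        data = np.ones((1, 1, 1, 13))
        data[..., 5] = 1.5  # diffusion-weighted volume brighter than b0
        maps = fit_parameter_maps(self._study(data, scheme), np.ones((1, 1, 1), bool))
        assert not maps.qc_mask[0, 0, 0]

    def test_deterministic(self, scheme, rng):
        data = rng.uniform(0.1, 1.0, (4, 4, 4, 13))
        data[..., 0] = 1.2
        study = self._study(data, scheme)
        m1 = fit_parameter_maps(study, np.ones((4, 4, 4), bool))
        m2 = fit_parameter_maps(study, np.ones((4, 4, 4), bool))
        np.testing.assert_array_equal(m1.qc_mask, m2.qc_mask)
        np.testing.assert_array_equal(m1.md_map, m2.md_map)


def test_noise_consistency_median_mkt_bias(scheme, rng):
    """With Rician noise at SNR 50 and floor correction, the median MKT bias
    over 1000 voxels stays within 0.02 for ground truth in [0.5, 1.0]."""
    sigma = 1.0 / 50.0
    n = 1000
    ks = rng.uniform(0.5, 1.0, n)
    amps = np.array([
        forward_signal(KurtosisTissueModel.isotropic(0.8, k), scheme) for k in ks
    ])
    noisy = np.hypot(amps + sigma * rng.standard_normal((n, 13)),
                     sigma * rng.standard_normal((n, 13)))
    corrected = rician_floor_correct(noisy, sigma)
    study = DWIStudy(data=corrected.reshape(n, 1, 1, 13), affine=np.eye(4),
                     scheme=scheme, sigma=sigma)
    maps = fit_parameter_maps(study, np.ones((n, 1, 1), bool))
    ok = maps.qc_mask.ravel()
    bias = maps.mkt_map.ravel()[ok] - ks[ok]
    assert ok.mean() > 0.98
    assert abs(np.median(bias)) <= 0.02
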