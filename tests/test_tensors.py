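import numpy as np
import pytest

from pardti import (
    GradientScheme,
    fa_of,
    fit_dual_nls,
    fit_single_loglinear,
    fit_single_nls,
    fit_volume,
    md_of,
    predict_dual,
    predict_single,
    tensor_eigenvalues,
)
from pardti.phantom import simulate_dwi
from pardti.tensors import D_CSF, EIG_MAX, _fa_md_batch, _fit_dual_batch

from conftest import random_spd_tensor

WM_TENSOR = np.diag([1.5e-3, 0.4e-3, 0.4e-3])


class TestForwardModels:
    def test_b0_returns_s0(self, scheme, rng):
        D = random_spd_tensor(rng)
        s = predict_single(1000.0, D, scheme)
        assert np.allclose(s[scheme.bvals == 0], 1000.0)

    def test_zero_tensor_flat_signal(self, scheme):
        assert np.allclose(predict_single(500.0, np.zeros((3, 3)), scheme), 500.0)

    def test_known_exponent_value(self):
        # one volume, b=1100 along x, isotropic 0.7e-3: S = S0 e^{-0.77}
        sch = GradientScheme(np.array([1100.0]), np.array([[1.0, 0, 0]]))
        s = predict_single(1000.0, np.eye(3) * 0.7e-3, sch)
        assert s[0] == pytest.approx(1000.0 * np.exp(-0.77), rel=1e-12)

    def test_dual_reduces_to_single_at_full_tissue(self, scheme, rng):
        for _ in range(100):
            D = random_spd_tensor(rng)
            a = predict_dual(1000.0, 1.0, D, scheme)
            b = predict_single(1000.0, D, scheme)
            assert np.allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_pure_free_water_ratio(self, scheme):
        s = predict_dual(1000.0, 0.0, WM_TENSOR, scheme)
        for b in (0.0, 300.0, 1100.0):
            sel = scheme.bvals == b
            assert np.allclose(s[sel] / 1000.0, np.exp(-3e-3 * b), rtol=1e-12)

    def test_mixture_value(self):
        sch = GradientScheme(np.array([1100.0]), np.array([[1.0, 0, 0]]))
        s = predict_dual(1000.0, 0.8, np.eye(3) * 0.7e-3, sch)
        expect = 1000.0 * (0.8 * np.exp(-0.77) + 0.2 * np.exp(-3.3))
        assert s[0] == pytest.approx(expect, rel=1e-12)

    def test_fraction_out_of_bounds_rejected(self, scheme):
        with pytest.raises(ValueError, match="f_par"):
            predict_dual(1000.0, 1.2, WM_TENSOR, scheme)


class TestLogLinearFit:
    def test_exact_recovery_noiseless(self, scheme, rng):
        D = random_spd_tensor(rng)
        s0, Dhat = fit_single_loglinear(predict_single(800.0, D, scheme), scheme)
        assert s0 == pytest.approx(800.0, rel=1e-10)
        assert np.allclose(Dhat, D, rtol=1e-10, atol=1e-16)

    def test_flat_signal_gives_zero_tensor(self, scheme):
        s0, Dhat = fit_single_loglinear(np.full(80, 900.0), scheme)
        assert s0 == pytest.approx(900.0)
        assert np.allclose(Dhat, 0.0, atol=1e-12)

    def test_too_few_volumes_rejected(self):
        sch = GradientScheme(
            np.array([0.0, 1000, 1000, 1000, 1000, 1000]),
            np.vstack([np.zeros(3), *[np.eye(3)[i % 3] for i in range(5)]]),
        )
        with pytest.raises(ValueError, match="7 volumes"):
            fit_single_loglinear(np.ones(6), sch)

    def test_nonpositive_signal_rejected(self, scheme):
        sig = np.ones(80)
        sig[5] = 0.0
        with pytest.raises(ValueError, match="[Nn]on-positive"):
            fit_single_loglinear(sig, scheme)


class TestNonlinearFits:
    def test_single_nls_recovers_noiseless(self, scheme, rng):
        D = random_spd_tensor(rng)
        sig = predict_single(1200.0, D, scheme)
        s0, Dhat, rss, conv = fit_single_nls(sig, scheme)
        assert conv
        assert s0 == pytest.approx(1200.0, rel=1e-8)
        assert np.allclose(Dhat, D, rtol=1e-6, atol=1e-12)
        assert rss < 1e-12

    def test_single_nls_init_at_truth_stays(self, scheme):
        sig = predict_single(1000.0, WM_TENSOR, scheme)
        s0, Dhat, rss, conv = fit_single_nls(sig, scheme,
                                             init=(1000.0, WM_TENSOR))
        assert conv and rss < 1e-14

    def test_dual_nls_recovers_noiseless(self, scheme):
        sig = predict_dual(1000.0, 0.85, WM_TENSOR, scheme)
        fit = fit_dual_nls(sig, scheme)
        assert fit.converged
        assert fit.f_par == pytest.approx(0.85, abs=1e-6)
        assert np.allclose(fit.d_par, WM_TENSOR, atol=1e-9)

    def test_dual_fractions_sum_to_one_exactly(self, scheme, rng):
        sig = predict_dual(1000.0, 0.6, random_spd_tensor(rng), scheme)
        sig *= 1.0 + 0.02 * rng.standard_normal(80)
        fit = fit_dual_nls(np.abs(sig), scheme)
        assert fit.f_par + fit.f_csf == 1.0

    def test_pure_free_water_hits_boundary(self, scheme):
        sig = predict_dual(1000.0, 0.0, np.eye(3) * 1e-3, scheme)
        fit = fit_dual_nls(sig, scheme)
        assert fit.f_par <= 0.02

    def test_single_shell_rejected_as_unidentifiable(self):
        bvals = np.r_[0.0, np.full(9, 1000.0)]
        bvecs = np.vstack([np.zeros(3)] + [np.eye(3)[i % 3] for i in range(9)])
        sch = GradientScheme(bvals, bvecs)
        with pytest.raises(ValueError, match="shells"):
            fit_dual_nls(np.ones(10), sch)

    def test_snr30_f_par_unbiased(self, scheme, rng):
        # Monte-Carlo: Rician noise at SNR 30, truth f_par 0.8
        n = 500
        s = predict_dual(1000.0, 0.8, WM_TENSOR, scheme)
        sigma = 1000.0 / 30.0
        y = np.sqrt(
            (s[None] + rng.normal(0, sigma, (n, 80))) ** 2
            + rng.normal(0, sigma, (n, 80)) ** 2
        )
        _, f, _, _, _ = _fit_dual_batch(y, scheme)
        assert abs(f.mean() - 0.8) < 0.03

    def test_snr30_md_within_5pct(self, scheme, rng):
        # isotropic 0.7e-3 truth, single-compartment NLS
        n = 1000
        s = predict_single(1000.0, np.eye(3) * 0.7e-3, scheme)
        sigma = 1000.0 / 30.0
        y = np.sqrt(
            (s[None] + rng.normal(0, sigma, (n, 80))) ** 2
            + rng.normal(0, sigma, (n, 80)) ** 2
        )
        from pardti.tensors import _fit_single_batch

        _, D6, _, _ = _fit_single_batch(y, scheme)
        _, md = _fa_md_batch(D6)
        assert np.median(md) == pytest.approx(0.7e-3, rel=0.05)


class TestEigenScalars:
    def test_isotropic(self):
        D = np.eye(3) * 1.1e-3
        assert fa_of(D) == 0.0
        assert md_of(D) == pytest.approx(1.1e-3)

    def test_stick_limit(self):
        assert fa_of(np.diag([2e-3, 0, 0])) == pytest.approx(1.0)

    def test_zero_tensor_defined(self):
        assert fa_of(np.zeros((3, 3))) == 0.0

    def test_formula_oracle(self):
        lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        D = np.diag(lam)
        md = lam.mean()
        fa_expect = np.sqrt(1.5 * np.sum((lam - md) ** 2) / np.sum(lam**2))
        assert md_of(D) == pytest.approx(0.76667e-3, rel=1e-4)
        assert fa_of(D) == pytest.approx(fa_expect, rel=1e-12)
        assert np.allclose(tensor_eigenvalues(D), np.sort(lam)[::-1])


class TestFitVolume:
    def test_noiseless_phantom_recovers_truth(self, scheme, labels24, truth24):
        dwi = simulate_dwi(truth24, scheme, snr=np.inf)
        mask = labels24.tissue_mask
        res = fit_volume(dwi, scheme, mask, model="dual")
        assert np.max(np.abs(res.maps["pVF"][mask] - truth24.f_par[mask])) < 1e-4
        fa_t, md_t = _fa_md_batch(truth24.d_par[mask])
        assert np.max(np.abs(res.maps["pFA"][mask] - fa_t)) < 1e-4
        assert np.max(np.abs(res.maps["pMD"][mask] - md_t)) < 1e-7

    def test_constraints_hold_on_noisy_fits(self, scheme, labels24, truth24, rng):
        dwi = simulate_dwi(truth24, scheme, snr=25.0, seed=7)
        mask = labels24.tissue_mask
        res = fit_volume(dwi, scheme, mask, model="dual")
        f = res.maps["pVF"][mask]
        assert np.all((f >= 0) & (f <= 1))
        lam = np.linalg.eigvalsh(
            np.stack([res.tensors[mask][:, [0, 3, 4]],
                      res.tensors[mask][:, [3, 1, 5]],
                      res.tensors[mask][:, [4, 5, 2]]], axis=1)
        )
        assert lam.min() >= -1e-12
        assert lam.max() <= EIG_MAX + 1e-12

    def test_snr30_pfa_close_to_truth(self, scheme, labels24, truth24):
        dwi = simulate_dwi(truth24, scheme, snr=30.0, seed=3)
        mask = labels24.tissue_mask
        res = fit_volume(dwi, scheme, mask, model="dual")
        sel = mask & (truth24.f_par >= 0.6)
        fa_t, _ = _fa_md_batch(truth24.d_par[sel])
        err = np.abs(res.maps["pFA"][sel] - fa_t)
        assert np.median(err) <= 0.05

    def test_empty_mask_gives_zero_maps(self, scheme):
        dwi = np.ones((4, 4, 4, 80))
        res = fit_volume(dwi, scheme, np.zeros((4, 4, 4), bool), model="dual")
        for m in res.maps.values():
            assert np.all(m == 0)
        assert not res.converged.any()

    def test_volume_count_mismatch_rejected(self, scheme):
        with pytest.raises(ValueError, match="80"):
            fit_volume(np.ones((4, 4, 4, 10)), scheme,
                       np.ones((4, 4, 4), bool))
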