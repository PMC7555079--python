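import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwiharm import (
    DWIDataset,
    disperse_directions,
    fdr_correct,
    fit_dti_metrics,
    fit_rish,
    kl_symmetric,
    paired_effect_size,
    pct_difference_preservation,
    voxelwise_errors,
)
from dwiharm.evaluation import MetricMap, hedges_g, real_sh_basis


def tensor_dataset(eigenvalues, n_dirs=30, bval=1200.0, shape=(3, 3, 3), seed=0):
    """Tiny dataset whose every voxel carries the same diffusion tensor."""
    dirs = disperse_directions(n_dirs, rng_seed=seed)
    T = np.diag(eigenvalues)
    quad = np.einsum("di,ij,dj->d", dirs, T, dirs)
    s0 = 100.0
    sig = s0 * np.exp(-bval * quad)
    signal = np.empty(shape + (n_dirs + 1,))
    signal[..., 0] = s0
    signal[..., 1:] = sig
    bvals = np.r_[0.0, np.full(n_dirs, bval)]
    bvecs = np.vstack([np.zeros(3), dirs])
    return DWIDataset(
        signal=signal,
        bvals=bvals,
        bvecs=bvecs,
        affine=np.eye(4),
        mask=np.ones(shape, bool),
    )


class TestDTIMetrics:
    def test_isotropic_tensor_gives_fa_zero_adc_d(self):
        d = 1.1e-3
        ds = tensor_dataset((d, d, d))
        adc, fa = fit_dti_metrics(ds)
        np.testing.assert_allclose(adc.samples(), d, atol=1e-9)
        np.testing.assert_allclose(fa.samples(), 0.0, atol=1e-6)

    def test_rank_one_tensor_gives_fa_one(self):
        ds = tensor_dataset((1.5e-3, 0.0, 0.0))
        _, fa = fit_dti_metrics(ds)
        np.testing.assert_allclose(fa.samples(), 1.0, atol=1e-6)

    def test_prolate_tensor_closed_form(self):
        # eigenvalues (1.7, 0.2, 0.2)e-3: ADC = 0.7e-3, FA = sqrt(2.25/2.97)
        ds = tensor_dataset((1.7e-3, 0.2e-3, 0.2e-3))
        adc, fa = fit_dti_metrics(ds)
        np.testing.assert_allclose(adc.samples(), 0.7e-3, atol=1e-9)
        np.testing.assert_allclose(fa.samples(), 0.8703, atol=1e-3)

    def test_fa_invariant_to_global_signal_scaling(self):
        ds = tensor_dataset((1.7e-3, 0.2e-3, 0.2e-3))
        scaled = ds.copy_with(signal=ds.signal * 3.7)
        _, fa = fit_dti_metrics(ds)
        _, fa2 = fit_dti_metrics(scaled)
        np.testing.assert_allclose(fa2.samples(), fa.samples(), atol=1e-10)

    def test_too_few_directions_rejected(self):
        ds = tensor_dataset((1e-3, 1e-3, 1e-3), n_dirs=5)
        with pytest.raises(ValueError, match="6"):
            fit_dti_metrics(ds)


class TestRISH:
    def test_isotropic_signal_has_zero_rish2(self):
        ds = tensor_dataset((0.9e-3, 0.9e-3, 0.9e-3), n_dirs=30)
        r0, r2 = fit_rish(ds)
        assert np.all(r0.samples() > 0)
        np.testing.assert_allclose(r2.samples(), 0.0, atol=1e-10)

    def test_quadratic_homogeneity_on_raw_fit(self):
        ds = tensor_dataset((1.7e-3, 0.2e-3, 0.2e-3), n_dirs=30)
        # scale only the DWI shell so the raw (unnormalized) fit sees factor a
        a = 2.5
        r0, r2 = fit_rish(ds, normalize=False)
        scaled = ds.copy_with(signal=ds.signal * a)
        r0s, r2s = fit_rish(scaled, normalize=False)
        np.testing.assert_allclose(r0s.samples(), a**2 * r0.samples(), rtol=1e-10)
        np.testing.assert_allclose(r2s.samples(), a**2 * r2.samples(), rtol=1e-8)

    def test_known_coefficients_round_trip(self):
        dirs = disperse_directions(60, rng_seed=4)
        basis, degrees = real_sh_basis(6, dirs)
        rng = np.random.default_rng(8)
        coeffs = rng.standard_normal(basis.shape[1])
        sig = basis @ coeffs
        shape = (2, 2, 2)
        signal = np.empty(shape + (61,))
        signal[..., 0] = 1.0
        signal[..., 1:] = sig
        ds = DWIDataset(
            signal=signal,
            bvals=np.r_[0.0, np.full(60, 1000.0)],
            bvecs=np.vstack([np.zeros(3), dirs]),
            affine=np.eye(4),
            mask=np.ones(shape, bool),
        )
        r0, r2 = fit_rish(ds, sh_order=6, normalize=False)
        np.testing.assert_allclose(
            r0.samples(), (coeffs[degrees == 0] ** 2).sum(), atol=1e-6
        )
        np.testing.assert_allclose(
            r2.samples(), (coeffs[degrees == 2] ** 2).sum(), atol=1e-6
        )

    def test_multi_shell_rejected(self):
        ds = tensor_dataset((1e-3, 1e-3, 1e-3), n_dirs=30)
        bvals = ds.bvals.copy()
        bvals[-1] = 2500.0
        with pytest.raises(ValueError, match="b-values"):
            fit_rish(ds.copy_with(bvals=bvals))


class TestVoxelwiseErrors:
    def _map(self, values):
        arr = np.asarray(values, float).reshape(1, 1, -1)
        return MetricMap(arr, "ADC", np.ones(arr.shape, bool))

    def test_identical_maps_give_zero_errors(self):
        mp = self._map(np.linspace(0.5, 2.0, 50))
        summary = voxelwise_errors(mp, mp)
        assert summary.mne_stats["mean"] == 0.0
        assert summary.error_stats["mean"] == 0.0

    @pytest.mark.parametrize(
        "pred,acq,err,mne", [(1.2, 1.0, 0.2, 0.2), (0.8, 1.0, -0.2, 0.2)]
    )
    def test_signed_error_and_relative_mne(self, pred, acq, err, mne):
        summary = voxelwise_errors(self._map([pred] * 20), self._map([acq] * 20))
        assert summary.error_stats["mean"] == pytest.approx(err)
        assert summary.mne_stats["mean"] == pytest.approx(mne)

    def test_zero_acquired_excluded_and_counted(self):
        acq = self._map([0.0, 1.0, 1.0, 1.0])
        pred = self._map([1.0, 1.0, 1.0, 1.0])
        summary = voxelwise_errors(pred, acq)
        assert summary.n_zero_acquired == 1

    def test_metric_mismatch_rejected(self):
        a = self._map([1.0])
        b = MetricMap(a.values, "FA", a.mask)
        with pytest.raises(ValueError, match="FA"):
            voxelwise_errors(a, b)


class TestKLSymmetric:
    def test_identical_samples_give_zero(self, rng):
        x = rng.standard_normal(500)
        assert kl_symmetric(x, x) == 0.0

    def test_two_bin_worked_value(self):
        # P = (0.5, 0.5), Q = (0.9, 0.1) -> 0.5 ln(25/9) + 0.9 ln 1.8 + 0.1 ln 0.2
        p = np.r_[np.zeros(50), np.ones(50)]
        q = np.r_[np.zeros(90), np.ones(10)]
        expected = (
            0.5 * np.log(0.5 / 0.9)
            + 0.5 * np.log(0.5 / 0.1)
            + 0.9 * np.log(0.9 / 0.5)
            + 0.1 * np.log(0.1 / 0.5)
        )
        assert kl_symmetric(p, q, k=2) == pytest.approx(expected, rel=1e-12)
        assert kl_symmetric(p, q, k=2) == pytest.approx(0.8789, abs=1e-4)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(0, 1, 300)
        b = r.normal(r.uniform(-1, 1), r.uniform(0.5, 2), 300)
        kl_ab = kl_symmetric(a, b)
        assert kl_ab >= 0.0
        assert kl_ab == pytest.approx(kl_symmetric(b, a), rel=1e-12)

    def test_constant_identical_samples(self):
        assert kl_symmetric(np.ones(10), np.ones(10)) == 0.0


class TestPctDifference:
    def _maps(self, h, b, ha, ba, shape=(4, 4, 4)):
        mk = lambda v: MetricMap(np.full(shape, v, float), "ADC", np.ones(shape, bool))
        return mk(h), mk(b), mk(ha), mk(ba)

    def test_inert_harmonization_gives_zero(self):
        maps = self._maps(1.0, 1.0, 2.0, 2.0)
        out, n_exc = pct_difference_preservation(*maps, region=((0, 0, 0), (2, 2, 2)))
        np.testing.assert_allclose(out, 0.0)
        assert n_exc == 0

    def test_equal_relative_change_cancels(self):
        maps = self._maps(1.1, 1.0, 2.2, 2.0)  # +10% in both arms
        out, _ = pct_difference_preservation(*maps, region=((0, 0, 0), (2, 2, 2)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_worked_value(self):
        maps = self._maps(1.1, 1.0, 2.4, 2.0)  # +10% vs +20% -> -10
        out, _ = pct_difference_preservation(*maps, region=((0, 0, 0), (2, 2, 2)))
        np.testing.assert_allclose(out, -10.0, atol=1e-10)

    def test_zero_baseline_excluded(self):
        maps = self._maps(1.1, 0.0, 2.4, 2.0)
        out, n_exc = pct_difference_preservation(*maps, region=((0, 0, 0), (2, 2, 2)))
        assert n_exc == 8
        assert np.all(np.isnan(out))


class TestEffectSize:
    def test_identical_samples_give_zero_g(self, rng):
        x = rng.standard_normal(40)
        res = paired_effect_size(x, x)
        assert res.g == 0.0

    def test_one_sd_difference_large_n_approaches_one(self, rng):
        x = rng.standard_normal(20000)
        sd = x.std(ddof=1)
        res = paired_effect_size(x, x + sd)
        assert res.g == pytest.approx(1.0, abs=0.01)

    def test_bias_correction_worked_value(self):
        # n1 = n2 = 21, one-SD mean difference: g = 1 - 3/159
        n = 21
        base = np.linspace(-2, 2, n)
        sd = base.std(ddof=1)
        res = paired_effect_size(base, base + sd)
        assert res.g == pytest.approx(1.0 * (1.0 - 3.0 / 159.0), rel=1e-12)
        assert res.g == pytest.approx(0.9811, abs=1e-4)

    def test_symmetric_in_samples(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 0.4
        assert hedges_g(a, b) == pytest.approx(hedges_g(b, a), rel=1e-14)

    def test_zero_pooled_sd_flagged(self):
        res = paired_effect_size(np.ones(5), np.full(5, 2.0))
        assert np.isnan(res.g)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            paired_effect_size(rng.standard_normal(5), rng.standard_normal(6))


class TestFDR:
    def test_corrected_pvalues_monotone_and_not_smaller(self, rng):
        from dwiharm.evaluation import EffectSizeResult

        pvals = np.sort(rng.uniform(0, 1, 12))
        results = [
            EffectSizeResult(
                g=0.1, means=(0, 0), sds=(1, 1), ns=(5, 5), t_stat=0.0, p_value=p
            )
            for p in pvals
        ]
        corrected = fdr_correct(results)
        assert np.all(np.diff(corrected) >= -1e-12)
        assert np.all(corrected >= pvals - 1e-12)
        assert all(r.p_fdr is not None for r in results)
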