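"""Deconvolution systems, residue recovery, perfusion-parameter estimation."""

import numpy as np
import pytest

from ctperf.curves import BolusParams, IntensityCurve, TissueClassSpec, make_bolus_curve, make_tissue_curve
from ctperf.deconv import (
    build_circulant_matrix,
    build_conv_matrix,
    deconvolve,
    estimate_params,
    make_maps,
)


def _aif(n=30, dt=1.5, **kw):
    return make_bolus_curve(BolusParams(**kw), n, dt)


class TestToeplitzMatrix:
    def test_hand_example(self):
        sys_ = build_conv_matrix(np.array([1.0, 2.0, 0.0]), dt=1.0)
        np.testing.assert_array_equal(
            sys_.matrix, [[1, 0, 0], [2, 1, 0], [0, 2, 1]]
        )

    def test_impulse_gives_identity(self):
        sys_ = build_conv_matrix(np.eye(5)[0], dt=1.0)
        np.testing.assert_array_equal(sys_.matrix, np.eye(5))

    def test_strictly_lower_triangular_structure(self, rng):
        v = rng.random(12)
        A = build_conv_matrix(v, dt=1.5).matrix
        assert np.all(A[np.triu_indices(12, k=1)] == 0)

    @pytest.mark.parametrize("n", range(2, 31))
    def test_matches_brute_force_oracle(self, n, rng):
        v = rng.random(n)
        dt = 1.5
        A = build_conv_matrix(v, dt=dt).matrix
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if j <= i:
                    expected[i, j] = dt * v[i - j]
        np.testing.assert_array_equal(A, expected)


class TestCirculantMatrix:
    def test_hand_example(self):
        sys_ = build_circulant_matrix(np.array([1.0, 2.0]), dt=1.0)
        np.testing.assert_array_equal(
            sys_.matrix,
            [[1, 0, 0, 2], [2, 1, 0, 0], [0, 2, 1, 0], [0, 0, 2, 1]],
        )

    def test_top_left_block_equals_toeplitz(self, rng):
        v = rng.random(10)
        A = build_conv_matrix(v, dt=1.5).matrix
        C = build_circulant_matrix(v, dt=1.5).matrix
        np.testing.assert_array_equal(C[:10, :10], A)

    def test_row_sums_equal(self, rng):
        C = build_circulant_matrix(rng.random(8), dt=1.0).matrix
        sums = C.sum(axis=1)
        np.testing.assert_allclose(sums, sums[0])

    @pytest.mark.parametrize("n", range(2, 31))
    def test_matches_modular_index_oracle(self, n, rng):
        v = rng.random(n)
        dt = 1.5
        C = build_circulant_matrix(v, dt=dt).matrix
        col = np.concatenate([dt * v, np.zeros(n)])
        L = 2 * n
        expected = np.empty((L, L))
        for i in range(L):
            for j in range(L):
                expected[i, j] = col[(i - j) % L]
        np.testing.assert_array_equal(C, expected)


class TestDeconvolve:
    def test_identity_system_returns_tissue(self, rng):
        sys_ = build_conv_matrix(np.eye(20)[0], dt=1.0)
        v = rng.random(20)
        r = deconvolve(v, sys_, truncation_fraction=0.0)
        np.testing.assert_allclose(r.r, v, atol=1e-10)

    def test_zero_tissue_gives_zero_residue(self):
        sys_ = build_circulant_matrix(_aif().baseline_subtracted(), dt=1.5)
        r = deconvolve(np.zeros(30), sys_, 0.0)
        np.testing.assert_allclose(r.r, 0.0, atol=1e-12)

    def test_all_zero_aif_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            sys_ = build_conv_matrix(np.zeros(10), dt=1.0)
            deconvolve(np.ones(10), sys_, 0.0)

    @pytest.mark.parametrize("mode", ["sSVD", "bcSVD"])
    def test_roundtrip_reconvolution_noiseless(self, mode):
        aif = _aif()
        tissue = make_tissue_curve(aif, TissueClassSpec("n", 0.04, 4.0)).values
        build = build_conv_matrix if mode == "sSVD" else build_circulant_matrix
        sys_ = build(aif.values, dt=1.5)
        r = deconvolve(tissue, sys_, truncation_fraction=0.0)
        v = tissue if mode == "sSVD" else np.concatenate([tissue, np.zeros(30)])
        recon = sys_.matrix @ r.r
        assert np.linalg.norm(recon - v) <= 1e-6 * np.linalg.norm(v)

    def test_truncation_monotonically_degrades_reconvolution(self):
        aif = _aif()
        tissue = make_tissue_curve(aif, TissueClassSpec("n", 0.04, 4.0)).values
        sys_ = build_circulant_matrix(aif.values, dt=1.5)
        v = np.concatenate([tissue, np.zeros(30)])
        errs = []
        for tf in (0.0, 0.02, 0.05, 0.10, 0.20, 0.40):
            r = deconvolve(tissue, sys_, tf)
            errs.append(np.linalg.norm(sys_.matrix @ r.r - v))
        assert all(b >= a - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_linearity_in_tissue(self):
        aif = _aif()
        tissue = make_tissue_curve(aif, TissueClassSpec("n", 0.04, 4.0)).values
        sys_ = build_circulant_matrix(aif.values, dt=1.5)
        r1 = deconvolve(tissue, sys_, 0.05)
        r3 = deconvolve(3.0 * tissue, sys_, 0.05)
        np.testing.assert_allclose(r3.r, 3.0 * r1.r, rtol=1e-9)


class TestEstimateParams:
    def test_impulse_aif_exponential_tissue_recovery(self):
        dt, cbf, mtt = 1.5, 0.05, 4.0
        impulse = IntensityCurve(np.eye(30)[0], dt=dt)
        tissue = make_tissue_curve(impulse, TissueClassSpec("n", cbf, mtt))
        sys_ = build_conv_matrix(impulse.values, dt=dt)
        r = deconvolve(tissue.values, sys_, 0.0)
        p = estimate_params(r, tissue.values, impulse.values)
        assert p.cbf == pytest.approx(cbf, rel=0.02)
        assert p.mtt == pytest.approx(mtt, rel=0.05)

    def test_planted_delay_read_back_as_tmax(self):
        aif = _aif()
        tissue = make_tissue_curve(aif, TissueClassSpec("d", 0.04, 4.0, delay=4.5))
        sys_ = build_circulant_matrix(aif.baseline_subtracted(), dt=1.5)
        r = deconvolve(tissue.baseline_subtracted(), sys_, 0.10)
        p = estimate_params(r, tissue.baseline_subtracted(), aif.baseline_subtracted())
        assert abs(p.tmax - 4.5) <= 1.5  # within one frame

    def test_zero_tissue_zero_params(self):
        aif = _aif()
        sys_ = build_circulant_matrix(aif.baseline_subtracted(), dt=1.5)
        r = deconvolve(np.zeros(30), sys_, 0.0)
        p = estimate_params(r, np.zeros(30), aif.baseline_subtracted())
        assert p.cbf == pytest.approx(0.0, abs=1e-12)
        assert p.cbv == pytest.approx(0.0, abs=1e-12)

    def test_near_zero_aif_integral_raises(self):
        r_sys = build_conv_matrix(np.eye(10)[0], dt=1.0)
        r = deconvolve(np.ones(10), r_sys, 0.0)
        with pytest.raises(ValueError, match="integral"):
            estimate_params(r, np.ones(10), np.zeros(10))

    def test_mtt_estimators_agree_at_fine_sampling(self):
        # central-volume ratio and residue transit time converge as dt -> 0
        dt, n = 0.2, 250
        aif = make_bolus_curve(BolusParams(), n, dt)
        tissue = make_tissue_curve(aif, TissueClassSpec("n", 0.04, 4.0))
        sys_ = build_circulant_matrix(aif.values, dt=dt)
        r = deconvolve(tissue.values, sys_, 0.0)
        a = estimate_params(r, tissue.values, aif.values, mtt_from="residue")
        b = estimate_params(r, tissue.values, aif.values, mtt_from="cvt")
        assert a.mtt == pytest.approx(b.mtt, rel=0.03)
        assert a.mtt == pytest.approx(4.0, rel=0.05)


class TestMakeMaps:
    def test_noiseless_phantom_cbf_recovery(self, clean_phantom):
        series, truth = clean_phantom
        maps = make_maps(series, truth.curves["AIF"], truth.brain_mask,
                         mode="bcSVD", truncation_fraction=0.0)
        for cls in ("normal", "core", "penumbra"):
            m = truth.masks[cls]
            rel = np.abs(maps.cbf[m] - truth.cbf[m]) / truth.cbf[m]
            assert np.median(rel) <= 0.05

    def test_masked_out_voxels_are_zero(self, clean_phantom):
        series, truth = clean_phantom
        mask = truth.brain_mask & ~truth.masks["core"]
        maps = make_maps(series, truth.curves["AIF"], mask)
        core = truth.masks["core"]
        for name in ("cbf", "cbv", "mtt", "tmax"):
            assert np.all(getattr(maps, name)[core] == 0)

    def test_modes_agree_without_delay(self, clean_phantom):
        series, truth = clean_phantom
        mask = truth.masks["normal"] | truth.masks["core"]  # zero-delay classes
        a = make_maps(series, truth.curves["AIF"], mask, mode="sSVD", truncation_fraction=0.0)
        b = make_maps(series, truth.curves["AIF"], mask, mode="bcSVD", truncation_fraction=0.0)
        rel = np.abs(a.cbf[mask] - b.cbf[mask]) / np.maximum(b.cbf[mask], 1e-12)
        assert np.median(rel) <= 0.05

    def test_scalar_and_vectorised_paths_agree(self, clean_phantom):
        series, truth = clean_phantom
        maps = make_maps(series, truth.curves["AIF"], truth.brain_mask,
                         mode="bcSVD", truncation_fraction=0.10)
        aif = truth.curves["AIF"]
        vx = (40, 45, 4)  # penumbra voxel
        assert truth.masks["penumbra"][vx]
        tissue = series.data[vx] - series.data[vx][:4].mean()
        sys_ = build_circulant_matrix(aif.baseline_subtracted(), dt=series.dt)
        r = deconvolve(tissue, sys_, 0.10)
        p = estimate_params(r, tissue, aif.baseline_subtracted())
        assert maps.cbf[vx] == pytest.approx(p.cbf, rel=1e-9)
        assert maps.mtt[vx] == pytest.approx(p.mtt, rel=1e-9)
        assert maps.tmax[vx] == pytest.approx(p.tmax, abs=1e-12)
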