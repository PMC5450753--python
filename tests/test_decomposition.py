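"""Parallel test, rotated temporal PCA, infomax ICA, and component
assembly/selection contracts."""

import numpy as np
import pytest
from statsmodels.multivariate.factor_rotation import rotate_factors

from denserp.decomposition import (DecompositionError, assemble_components,
                                   best_match, factor_scores_by_channel,
                                   parallel_test, select_components,
                                   spatial_infomax_ica, temporal_pca_promax)


def _erp_like(data4d, fs=250.0, window=(-200.0, 800.0)):
    from denserp.preprocessing import CONDITIONS, ERPDataset
    S, Cd, C, T = data4d.shape
    return ERPDataset(data4d, [f"S{i}" for i in range(S)], CONDITIONS[:Cd],
                      fs, window, np.full((S, Cd), 30))


class TestParallelTest:
    def test_constructed_rank_three_recovered(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1, 250)
        basis = np.stack([np.sin(2 * np.pi * (i + 1) * t) for i in range(3)])
        X = rng.normal(size=(500, 3)) @ basis * 10 + rng.standard_normal((500, 250))
        assert parallel_test(X, 20, seed=0).retained == 3

    def test_constant_data_retains_nothing(self):
        assert parallel_test(np.ones((50, 30)), 20, seed=0).retained == 0

    def test_white_noise_null_retention(self):
        """Monte-Carlo under the null: the mean-crossing rule usually keeps
        at most a couple of factors (median 0); occasional longer runs are
        inherent to correlated scree fluctuations."""
        rng = np.random.default_rng(42)
        rets = [parallel_test(rng.standard_normal((500, 100)), 10, seed=s).retained
                for s in range(20)]
        assert sum(r <= 2 for r in rets) >= 14
        assert np.median(rets) <= 1

    def test_surrogate_floor(self):
        with pytest.raises(DecompositionError):
            parallel_test(np.zeros((10, 5)), 5, seed=0)


class TestTemporalPca:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        t = np.exp(-0.5 * ((np.arange(250) - 120) / 20.0) ** 2)
        X = np.outer(rng.normal(2, 1, 400), t)
        tf = temporal_pca_promax(X, 1)
        assert tf.variance_fraction[0] > 0.999
        assert abs(np.corrcoef(tf.loadings[:, 0], t)[0, 1]) > 0.999

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 10))
        tf = temporal_pca_promax(X, 10)
        assert np.abs(tf.reconstruct() - X).max() < 1e-8

    def test_promax_separates_overlapping_gaussians(self):
        """Two overlapping deflections (288/364 ms, FWHM 120 ms): oblique
        rotation recovers both, the unrotated second PC does not."""
        rng = np.random.default_rng(2)
        tt = np.arange(250) * 4.0 - 200.0
        g1 = np.exp(-0.5 * ((tt - 288) / 50.97) ** 2)
        g2 = np.exp(-0.5 * ((tt - 364) / 50.97) ** 2)
        amps = rng.normal(2, 1, size=(300, 2))
        X = np.outer(amps[:, 0], g1) + np.outer(amps[:, 1], g2)
        X += 0.05 * rng.standard_normal(X.shape)
        tf = temporal_pca_promax(X, 2, kappa=3)
        r = np.zeros((2, 2))
        for i in range(2):
            r[i, 0] = abs(np.corrcoef(tf.loadings[:, i], g1)[0, 1])
            r[i, 1] = abs(np.corrcoef(tf.loadings[:, i], g2)[0, 1])
        assert max(r[0, 0], r[1, 0]) > 0.95 and max(r[0, 1], r[1, 1]) > 0.95
        Vt = np.linalg.svd(X - X.mean(0), full_matrices=False)[2]
        assert abs(np.corrcoef(Vt[1], g2)[0, 1]) < 0.9

    def test_kappa_one_equals_varimax(self):
        """Promax with power one is a no-op oblique step: it returns the
        (Kaiser-normalized) varimax solution unchanged."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 30)) @ rng.normal(size=(30, 30))
        tf = temporal_pca_promax(X, 3, kappa=1)
        Xc = X - X.mean(0, keepdims=True)
        sv, Vt = np.linalg.svd(Xc, full_matrices=False)[1:]
        L = Vt[:3].T * (sv[:3] / np.sqrt(X.shape[0] - 1))
        h = np.linalg.norm(L, axis=1, keepdims=True)
        Lv, _ = rotate_factors(L / h, "varimax")
        Lv *= h
        assert np.allclose(np.abs(tf.loadings), np.abs(Lv), atol=1e-8)

    def test_factor_correlations_well_formed(self):
        rng = np.random.default_rng(5)
        tf = temporal_pca_promax(rng.normal(size=(200, 50)), 4)
        fc = tf.factor_correlations
        assert np.allclose(fc, fc.T) and np.allclose(np.diag(fc), 1.0)

    def test_excess_factors_rejected(self):
        with pytest.raises(DecompositionError):
            temporal_pca_promax(np.random.default_rng(0).normal(size=(5, 30)), 10)


class TestInfomax:
    def test_known_two_by_two_mixing_recovered(self):
        rng = np.random.default_rng(6)
        S = rng.laplace(size=(5000, 2))
        A = np.array([[1.0, 0.6], [-0.4, 1.0]])
        sc = spatial_infomax_ica(S @ A.T, 2, seed=0)
        assert sc.converged
        for j in range(2):
            assert max(abs(np.corrcoef(sc.maps[:, i], A[:, j])[0, 1])
                       for i in range(2)) > 0.95

    def test_whitened_independent_input_near_signed_permutation(self):
        rng = np.random.default_rng(7)
        S = rng.laplace(size=(8000, 3))
        S = (S - S.mean(0)) / S.std(0)
        sc = spatial_infomax_ica(S, 3, seed=1)
        P = np.abs(sc.unmixing) / np.abs(sc.unmixing).max(axis=1, keepdims=True)
        for row in P:
            assert sorted(row)[-2] < 0.1  # one dominant entry per row

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        Y = rng.laplace(size=(2000, 4)) @ rng.normal(size=(4, 4))
        a = spatial_infomax_ica(Y, 4, seed=3)
        b = spatial_infomax_ica(Y, 4, seed=3)
        assert np.array_equal(a.maps, b.maps)

    def test_mixing_unmixing_identity(self):
        rng = np.random.default_rng(9)
        Y = rng.laplace(size=(3000, 6)) @ rng.normal(size=(6, 6))
        sc = spatial_infomax_ica(Y, 4, seed=0)
        assert np.abs(sc.unmixing @ sc.maps - np.eye(4)).max() < 1e-6


def _synthetic_erp(rng, S=12, Cd=4, C=32, T=250, k=3):
    """Low-rank spatiotemporal data with known bilinear structure."""
    tt = np.arange(T) * 4.0 - 200.0
    waves = np.stack([np.exp(-0.5 * ((tt - mu) / 45.0) ** 2)
                      for mu in (150.0, 290.0, 420.0)])[:k]
    maps = rng.normal(size=(k, C))
    maps -= maps.mean(axis=1, keepdims=True)  # average-referenced, like ERPs
    amps = rng.normal(0.0, 1.5, size=(S, Cd, k))
    data = np.einsum("sck,kx,kt->scxt", amps, maps, waves)
    data += 0.02 * rng.standard_normal(data.shape)
    return data, waves, maps


class TestAssembleSelect:
    def test_candidate_count_is_the_cross(self):
        rng = np.random.default_rng(10)
        data, _, _ = _synthetic_erp(rng)
        erp = _erp_like(data)
        tf = temporal_pca_promax(erp, 17)
        sc = spatial_infomax_ica(factor_scores_by_channel(tf), 8, seed=0,
                                 max_iter=50)
        cands = assemble_components(tf, sc, erp=erp)
        assert len(cands) == 17 * 8 == 136

    def test_bilinear_expansion_completeness(self):
        """Summed candidate reconstructions equal the PCA+ICA-retained part
        of the data."""
        # noiseless low-rank data so the ICA-retained subspace is the whole
        # score space and the bilinear expansion is exactly complete
        rng = np.random.default_rng(11)
        tt = np.arange(250) * 4.0 - 200.0
        waves = np.stack([np.exp(-0.5 * ((tt - mu) / 45.0) ** 2)
                          for mu in (150.0, 290.0, 420.0)])
        maps = rng.normal(size=(3, 32))
        maps -= maps.mean(axis=1, keepdims=True)
        amps = rng.normal(0.0, 1.5, size=(12, 4, 3))
        data = np.einsum("sck,kx,kt->scxt", amps, maps, waves)
        erp = _erp_like(data)
        tf = temporal_pca_promax(erp, 3)
        Y = factor_scores_by_channel(tf)
        sc = spatial_infomax_ica(Y, 3, seed=0)
        cands = assemble_components(tf, sc, erp=erp)
        total = sum(c.reconstruction() for c in cands)
        S, Cd, C, T = data.shape
        retained = (tf.scores @ tf.loadings.T).reshape(S, Cd, C, T)
        assert np.abs(total - retained).max() < 1e-6 * np.abs(retained).max()

    def test_variance_audit(self):
        rng = np.random.default_rng(12)
        data, _, _ = _synthetic_erp(rng)
        erp = _erp_like(data)
        tf = temporal_pca_promax(erp, 3)
        sc = spatial_infomax_ica(factor_scores_by_channel(tf), 3, seed=0)
        cands = assemble_components(tf, sc, erp=erp)
        retained_share = 100.0 * float(tf.variance_fraction.sum())
        assert sum(c.variance_percent for c in cands) == \
            pytest.approx(retained_share, abs=0.5)

    def test_truth_components_selected_and_matched(self):
        rng = np.random.default_rng(13)
        data, waves, maps = _synthetic_erp(rng)
        erp = _erp_like(data)
        tf = temporal_pca_promax(erp, 3)
        sc = spatial_infomax_ica(factor_scores_by_channel(tf), 3, seed=0)
        selected = select_components(assemble_components(tf, sc, erp=erp), 0.5)
        for k in range(3):
            _, rt, rs = best_match(selected, waves[k], maps[k])
            assert rt > 0.95 and rs > 0.95

    def test_variance_floor_filtering(self):
        rng = np.random.default_rng(14)
        data, _, _ = _synthetic_erp(rng)
        erp = _erp_like(data)
        tf = temporal_pca_promax(erp, 4)
        sc = spatial_infomax_ica(factor_scores_by_channel(tf), 4, seed=0)
        cands = assemble_components(tf, sc, erp=erp)
        everything = select_components(cands, 0.0)
        assert len(everything) == len(cands)
        kept = select_components(cands, 0.5)
        assert {id(c) for c in kept} == \
            {id(c) for c in cands if c.variance_percent >= 0.5}
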