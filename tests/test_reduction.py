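import numpy as np
import pytest

from cognet.errors import RankError, ShapeError, ValidationError
from cognet.reduction import (EigSpectrum, concat_group_pca, estimate_order_mdl,
                              reduce_subject)


def _lowrank(n_vox, n_t, rank, rng, noise=0.0):
    X = rng.normal(size=(n_vox, rank)) @ rng.normal(size=(rank, n_t))
    if noise:
        X = X + noise * rng.normal(size=(n_vox, n_t))
    return X


class TestSubjectReduction:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        X = _lowrank(200, 50, 3, rng)
        Xc = X - X.mean(axis=1, keepdims=True)
        reduced, V = reduce_subject(X, 3)
        np.testing.assert_allclose(reduced @ V.T, Xc, atol=1e-8 * np.abs(Xc).max())

    def test_full_rank_is_lossless(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 20))
        Xc = X - X.mean(axis=1, keepdims=True)
        # per-voxel centering costs one temporal dimension: rank is T - 1
        reduced, V = reduce_subject(X, 19)
        np.testing.assert_allclose(reduced @ V.T, Xc, atol=1e-10)

    def test_variance_retained_matches_eigen_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 30))
        Xc = X - X.mean(axis=1, keepdims=True)
        # independent oracle: dense eigendecomposition of the temporal covariance
        ev = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        for k in (1, 5, 12):
            reduced, _ = reduce_subject(X, k)
            assert np.sum(reduced**2) == pytest.approx(ev[:k].sum(), rel=1e-10)

    def test_rank_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(RankError):
            reduce_subject(rng.normal(size=(50, 10)), 11)
        with pytest.raises(RankError):
            reduce_subject(_lowrank(50, 10, 2, rng), 5)


class TestGroupPCA:
    def test_noise_free_signal_captured(self, clean_cohort):
        mats = [reduce_subject(b, 6)[0] for b in clean_cohort.bolds[:5]]
        red = concat_group_pca(mats, 6)
        ev = red.spectrum.eigenvalues
        assert ev[:6].sum() / ev.sum() >= 0.99

    def test_whitened_rows_standardised_and_transform_identity(self, clean_whitened):
        Z = clean_whitened.whitened
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(clean_whitened.whitening @ clean_whitened.dewhitening,
                                   np.eye(clean_whitened.k), atol=1e-8)

    def test_single_subject_equals_subject_pca(self):
        rng = np.random.default_rng(4)
        X = _lowrank(150, 40, 5, rng, noise=0.1)
        reduced, _ = reduce_subject(X, 8)
        red = concat_group_pca([reduced], 5)
        # oracle: direct SVD of the centred data
        Xc = X - X.mean(axis=1, keepdims=True)
        Xc = Xc - Xc.mean(axis=0, keepdims=True)
        u = np.linalg.svd(Xc, full_matrices=False)[0][:, :5]
        overlap = np.abs(u.T @ (red.whitened.T / np.sqrt(X.shape[0])))
        np.testing.assert_allclose(np.abs(np.linalg.det(overlap)), 1.0, atol=1e-6)

    def test_group_eigenvalues_match_pooled_covariance_oracle(self):
        rng = np.random.default_rng(5)
        mats = [rng.normal(size=(60, 7)) for _ in range(3)]
        red = concat_group_pca(mats, 4)
        G = np.concatenate(mats, axis=1)
        G = G - G.mean(axis=0, keepdims=True)
        ev_oracle = np.sort(np.linalg.eigvalsh(G.T @ G / 60))[::-1]
        np.testing.assert_allclose(red.spectrum.eigenvalues, ev_oracle, atol=1e-10)

    def test_two_stage_agrees_with_direct_pca_on_low_rank(self):
        rng = np.random.default_rng(6)
        M = rng.normal(size=(5, 300))               # shared spatial sources
        subs = [M.T @ np.diag(rng.uniform(1, 2, 5)) @ rng.normal(size=(5, 40))
                for _ in range(4)]
        mats = [reduce_subject(s, 5)[0] for s in subs]
        red = concat_group_pca(mats, 5)
        G = np.concatenate([s - s.mean(axis=1, keepdims=True) for s in subs], axis=1)
        G = G - G.mean(axis=0, keepdims=True)
        u_direct = np.linalg.svd(G, full_matrices=False)[0][:, :5]
        u_two = red.whitened.T / np.sqrt(300)
        # principal angles between the two 5-D subspaces
        s = np.linalg.svd(u_direct.T @ u_two, compute_uv=False)
        angles = np.arccos(np.clip(s, -1, 1))
        assert angles.max() < 1e-6

    def test_shape_errors(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ShapeError):
            concat_group_pca([rng.normal(size=(50, 5)), rng.normal(size=(40, 5))], 3)
        with pytest.raises(RankError):
            concat_group_pca([rng.normal(size=(50, 3))], 10)


class TestMDL:
    @staticmethod
    def _mdl_oracle(ev, n):
        """Independent direct evaluation of the description-length formula."""
        p = len(ev)
        out = []
        for k in range(p):
            tail = ev[k:]
            gm = np.exp(np.mean(np.log(tail)))
            am = np.mean(tail)
            out.append(-(p - k) * n * np.log(gm / am)
                       + 0.5 * k * (2 * p - k + 1) * np.log(n))
        return np.asarray(out)

    @pytest.mark.parametrize("k_true", [2, 4, 8])
    def test_rank_recovery_and_oracle_argmin(self, k_true):
        rng = np.random.default_rng(k_true)
        p, n = 30, 10_000
        A = rng.normal(size=(p, k_true)) * np.sqrt(10)
        X = A @ rng.normal(size=(k_true, n)) + rng.normal(size=(p, n))
        ev = np.sort(np.linalg.eigvalsh(X @ X.T / n))[::-1]
        spec = EigSpectrum(ev, n)
        k_hat = estimate_order_mdl(spec)
        assert k_hat == k_true
        assert k_hat == int(np.argmin(self._mdl_oracle(ev, n)))

    def test_white_noise_gives_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 20_000))
        ev = np.sort(np.linalg.eigvalsh(X @ X.T / 20_000))[::-1]
        assert estimate_order_mdl(EigSpectrum(ev, 20_000)) == 0

    def test_flat_spectrum_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert estimate_order_mdl(EigSpectrum(np.ones(10), 1000)) == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        ev = np.sort(rng.uniform(0.5, 10, 15))[::-1]
        a = estimate_order_mdl(EigSpectrum(ev, 5000))
        b = estimate_order_mdl(EigSpectrum(ev * 1e6, 5000))
        assert a == b

    def test_spectrum_contract(self):
        with pytest.raises(ValidationError):
            EigSpectrum(np.array([1.0, 2.0, 0.5]), 100)       # not descending
        with pytest.raises(ValidationError):
            estimate_order_mdl(EigSpectrum(np.array([3.0, 2.0, 1.0]), 2))
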