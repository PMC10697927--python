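"""PCA reduction, whitening, non-negative ICA and NMF, with independent oracles."""

import numpy as np
import pytest

from nmfidif import DynamicImage
from nmfidif.unmix import (
    RankDeficiencyError,
    VoxelTacMatrix,
    build_voxel_matrix,
    nmf,
    nonneg_ica,
    pca_reduce,
    unmix_voi,
    whiten,
)

FRAMING4 = np.array([[0, 10], [10, 10], [20, 10], [30, 10]], float)


def _zmat(Z, framing=None):
    Z = np.asarray(Z, float)
    if framing is None:
        framing = np.column_stack(
            [np.arange(Z.shape[0]) * 10.0, np.full(Z.shape[0], 10.0)]
        )
    idx = np.column_stack([np.arange(Z.shape[1])] * 3)
    return VoxelTacMatrix(Z=Z, voxel_indices=idx, framing=framing)


class TestBuildVoxelMatrix:
    def test_columns_are_voxel_tacs(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[1, 0, 0] = [4, 5, 6]
        img = DynamicImage(data, (1, 1, 1), [[0, 10], [10, 10], [20, 10]])
        mask = np.ones((2, 1, 1), bool)
        Z = build_voxel_matrix(img, mask)
        assert Z.Z.shape == (3, 2)
        assert np.array_equal(Z.Z[:, 0], [1, 2, 3])
        assert np.array_equal(Z.Z[:, 1], [4, 5, 6])

    def test_all_zero_image_gives_zero_matrix(self):
        img = DynamicImage(np.zeros((3, 3, 3, 2)), (1, 1, 1), [[0, 10], [10, 10]])
        Z = build_voxel_matrix(img, np.ones((3, 3, 3), bool))
        assert np.all(Z.Z == 0)

    def test_negatives_clipped_and_recorded(self):
        data = np.full((1, 1, 1, 2), -0.5)
        img = DynamicImage(data, (1, 1, 1), [[0, 10], [10, 10]])
        Z = build_voxel_matrix(img, np.ones((1, 1, 1), bool))
        assert np.all(Z.Z == 0)
        assert Z.clipped_mass == pytest.approx(1.0)

    def test_phantom_columns_equal_region_truth(self, clean_phantom, clean_Z, voxel_region_labels):
        _, truth = clean_phantom
        for j in range(clean_Z.n_voxels):
            if voxel_region_labels[j]:
                expected = truth.region_tacs[voxel_region_labels[j]].values
                np.testing.assert_allclose(clean_Z.Z[:, j], expected, rtol=1e-12)
            else:  # background voxels inside the VOI carry no activity
                assert np.all(clean_Z.Z[:, j] == 0)

    def test_wrong_mask_shape_rejected(self):
        img = DynamicImage(np.zeros((3, 3, 3, 1)), (1, 1, 1), [[0, 10]])
        with pytest.raises(ValueError, match="shape"):
            build_voxel_matrix(img, np.ones((2, 2, 2), bool))


class TestPcaReduce:
    def test_exact_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        G = rng.uniform(0, 1, (6, 2))
        H = rng.uniform(0, 1, (2, 40))
        Z = _zmat(G @ H)
        pca = pca_reduce(Z, 2)
        assert np.linalg.norm(Z.Z - pca.B @ pca.x) < 1e-8
        assert np.allclose(pca.B.T @ pca.B, np.eye(2), atol=1e-10)

    def test_leading_direction_matches_sklearn(self):
        """n=1 on anisotropic data spans the dominant principal axis."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(1)
        direction = np.array([3.0, 1.0, 0.5, 0.2])
        X = np.abs(np.outer(direction, rng.normal(2, 1, 200)) + rng.normal(0, 0.05, (4, 200)))
        Z = _zmat(X, FRAMING4)
        pca = pca_reduce(Z, 1)
        ref = sklearn.PCA(n_components=1).fit(X.T).components_[0]
        cosine = abs(np.dot(pca.B[:, 0], ref))
        assert cosine > 0.999

    def test_eigenvalues_non_increasing(self, clean_Z):
        pca = pca_reduce(clean_Z, 3)
        assert np.all(np.diff(pca.eigenvalues) <= 1e-9)

    def test_rank_exceeded_raises(self):
        rng = np.random.default_rng(2)
        Z = _zmat(np.outer(rng.uniform(1, 2, 4), rng.uniform(1, 2, 30)), FRAMING4)
        with pytest.raises(RankDeficiencyError):
            pca_reduce(Z, 2)


class TestWhiten:
    def test_already_white_data_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 20000))
        res = whiten(x)
        assert np.allclose(res.M, np.eye(2), atol=0.05)
        assert np.allclose(res.z, x, atol=0.2)

    def test_diagonal_covariance_closed_form(self):
        rng = np.random.default_rng(4)
        x = np.vstack([2.0 * rng.standard_normal(200000), rng.standard_normal(200000)])
        res = whiten(x)
        assert np.allclose(res.M, np.diag([0.5, 1.0]), atol=0.01)

    def test_output_covariance_is_identity(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 5, (4, 300)) * np.array([[10, 3, 1, 0.3]]).T
        res = whiten(x)
        assert np.allclose(np.cov(res.z), np.eye(4), atol=1e-6)
        assert np.allclose(res.M @ res.M_inv, np.eye(4), atol=1e-8)

    def test_near_singular_covariance_raises(self):
        x = np.vstack([np.arange(50.0), 2 * np.arange(50.0)])
        with pytest.raises(RankDeficiencyError, match="smaller n"):
            whiten(x)


def _whitened_mixture(sources, seed):
    """Mix non-negative sources with a random rotation and whiten."""
    rng = np.random.default_rng(seed)
    n = sources.shape[0]
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    x = Q @ sources
    return whiten(x).z


class TestNonnegIca:
    def test_separated_sources_reach_zero_objective(self):
        # non-negative unit-variance sources, already separated: the
        # rotation search must find a (signed-)permutation with J ~ 0
        rng = np.random.default_rng(6)
        s = rng.exponential(1.0, (2, 40000))
        s /= s.std(axis=1, keepdims=True)
        res = nonneg_ica(s, seed=0, tol=1e-14)
        assert res.objective_history[-1] < 1e-8
        assert np.allclose(res.W @ res.W.T, np.eye(2), atol=1e-8)
        # recovered demixing is a signed permutation of the identity
        assert np.allclose(np.abs(res.W) @ np.abs(res.W.T), np.eye(2), atol=1e-3)

    def test_recovers_rotated_sources(self):
        """Well-grounded uncorrelated sources mixed by a rotation are
        recovered up to permutation and scale (r > 0.99)."""
        rng = np.random.default_rng(7)
        s = rng.exponential(1.0, (2, 6000))
        s[0, rng.uniform(size=6000) < 0.3] = 0.0  # strengthen grounding
        s[1, rng.uniform(size=6000) < 0.3] = 0.0
        z = _whitened_mixture(s, seed=8)
        res = nonneg_ica(z, seed=0)
        assert res.objective_history[-1] < 1e-6
        corr = np.abs(np.corrcoef(res.y, s)[:2, 2:])
        # best assignment by exhaustive permutation
        assert max(corr[0, 0] * corr[1, 1], corr[0, 1] * corr[1, 0]) > 0.99**2

    def test_objective_history_non_increasing(self):
        rng = np.random.default_rng(9)
        s = rng.exponential(1.0, (3, 2000))
        z = _whitened_mixture(s, seed=10)
        res = nonneg_ica(z, seed=1)
        assert np.all(np.diff(res.objective_history) <= 0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(11)
        z = _whitened_mixture(rng.exponential(1.0, (2, 1000)), seed=12)
        a = nonneg_ica(z, seed=5)
        b = nonneg_ica(z, seed=5)
        assert np.array_equal(a.W, b.W)

    def test_unwhitened_input_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="whitened"):
            nonneg_ica(5.0 * rng.standard_normal((2, 500)), seed=0)


class TestNmf:
    def test_exact_factorization_is_fixed_point(self):
        rng = np.random.default_rng(14)
        G = rng.uniform(0.1, 1, (6, 2))
        H = rng.uniform(0.1, 1, (2, 30))
        Z = _zmat(G @ H)
        res = nmf(Z, G, H, max_iter=50)
        assert res.error_history[-1] < 1e-10
        np.testing.assert_allclose(res.G, G, rtol=1e-6)
        np.testing.assert_allclose(res.H, H, rtol=1e-6)

    def test_error_history_non_increasing(self):
        rng = np.random.default_rng(15)
        Z = _zmat(rng.uniform(0, 10, (8, 50)),
                  np.column_stack([np.arange(8) * 10.0, np.full(8, 10.0)]))
        res = nmf(Z, rng.uniform(0.1, 1, (8, 3)), rng.uniform(0.1, 1, (3, 50)))
        assert np.all(np.diff(res.error_history) <= 1e-9 * res.error_history[0])

    def test_zero_initializer_component_rejected(self):
        Z = _zmat(np.ones((4, 5)), FRAMING4)
        G0 = np.ones((4, 2))
        G0[:, 1] = 0.0
        with pytest.raises(ValueError, match="zero"):
            nmf(Z, G0, np.ones((2, 5)))

    def test_matches_sklearn_multiplicative_updates(self):
        """Independent cross-check: scikit-learn's NMF with the same
        'mu' updates and the same custom init reaches the same error."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(16)
        Zarr = rng.uniform(0, 5, (10, 40))
        G0 = rng.uniform(0.1, 1, (10, 3))
        H0 = rng.uniform(0.1, 1, (3, 40))
        framing = np.column_stack([np.arange(10) * 10.0, np.full(10, 10.0)])
        ours = nmf(_zmat(Zarr, framing), G0, H0, max_iter=300, tol=0.0)
        model = sklearn.NMF(
            n_components=3, init="custom", solver="mu", beta_loss="frobenius",
            max_iter=300, tol=0.0,
        )
        W = model.fit_transform(Zarr, W=G0.copy(), H=H0.copy())
        theirs = np.linalg.norm(Zarr - W @ model.components_)
        assert ours.error_history[-1] == pytest.approx(theirs, rel=1e-3)


class TestFullPipeline:
    def test_noiseless_phantom_components_recovered(self, clean_phantom, clean_Z):
        """The nnICA-initialized NMF separates the three heart tissues."""
        _, truth = clean_phantom
        decomp, ica = unmix_voi(clean_Z, 3, seed=0)
        assert np.all(decomp.G >= 0) and np.all(decomp.H >= 0)
        # every true region TAC is matched by some G column
        for name in ("RV", "LV", "MYO"):
            best = max(
                np.corrcoef(decomp.G[:, i], truth.region_tacs[name].values)[0, 1]
                for i in range(3)
            )
            assert best > 0.99, name

    def test_reconstruction_error_small_on_noiseless_data(self, clean_Z):
        """At the true model order the factorization is near-exact; below
        it, the error approaches the unconstrained low-rank optimum."""
        decomp3, _ = unmix_voi(clean_Z, 3, seed=0)
        assert decomp3.error_history[-1] / np.linalg.norm(clean_Z.Z) < 0.05
        decomp2, _ = unmix_voi(clean_Z, 2, seed=0)
        svals = np.linalg.svd(clean_Z.Z, compute_uv=False)
        best_rank2 = np.sqrt(np.sum(svals[2:] ** 2))  # Eckart-Young bound
        assert decomp2.error_history[-1] < 1.5 * best_rank2

    def test_matches_least_squares_oracle_given_true_masks(
        self, clean_phantom, clean_Z, voxel_region_labels
    ):
        """On separable data the pipeline agrees with direct least-squares
        unmixing that is told the true voxel memberships."""
        _, truth = clean_phantom
        # oracle: per-region mean TACs from the true masks
        oracle = {
            name: clean_Z.Z[:, voxel_region_labels == name].mean(axis=1)
            for name in ("RV", "LV", "MYO")
        }
        decomp, _ = unmix_voi(clean_Z, 3, seed=0)
        for name, ref in oracle.items():
            best = max(
                np.corrcoef(decomp.G[:, i], ref)[0, 1] for i in range(3)
            )
            assert best > 0.99

    def test_deterministic_under_fixed_seed(self, clean_Z):
        a, _ = unmix_voi(clean_Z, 3, seed=42)
        b, _ = unmix_voi(clean_Z, 3, seed=42)
        assert np.array_equal(a.G, b.G)
        assert np.array_equal(a.H, b.H)
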