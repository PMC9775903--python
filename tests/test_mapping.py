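"""PCA reduction and ROMP sparse regression."""

from __future__ import annotations

import numpy as np
import pytest

from voxenc.mapping import (
    DesignMatrix,
    FitConfig,
    fit_voxelwise,
    pca_fit,
    pca_transform,
    predict,
    romp_fit,
)


class TestPCA:
    def test_tall_full_rank_keeps_m_minus_1(self, rng):
        F = rng.standard_normal((12, 200))
        assert pca_fit(F).k == 11

    def test_identical_rows_are_rank_deficient(self):
        F = np.ones((2, 5))
        with pytest.warns(UserWarning):
            model = pca_fit(F)
        assert model.k == 0

    def test_reconstruction_from_all_components(self, rng):
        F = rng.standard_normal((10, 50))
        model = pca_fit(F)
        Z = pca_transform(model, F)
        rec = Z.X @ model.components.T + model.mean
        assert np.abs(rec - F).max() < 1e-8

    def test_components_are_orthonormal(self, rng):
        model = pca_fit(rng.standard_normal((15, 40)))
        eye = model.components.T @ model.components
        assert np.abs(eye - np.eye(model.k)).max() < 1e-8

    def test_transform_of_mean_is_zero(self, rng):
        F = rng.standard_normal((8, 20))
        model = pca_fit(F)
        z = pca_transform(model, F.mean(axis=0, keepdims=True).repeat(2, axis=0))
        assert np.abs(z.X).max() < 1e-10

    def test_transform_shape_is_m_by_m_minus_1(self, rng):
        F = rng.standard_normal((10, 30))
        assert pca_transform(pca_fit(F), F).X.shape == (10, 9)

    def test_training_variance_matches_explained(self, rng):
        F = rng.standard_normal((20, 35))
        model = pca_fit(F)
        Z = pca_transform(model, F)
        assert np.abs(Z.X.var(axis=0, ddof=1) - model.explained_variance).max() < 1e-8

    def test_full_rank_transform_preserves_distances(self, rng):
        F = rng.standard_normal((9, 40))
        Z = pca_transform(pca_fit(F), F).X
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(F), pdist(Z), atol=1e-8)

    def test_width_mismatch_rejected(self, rng):
        model = pca_fit(rng.standard_normal((5, 10)))
        with pytest.raises(ValueError, match="width"):
            pca_transform(model, rng.standard_normal((3, 11)))


class TestROMP:
    def test_zero_response_gives_empty_model(self, rng):
        X = rng.standard_normal((20, 10))
        mdl = romp_fit(X, np.zeros(20), FitConfig(sparsity=3))
        assert mdl.b == 0.0 and mdl.support.size == 0 and (mdl.w == 0).all()

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_recovery_on_orthonormal_designs(self, seed):
        """Noiseless 4-sparse targets on 64x64 orthonormal designs recover exactly."""
        r = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(r.standard_normal((64, 64)))
        w_true = np.zeros(64)
        sup = r.choice(64, 4, replace=False)
        w_true[sup] = r.uniform(0.5, 2.0, 4) * r.choice([-1, 1], 4)
        mdl = romp_fit(Q, Q @ w_true, FitConfig(sparsity=4))
        assert set(mdl.support) == set(sup)
        assert np.abs(mdl.w - w_true).max() <= 1e-10

    @pytest.mark.parametrize("seed", range(15))
    def test_residual_norms_never_increase(self, seed):
        r = np.random.default_rng(100 + seed)
        X = r.standard_normal((40, 60))
        y = r.standard_normal(40)
        mdl = romp_fit(X, y, FitConfig(sparsity=5, max_iter=20))
        rn = mdl.diagnostics["residual_norms"]
        assert all(rn[i + 1] <= rn[i] + 1e-10 for i in range(len(rn) - 1))

    def test_support_respects_2K_bound(self, rng):
        X = rng.standard_normal((40, 60))
        y = rng.standard_normal(40)
        cfg = FitConfig(sparsity=5, max_iter=30)
        mdl = romp_fit(X, y, cfg)
        assert mdl.support.size <= 2 * cfg.sparsity

    def test_sparsity_exceeding_features_rejected(self, rng):
        with pytest.raises(ValueError, match="sparsity"):
            romp_fit(rng.standard_normal((10, 3)), np.zeros(10), FitConfig(sparsity=4))

    def test_intercept_recovers_offset(self, rng):
        X = rng.standard_normal((50, 8))
        w = np.zeros(8)
        w[2] = 1.5
        y = X @ w + 7.0
        mdl = romp_fit(X, y, FitConfig(sparsity=1))
        assert mdl.b == pytest.approx(7.0, abs=1e-8)
        assert mdl.w[2] == pytest.approx(1.5, abs=1e-8)


class TestVoxelwise:
    def test_voxels_fit_independently_and_in_order(self, rng):
        X = rng.standard_normal((30, 10))
        W = np.zeros((10, 2))
        W[1, 0], W[4, 1] = 2.0, -1.0
        R = X @ W
        models = fit_voxelwise(X, R, FitConfig(sparsity=1))
        assert len(models) == 2
        assert models[0].support.tolist() == [1]
        assert models[1].support.tolist() == [4]

    def test_duplicate_voxel_columns_give_identical_models(self, rng):
        X = rng.standard_normal((25, 8))
        y = X[:, 3] * 2.0 + 0.5
        models = fit_voxelwise(X, np.stack([y, y], axis=1), FitConfig(sparsity=2))
        assert (models[0].w == models[1].w).all() and models[0].b == models[1].b

    def test_zero_variance_voxel_warns_not_fails(self, rng):
        X = rng.standard_normal((20, 5))
        R = np.column_stack([np.full(20, 3.0), X[:, 0]])
        with pytest.warns(UserWarning, match="zero variance"):
            models = fit_voxelwise(X, R, FitConfig(sparsity=1))
        assert (models[0].w == 0).all() and models[0].b == pytest.approx(3.0)

    def test_noiseless_training_residuals_below_tolerance(self, rng):
        X = rng.standard_normal((40, 12))
        W = np.zeros((12, 3))
        for j in range(3):
            W[rng.choice(12, 2, replace=False), j] = rng.uniform(0.5, 2, 2)
        R = X @ W + rng.uniform(-1, 1, 3)
        models = fit_voxelwise(X, R, FitConfig(sparsity=2))
        for j, mdl in enumerate(models):
            resid = R[:, j] - (X @ mdl.w + mdl.b)
            assert np.linalg.norm(resid) <= 1e-6 * np.linalg.norm(R[:, j])


class TestPredict:
    def test_zero_weight_model_predicts_intercept(self, rng):
        from voxenc.mapping import SparseLinearModel

        mdl = SparseLinearModel(np.zeros(4), 2.5, np.array([], dtype=int))
        out = predict([mdl], rng.standard_normal((6, 4)))
        assert (out == 2.5).all()

    def test_single_feature_arithmetic(self):
        from voxenc.mapping import SparseLinearModel

        mdl = SparseLinearModel(np.array([2.0]), 1.0, np.array([0]))
        out = predict([mdl], np.array([[0.0], [1.0], [2.0]]))
        assert out.ravel().tolist() == [1.0, 3.0, 5.0]

    def test_matches_per_row_dot_product(self, rng):
        from voxenc.mapping import SparseLinearModel

        models = [
            SparseLinearModel(w := rng.standard_normal(5), float(rng.standard_normal()),
                              np.flatnonzero(w))
            for _ in range(3)
        ]
        X = rng.standard_normal((7, 5))
        out = predict(models, X)
        for i in range(7):
            for j, mdl in enumerate(models):
                assert out[i, j] == pytest.approx(X[i] @ mdl.w + mdl.b)

    def test_width_mismatch_rejected(self, rng):
        from voxenc.mapping import SparseLinearModel

        mdl = SparseLinearModel(np.zeros(4), 0.0, np.array([], dtype=int))
        with pytest.raises(ValueError):
            predict([mdl], rng.standard_normal((3, 5)))


def test_design_matrix_validation():
    with pytest.raises(ValueError):
        DesignMatrix(np.ones((1, 3)))  # m >= 2
    with pytest.raises(ValueError):
        DesignMatrix(np.array([[np.inf, 0.0], [0.0, 1.0]]))
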