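"""Tests for the class-weighted RBF SVM."""

import numpy as np
import pytest

from fhrscreen.classifier import (ScalingTransform, SvmModel, class_weights,
                                  fit, grid_search, predict, rbf_gram,
                                  rbf_kernel)
from fhrscreen.errors import InvalidInputError


def separable_blobs(n_pos=10, n_neg=10, gap_sd=6.0, seed=0, dim=2):
    """Two Gaussian blobs whose centres sit ``gap_sd`` standard deviations
    apart: linearly separable with overwhelming probability."""
    r = np.random.default_rng(seed)
    X = np.vstack([
        r.normal(0.0, 1.0, size=(n_pos, dim)),
        r.normal(gap_sd, 1.0, size=(n_neg, dim)),
    ])
    y = np.array([1] * n_pos + [-1] * n_neg)
    return X, y


class TestRbfKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=10)
        assert rbf_kernel(x, x, gamma=2.0) == 1.0

    def test_hand_arithmetic(self):
        assert rbf_kernel([0.0], [1.0], gamma=2.0) == pytest.approx(
            np.exp(-2.0), abs=1e-12)

    def test_symmetry_and_range(self, rng):
        a, b = rng.normal(size=(2, 5))
        k = rbf_kernel(a, b, gamma=0.5)
        assert k == pytest.approx(rbf_kernel(b, a, gamma=0.5))
        assert 0 < k <= 1

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidInputError):
            rbf_kernel([0.0, 1.0], [0.0], gamma=1.0)

    def test_gram_matrix_positive_semidefinite(self, rng):
        X = rng.normal(size=(20, 4))
        K = rbf_gram(X, X, gamma=2.0)
        assert np.allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestScaling:
    def test_training_extremes_map_to_interval_ends(self, rng):
        X = rng.normal(size=(30, 3)) * 10
        sc = ScalingTransform.fit(X)
        Z = sc.transform(X)
        assert np.allclose(Z.min(axis=0), -1.0)
        assert np.allclose(Z.max(axis=0), 1.0)

    def test_degenerate_feature_maps_to_midpoint(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        sc = ScalingTransform.fit(X)
        Z = sc.transform(X)
        assert np.allclose(Z[:, 1], 0.0)

    def test_same_transform_for_new_data(self):
        X = np.array([[0.0], [10.0]])
        sc = ScalingTransform.fit(X)
        assert sc.transform([[5.0]])[0, 0] == pytest.approx(0.0)
        assert sc.transform([[20.0]])[0, 0] == pytest.approx(3.0)


class TestFit:
    def test_separable_toy_set_perfect_training_accuracy(self):
        X, y = separable_blobs(n_pos=10, n_neg=10)
        model = fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_dual_constraint_and_box_bounds(self):
        X, y = separable_blobs(n_pos=8, n_neg=16, gap_sd=3.0, seed=4)
        model = fit(X, y, C=4.0, gamma=2.0)
        assert abs(model.dual_coef.sum()) < 1e-6
        for coef, label in zip(model.dual_coef, model.support_labels):
            alpha = coef * label  # dual_coef stores alpha_i * d_i
            assert -1e-9 <= alpha <= model.C * model.weights[int(label)] + 1e-9

    def test_class_weight_ratio_is_inverse_cardinality(self):
        y = np.array([1] * 20 + [-1] * 40)
        w = class_weights(y)
        assert w[1] / w[-1] == pytest.approx(2.0)

    def test_duplicating_points_leaves_decision_unchanged(self, rng):
        X, y = separable_blobs(n_pos=10, n_neg=20, gap_sd=4.0, seed=7)
        m1 = fit(X, y)
        m2 = fit(np.vstack([X, X]), np.concatenate([y, y]))
        grid = rng.normal(2.0, 3.0, size=(40, 2))
        assert np.allclose(m1.decision_function(grid),
                           m2.decision_function(grid), atol=1e-2)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            fit(np.zeros((5, 2)), np.ones(5))

    def test_free_support_vectors_sit_on_margin(self):
        X, y = separable_blobs(n_pos=15, n_neg=15, gap_sd=3.0, seed=9)
        model = fit(X, y, C=4.0, gamma=0.5)
        f = model.decision_function(X)
        sv_idx = {tuple(np.round(sv, 9)): i
                  for i, sv in enumerate(model.support_vectors)}
        Z = model.scaling.transform(X)
        for j, z in enumerate(Z):
            i = sv_idx.get(tuple(np.round(z, 9)))
            if i is None:
                continue
            alpha = model.dual_coef[i] * model.support_labels[i]
            bound = model.C * model.weights[int(model.support_labels[i])]
            if 1e-6 < alpha < bound - 1e-6:
                assert abs(abs(f[j]) - 1.0) < 1e-2

    def test_weighting_helps_minority_sensitivity(self):
        # 1:2 imbalance with overlap: the weighted fit should recall the
        # minority class at least as well as the unweighted fit in most
        # replicates.
        better = 0
        for seed in range(20):
            X, y = separable_blobs(n_pos=10, n_neg=20, gap_sd=1.5, seed=seed)
            Xt, yt = separable_blobs(n_pos=50, n_neg=100, gap_sd=1.5,
                                     seed=1000 + seed)
            mw = fit(X, y, C=1.0, gamma=0.5, weighted=True)
            mu = fit(X, y, C=1.0, gamma=0.5, weighted=False)
            rec_w = np.mean(mw.predict(Xt[yt == 1]) == 1)
            rec_u = np.mean(mu.predict(Xt[yt == 1]) == 1)
            better += int(rec_w >= rec_u)
        assert better >= 11


class TestPredict:
    def test_labels_in_plus_minus_one(self, rng):
        X, y = separable_blobs()
        model = fit(X, y)
        out = predict(model, rng.normal(size=(50, 2)))
        assert set(np.unique(out)) <= {-1, 1}

    def test_training_labels_reproduced_on_separable_set(self):
        X, y = separable_blobs(n_pos=12, n_neg=8, seed=3)
        model = fit(X, y)
        assert np.array_equal(predict(model, X), y)


class TestPersistence:
    def test_round_trip_is_bit_identical(self, tmp_path, rng):
        X, y = separable_blobs(n_pos=10, n_neg=20, gap_sd=2.0, seed=5)
        model = fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        back = SvmModel.load(path)
        Xn = rng.normal(1.0, 4.0, size=(100, 2))
        f1 = model.decision_function(Xn)
        f2 = back.decision_function(Xn)
        assert np.array_equal(f1, f2)
        assert np.array_equal(model.predict(Xn), back.predict(Xn))


class TestGridSearch:
    def test_single_cell_grid_returned(self):
        X, y = separable_blobs()
        C, g, table = grid_search(X, y, C_grid=[4.0], gamma_grid=[2.0],
                                  n_folds=2, refine=False)
        assert (C, g) == (4.0, 2.0)
        assert len(table) == 1

    def test_planted_dominating_cell_recovered(self):
        X, y = separable_blobs(n_pos=12, n_neg=12, gap_sd=6.0, seed=8)
        # Only one cell can classify at all: a gamma so large that the
        # kernel collapses everywhere except the plant.
        C, g, _ = grid_search(X, y, C_grid=[1.0], gamma_grid=[0.5, 1e6],
                              n_folds=3, refine=False)
        assert g == 0.5

    def test_operating_point_representable_after_refinement(self):
        X, y = separable_blobs(n_pos=15, n_neg=30, gap_sd=4.0, seed=2)
        _, _, table = grid_search(X, y, C_grid=[2.0 ** e for e in (1, 3)],
                                  gamma_grid=[2.0 ** e for e in (-1, 1)],
                                  n_folds=3)
        cells = {(round(c, 6), round(g, 6)) for c, g, _ in table}
        assert (4.0, 2.0) in cells

    def test_empty_grid_rejected(self):
        X, y = separable_blobs()
        with pytest.raises(InvalidInputError):
            grid_search(X, y, C_grid=[], gamma_grid=[1.0])
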