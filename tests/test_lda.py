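"""LDA training/prediction, class remapping and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emgrasp.classes import (ALL_POSTURES, GRASPS, HAND_CLOSE, HAND_OPEN,
                             MAINTENANCE_CLASSES, NO_MOVEMENT, ClassSet,
                             remap_maintenance)
from emgrasp.lda import (assign_folds, classification_error, decision_scores,
                         predict, predict_batch, train_lda, two_fold_cv)


class TestClassSets:
    def test_selection_class_count_is_n_plus_2(self):
        for n in (2, 4, 6):
            assert len(ClassSet.most_used(n).selection_classes) == n + 2

    def test_most_used_subsets_nest(self):
        assert ClassSet.most_used(2).grasps == ("chuck", "fine_pinch")
        assert ClassSet.most_used(4).grasps == ("chuck", "fine_pinch", "key", "power")

    def test_remap_examples(self):
        assert remap_maintenance(["chuck", "key", HAND_OPEN]) == [
            HAND_CLOSE, HAND_CLOSE, HAND_OPEN]
        assert remap_maintenance([NO_MOVEMENT]) == [NO_MOVEMENT]
        assert set(remap_maintenance(ALL_POSTURES)) == set(MAINTENANCE_CLASSES)

    def test_remap_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown class label"):
            remap_maintenance(["fist_bump"])


class TestTrainPredict:
    def test_separated_gaussians_held_out_error_below_1pct(self):
        gen = np.random.default_rng(0)
        Xtr = np.vstack([gen.normal((0, 0), 0.5, (200, 2)),
                         gen.normal((10, 10), 0.5, (200, 2))])
        ytr = np.repeat(["lo", "hi"], 200)
        Xte = np.vstack([gen.normal((0, 0), 0.5, (200, 2)),
                         gen.normal((10, 10), 0.5, (200, 2))])
        model = train_lda(Xtr, ytr)
        err = classification_error(predict_batch(model, Xte), ytr)
        assert err < 1.0

    def test_class_means_predict_their_own_class(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = train_lda(X, y)
        for cls, mean in zip(model.classes, model.means):
            assert predict(model, mean) == cls

    def test_matches_gaussian_bayes_oracle(self, gaussian_blobs):
        """Predictions equal the argmax of explicit pooled-covariance
        Gaussian log-posteriors computed from scratch."""
        X, y = gaussian_blobs
        model = train_lda(X, y, shrinkage=0.0)
        # independent oracle: quadratic form per class with the pooled cov
        classes = sorted(set(y))
        means = {c: X[y == c].mean(axis=0) for c in classes}
        pooled = sum((X[y == c] - means[c]).T @ (X[y == c] - means[c]) for c in classes)
        pooled /= len(y) - len(classes)
        inv = np.linalg.inv(pooled)
        logpost = np.stack([
            -0.5 * np.einsum("nd,dk,nk->n", X - means[c], inv, X - means[c])
            for c in model.classes
        ], axis=1)
        oracle = np.asarray(model.classes, dtype=object)[np.argmax(logpost, axis=1)]
        assert np.array_equal(predict_batch(model, X), oracle)

    def test_midpoint_tie_goes_to_earlier_listed_class(self):
        # power-of-two data keeps the discriminant scores exactly tied at
        # the midpoint of the two class means
        X = np.array([[-3.0], [-1.0], [1.0], [3.0]])
        y = np.array(["first", "first", "second", "second"])
        model = train_lda(X, y, shrinkage=0.0)
        scores = decision_scores(model, np.array([[0.0]]))
        assert scores[0, 0] == scores[0, 1]
        assert predict(model, np.array([0.0])) == "first"

    def test_agrees_with_nearest_mahalanobis_mean_on_spherical_data(self):
        gen = np.random.default_rng(4)
        means = np.array([[0.0, 0], [5, 0], [0, 5]])
        X = np.vstack([gen.normal(m, 1.0, (100, 2)) for m in means])
        y = np.repeat(["a", "b", "c"], 100)
        model = train_lda(X, y, shrinkage=0.0)
        inv = np.linalg.inv(model.covariance)
        d2 = np.stack([np.einsum("nd,dk,nk->n", X - m, inv, X - m)
                       for m in model.means], axis=1)
        nearest = np.asarray(model.classes, dtype=object)[np.argmin(d2, axis=1)]
        assert np.array_equal(predict_batch(model, X), nearest)

    def test_small_class_raises_naming_class(self):
        X = np.random.default_rng(5).standard_normal((5, 2))
        y = np.array(["a", "a", "a", "a", "rare"])
        with pytest.raises(ValueError, match="'rare'"):
            train_lda(X, y)

    def test_singular_covariance_without_shrinkage_advises(self):
        X = np.zeros((8, 3))
        X[:, 0] = np.arange(8)
        y = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        with pytest.raises(ValueError, match="shrinkage"):
            train_lda(X, y, shrinkage=0.0)

    def test_dimension_mismatch_raises(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = train_lda(X, y)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros(7))

    @given(seed=st.integers(0, 30))
    def test_shift_invariance(self, seed):
        """Decision boundaries are unchanged by adding a constant vector."""
        gen = np.random.default_rng(seed)
        X = np.vstack([gen.normal(0, 1, (30, 3)), gen.normal(2, 1, (30, 3))])
        y = np.repeat(["a", "b"], 30)
        shift = gen.normal(0, 10, 3)
        m1 = train_lda(X, y)
        m2 = train_lda(X + shift, y)
        assert np.array_equal(predict_batch(m1, X), predict_batch(m2, X + shift))

    def test_cross_check_against_sklearn(self, gaussian_blobs):
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = gaussian_blobs
        model = train_lda(X, y, shrinkage=0.0)
        ref = sklearn_lda.LinearDiscriminantAnalysis(
            priors=np.full(3, 1 / 3)).fit(X, y)
        agree = np.mean(predict_batch(model, X) == ref.predict(X))
        assert agree >= 0.99

    def test_maintenance_model_never_emits_grasp(self, gaussian_blobs):
        X, y = gaussian_blobs
        mapped = np.asarray(remap_maintenance(
            np.where(y == "a", "chuck", np.where(y == "b", "key", HAND_OPEN))), dtype=object)
        model = train_lda(X, mapped)
        preds = predict_batch(model, np.random.default_rng(0).standard_normal((500, 4)) * 5)
        assert set(preds) <= set(MAINTENANCE_CLASSES)


class TestErrorAndCv:
    @pytest.mark.parametrize("pred,truth,expected", [
        (list("aaaa"), list("aaaa"), 0.0),
        (list("aaaa"), list("bbbb"), 100.0),
        (list("aaabbbcccddd"), list("aaabbbcccxyz"), 25.0),
    ])
    def test_classification_error(self, pred, truth, expected):
        assert classification_error(pred, truth) == expected

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            classification_error([], [])

    def test_assign_folds_alternates(self):
        assert np.array_equal(assign_folds([1, 2, 3, 4]), [0, 1, 0, 1])

    def test_separable_classes_give_near_zero_error(self):
        gen = np.random.default_rng(6)
        X = np.vstack([gen.normal(8 * i, 0.3, (40, 2)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], 40)
        folds = np.tile([0, 1], 60)
        assert two_fold_cv(X, y, folds) < 1.0

    def test_fold_swap_symmetry(self, gaussian_blobs):
        X, y = gaussian_blobs
        folds = np.tile([0, 1], len(y) // 2)
        assert two_fold_cv(X, y, folds) == two_fold_cv(X, y, 1 - folds)

    def test_class_missing_from_one_fold_raises(self):
        X = np.random.default_rng(7).standard_normal((8, 2))
        y = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        folds = np.array([0, 1, 0, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="'b'"):
            two_fold_cv(X, y, folds)

    def test_error_decreases_with_class_separation(self):
        """Average CV error is non-increasing as class means move apart."""
        errs = []
        for sep in (0.5, 2.0, 6.0):
            per_seed = []
            for seed in range(5):
                gen = np.random.default_rng(seed)
                X = np.vstack([gen.normal(0, 1, (40, 2)),
                               gen.normal(sep, 1, (40, 2))])
                y = np.repeat(["a", "b"], 40)
                folds = np.tile([0, 1], 40)
                per_seed.append(two_fold_cv(X, y, folds))
            errs.append(np.mean(per_seed))
        assert errs[0] >= errs[1] >= errs[2]
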