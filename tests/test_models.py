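"""The five classifiers: planted-data oracles, contracts, determinism."""

import numpy as np
import pytest

import palmscreen as ps
from palmscreen import models as md
from palmscreen.models import ClassifierConfig


def two_clouds(rng, n=40, gap=8.0, d=3):
    """Well-separated Gaussian clouds; anemic cloud at the origin."""
    x0 = rng.normal(0.0, 1.0, size=(n, d))
    x1 = rng.normal(gap, 1.0, size=(n, d))
    x = np.vstack([x0, x1])
    y = np.array([1] * n + [0] * n)
    return x, y


class TestNaiveBayes:
    def test_separable_clouds_perfect_training_accuracy(self):
        x, y = two_clouds(np.random.default_rng(0))
        model = md.train_naive_bayes(x, y)
        pred, _ = model.predict(x)
        assert (md.encode_labels(pred) == y).all()

    def test_uninformative_features_score_near_prior(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 2))
        y = np.array([1] * 200 + [0] * 100)  # prior 2/3 anemic
        model = md.train_naive_bayes(x, y)
        scores = model.score(rng.normal(size=(200, 2)))
        assert abs(scores.mean() - 2 / 3) < 0.1

    def test_hand_computed_gaussian_example(self):
        """Class A {1, 2}, class B {10, 11}: the Gaussian likelihood of 1.5
        under A (mean 1.5) dominates its likelihood under B (mean 10.5)."""
        x = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array([1, 1, 0, 0])  # A = anemic
        model = md.train_naive_bayes(x, y)
        label, score = model.predict(np.array([[1.5]]))
        assert label[0] == ps.ANEMIC and score[0] > 0.99

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            md.train_naive_bayes(np.zeros((5, 2)), np.ones(5, dtype=int))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x, y = two_clouds(rng, n=25)
        perm = rng.permutation(len(x))
        q = rng.normal(3.0, 2.0, size=(50, 3))
        s1 = md.train_naive_bayes(x, y).score(q)
        s2 = md.train_naive_bayes(x[perm], y[perm]).score(q)
        assert np.allclose(s1, s2)

    def test_score_monotone_between_class_means_in_1d(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 1, (50, 1)), rng.normal(10, 1, (50, 1))])
        y = np.array([1] * 50 + [0] * 50)  # anemic mean < non-anemic mean
        model = md.train_naive_bayes(x, y)
        grid = np.linspace(0, 10, 41)[:, None]
        s = model.score(grid)
        assert (np.diff(s) <= 1e-12).all()


class TestKnn:
    def test_k1_at_a_training_point_scores_one(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([1, 0])
        model = md.train_knn(x, y, ClassifierConfig(knn_k=1, standardize=False))
        assert model.score(np.array([[0.0, 0.0]]))[0] == 1.0

    def test_k_equal_n_scores_global_fraction_everywhere(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 2))
        y = np.array([1] * 18 + [0] * 12)
        model = md.train_knn(x, y, ClassifierConfig(knn_k=30, standardize=False))
        scores = model.score(rng.normal(size=(10, 2)))
        assert np.allclose(scores, 18 / 30)

    def test_k_clamped_when_exceeding_train_size(self, caplog):
        import logging

        x, y = np.array([[0.0], [1.0], [9.0]]), np.array([1, 1, 0])
        with caplog.at_level(logging.WARNING):
            model = md.train_knn(x, y, ClassifierConfig(knn_k=100))
        assert "clamped" in caplog.text
        assert np.allclose(model.score(np.array([[5.0]])), 2 / 3)

    def test_planted_five_points_match_exhaustive_distance_sort(self):
        """Oracle: full distance sort by hand for k = 3."""
        x = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 1.0], [10.0, 10.0], [11.0, 9.0]])
        y = np.array([1, 1, 0, 0, 0])
        queries = np.array([[0.5, 0.2], [10.5, 9.5], [4.0, 3.0]])
        cfg = ClassifierConfig(knn_k=3, standardize=False)
        model = md.train_knn(x, y, cfg)
        for q in queries:
            d = np.linalg.norm(x - q, axis=1)
            expected = y[np.argsort(d, kind="stable")[:3]].mean()
            assert model.score(q[None, :])[0] == pytest.approx(expected)


class TestDecisionTree:
    @staticmethod
    def brute_force_best_split(x, y):
        """Exhaustive Gini search over all features and midpoint thresholds."""

        def gini(labels):
            if len(labels) == 0:
                return 0.0
            p = labels.mean()
            return 2 * p * (1 - p)

        best = (-1.0, None, None)
        n = len(y)
        for j in range(x.shape[1]):
            vals = np.unique(x[:, j])
            for t in (vals[:-1] + vals[1:]) / 2:
                left = y[x[:, j] <= t]
                right = y[x[:, j] > t]
                gain = gini(y) - (len(left) * gini(left) + len(right) * gini(right)) / n
                if gain > best[0]:
                    best = (gain, j, t)
        return best

    def test_first_split_matches_exhaustive_gini_search(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 2))
        y = (x[:, 0] + 0.3 * rng.normal(size=30) > 0).astype(int)
        cfg = ClassifierConfig(tree_min_leaf=1, tree_min_split=2)
        model = md.train_decision_tree(x, y, cfg)
        tree = model.estimator.tree_
        gain_star, j_star, t_star = self.brute_force_best_split(x, y)
        assert tree.feature[0] == j_star
        assert tree.threshold[0] == pytest.approx(t_star)

    def test_separable_1d_gives_depth_one_perfect_tree(self):
        x = np.linspace(0, 1, 20)[:, None]
        y = (x[:, 0] > 0.5).astype(int)
        cfg = ClassifierConfig(tree_min_leaf=1, tree_min_split=2)
        model = md.train_decision_tree(x, y, cfg)
        assert model.estimator.get_depth() == 1
        pred, _ = model.predict(x)
        assert (md.encode_labels(pred) == y).all()

    def test_min_leaf_constraint_limits_leaf_sizes(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 2))
        y = (rng.random(60) > 0.5).astype(int)
        model = md.train_decision_tree(x, y, ClassifierConfig(tree_min_leaf=10, tree_min_split=5))
        tree = model.estimator.tree_
        leaf_sizes = tree.n_node_samples[tree.children_left == -1]
        assert (leaf_sizes >= 10).all()

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        x, y = two_clouds(rng, n=20)
        perm = rng.permutation(len(x))
        q = rng.normal(4.0, 3.0, size=(30, 3))
        s1 = md.train_decision_tree(x, y).score(q)
        s2 = md.train_decision_tree(x[perm], y[perm]).score(q)
        assert np.allclose(s1, s2)

    def test_bagged_mode_trains_and_scores(self):
        x, y = two_clouds(np.random.default_rng(9), n=30)
        model = md.train_decision_tree(x, y, ClassifierConfig(tree_bagged=True, tree_min_leaf=1, tree_min_split=2))
        pred, _ = model.predict(x)
        assert (md.encode_labels(pred) == y).mean() > 0.9


class TestSvm:
    def test_separable_clouds_generalize(self):
        rng = np.random.default_rng(10)
        x, y = two_clouds(rng, n=60)
        xt, yt = two_clouds(rng, n=50)
        model = md.train_svm(x, y)
        pred, _ = model.predict(xt)
        assert (md.encode_labels(pred) == yt).mean() >= 0.95

    def test_degenerate_identical_points_score_half(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0]])
        y = np.array([1, 0])
        model = md.train_svm(x, y)
        assert model.score(np.array([[1.0, 1.0]]))[0] == pytest.approx(0.5, abs=0.05)

    def test_flipping_labels_negates_decision_function(self):
        rng = np.random.default_rng(11)
        x, y = two_clouds(rng, n=20, d=2)
        q = rng.normal(4.0, 3.0, size=(25, 2))
        # tight tolerance: antisymmetry holds for the exactly-solved dual
        cfg = ClassifierConfig(svm_max_iter=-1, svm_tolerance=1e-8)
        m1 = md.train_svm(x, y, cfg)
        m2 = md.train_svm(x, 1 - y, cfg)
        d1 = m1.estimator.decision_function(m1.scaler.transform(q))
        d2 = m2.estimator.decision_function(m2.scaler.transform(q))
        assert np.allclose(d1, -d2, atol=1e-6)

    def test_iteration_cap_flags_nonconvergence(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(400, 3))
        y = (rng.random(400) > 0.5).astype(int)  # pure noise: slow to converge
        model = md.train_svm(x, y, ClassifierConfig(svm_max_iter=2))
        assert model.converged is False


class TestCnn:
    @staticmethod
    def color_thumbnails(rng, n_per_class=25, size=32):
        """Reddish vs pale-green 32x32 blobs: a pure color-separable task."""
        reds = np.clip(rng.normal([180, 90, 90], 12, size=(n_per_class, size, size, 3)), 0, 255)
        pales = np.clip(rng.normal([150, 170, 130], 12, size=(n_per_class, size, size, 3)), 0, 255)
        x = np.concatenate([reds, pales]).astype(np.uint8)
        y = np.array([0] * n_per_class + [1] * n_per_class)
        return x, y

    def test_no_signal_loss_stays_near_ln2(self):
        x = np.zeros((40, 32, 32, 3), dtype=np.uint8)
        y = np.array([0, 1] * 20)
        model = md.train_cnn(x, y, ClassifierConfig(seed=0))
        history = model.estimator.fit(x, y, epochs=1)  # one more epoch, loss already flat
        assert abs(history[-1] - np.log(2)) < 0.05

    def test_color_separable_thumbnails_learned_within_ten_epochs(self):
        rng = np.random.default_rng(13)
        x, y = self.color_thumbnails(rng)
        model = md.train_cnn(x, y, ClassifierConfig(seed=1))
        pred, _ = model.predict(x)
        assert (md.encode_labels(pred) == y).mean() >= 0.9

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(14)
        x, y = self.color_thumbnails(rng, n_per_class=10)
        cfg = ClassifierConfig(seed=5, cnn_max_epochs=2)
        s1 = md.train_cnn(x, y, cfg).score(x)
        s2 = md.train_cnn(x, y, cfg).score(x)
        assert np.array_equal(s1, s2)


class TestPredictContract:
    def test_tie_score_maps_to_anemic(self):
        model = md.train_naive_bayes(np.array([[0.0], [1.0]]), np.array([1, 0]))
        labels = np.where(np.array([0.5]) >= 0.5, ps.ANEMIC, ps.NON_ANEMIC)
        assert labels[0] == ps.ANEMIC  # documented tie rule

    def test_batch_equals_elementwise(self):
        rng = np.random.default_rng(15)
        x, y = two_clouds(rng, n=15)
        q = rng.normal(4, 3, size=(10, 3))
        for kind in ("naive_bayes", "knn", "decision_tree", "svm"):
            model = md.train(kind, x, y)
            batch = model.score(q)
            single = np.array([model.score(qi[None, :])[0] for qi in q])
            assert np.allclose(batch, single)

    def test_shape_mismatch_rejected(self):
        model = md.train_naive_bayes(np.zeros((4, 3)), np.array([1, 1, 0, 0]))
        with pytest.raises(ValueError, match="expected"):
            model.score(np.zeros((2, 5)))

    def test_scores_always_in_unit_interval(self, small_cohort):
        records, images = small_cohort
        crops = [ps.crop_roi(i, ps.segment_palm(i)) for i in images]
        x = np.array([ps.compute_features(c).as_array() for c in crops])
        y = md.encode_labels([r.label for r in records])
        for kind in ("naive_bayes", "knn", "decision_tree", "svm"):
            s = md.train(kind, x, y).score(x)
            assert (s >= 0).all() and (s <= 1).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            md.train("forest", np.zeros((2, 1)), np.array([0, 1]))
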