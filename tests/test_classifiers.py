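"""The three pairwise classifiers and their analytic oracles."""

import numpy as np
import pytest

from bbbdetect import classifiers as clf


@pytest.fixture
def wlda_1d():
    """1-D two-class fit: class1 = {0, 2}, class2 = {4, 6}, unit weights.

    Means are (1, 5); the weighted pooled scatter is
    (0-1)^2 + (2-1)^2 + (4-5)^2 + (6-5)^2 = 4.
    """
    X = np.array([[0.0], [2.0], [4.0], [6.0]])
    y = np.array(["c1", "c1", "c2", "c2"])
    return clf.fit_wlda(X, y, w=(1.0, 1.0), labels=("c1", "c2"))


class TestCentroid:
    def test_single_point_classes(self):
        m = clf.fit_centroid([[0, 0], [2, 2]], ["A", "B"], labels=("A", "B"))
        assert np.allclose(m.centroids, [[0, 0], [2, 2]])

    def test_mean_of_class(self):
        m = clf.fit_centroid([[0, 0], [2, 0], [5, 5]], ["A", "A", "B"],
                             labels=("A", "B"))
        assert np.allclose(m.centroids[0], [1, 0])

    def test_nearest_centroid_1d(self):
        m = clf.CentroidModel(("NORM", "LBBB"), [[0.0], [2.0]])
        assert clf.predict_centroid(m, [0.9]) == "NORM"
        assert clf.predict_centroid(m, [1.1]) == "LBBB"

    def test_exact_tie_resolves_to_norm(self):
        m = clf.CentroidModel(("LBBB", "NORM"), [[0.0], [2.0]])
        assert clf.predict_centroid(m, [1.0]) == "NORM"

    def test_centroid_input_is_its_class(self):
        m = clf.CentroidModel(("NORM", "LBBB"), [[0.0, 1.0], [3.0, -1.0]])
        assert clf.predict_centroid(m, [0.0, 1.0]) == "NORM"

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            clf.fit_centroid([[0], [1]], ["A", "A"], labels=("A", "B"))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = np.array(["A", "B"] * 10)
        perm = rng.permutation(20)
        m1 = clf.fit_centroid(X, y, labels=("A", "B"))
        m2 = clf.fit_centroid(X[perm], y[perm], labels=("A", "B"))
        assert np.allclose(m1.centroids, m2.centroids)


class TestWLDA:
    def test_worked_example_sigma(self, wlda_1d):
        assert np.allclose(wlda_1d.means, [[1.0], [5.0]])
        assert np.allclose(wlda_1d.sigma, [[4.0]])

    def test_midpoint_posterior_is_half(self, wlda_1d):
        p = clf.wlda_posterior(wlda_1d, [3.0])
        assert np.allclose(p, [0.5, 0.5])

    def test_posterior_at_one(self, wlda_1d):
        # g1 - g2 = 2 by hand => P(c1) = 1 / (1 + e^-2)
        p = clf.wlda_posterior(wlda_1d, [1.0])
        assert p[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)
        assert p[0] == pytest.approx(0.8808, abs=5e-5)

    def test_posteriors_sum_to_one(self, wlda_1d):
        rng = np.random.default_rng(1)
        P = clf.wlda_posterior(wlda_1d, rng.standard_normal((500, 1)) * 50)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((P >= 0) & (P <= 1))

    def test_predict_mean_is_own_class(self, wlda_1d):
        assert clf.predict_wlda(wlda_1d, [1.0]) == "c1"
        assert clf.predict_wlda(wlda_1d, [5.0]) == "c2"

    def test_boundary_tie_resolves_to_norm(self):
        # symmetric means around 0 make the posterior at x = 0 exactly 0.5
        m = clf.WLDAModel(("LBBB", "NORM"), [[-1.0], [1.0]],
                          [[1.0]], [[1.0]], (1, 1))
        assert np.allclose(clf.wlda_posterior(m, [0.0]), [0.5, 0.5])
        assert clf.predict_wlda(m, [0.0]) == "NORM"

    def test_sigma_linear_in_weights(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = np.array(["a", "b"] * 15)
        m1 = clf.fit_wlda(X, y, w=(0.3, 0.7), labels=("a", "b"))
        m2 = clf.fit_wlda(X, y, w=(3.0, 7.0), labels=("a", "b"))
        assert np.allclose(m2.sigma, 10 * m1.sigma)

    def test_prediction_invariant_to_uniform_weight_scaling(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((25, 5)),
                       rng.standard_normal((25, 5)) + 1.5])
        y = np.array(["a"] * 25 + ["b"] * 25)
        Xt = rng.standard_normal((200, 5)) * 3
        base = clf.predict_wlda(clf.fit_wlda(X, y, (0.05, 0.4), labels=("a", "b")), Xt)
        for scale in (0.01, 1.0, 37.5):
            m = clf.fit_wlda(X, y, (0.05 * scale, 0.4 * scale), labels=("a", "b"))
            assert np.array_equal(clf.predict_wlda(m, Xt), base)

    def test_identity_sigma_equals_centroid_rule(self):
        # with Sigma = I and equal priors the discriminant reduces to
        # -1/2 ||x - m_i||^2 + const: nearest-centroid classification
        rng = np.random.default_rng(4)
        means = rng.standard_normal((2, 6))
        eye = np.eye(6)
        wm = clf.WLDAModel(("NORM", "RBBB"), means, eye, eye, (1, 1))
        cm = clf.CentroidModel(("NORM", "RBBB"), means)
        X = rng.standard_normal((1000, 6)) * 2
        assert np.array_equal(clf.predict_wlda(wm, X), clf.predict_centroid(cm, X))

    def test_degenerate_scatter_triggers_ridge(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        y = np.array(["a", "a", "b", "b"])
        m = clf.fit_wlda(X, y, (1, 1), labels=("a", "b"))
        assert m.ridge_eps > 0
        assert np.all(np.isfinite(m.sigma_inv))

    def test_ridge_disabled_raises(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(np.linalg.LinAlgError):
            clf.fit_wlda(X, y, (1, 1), labels=("a", "b"), ridge=False)

    def test_non_finite_input_rejected(self, wlda_1d):
        with pytest.raises(ValueError, match="finite"):
            clf.wlda_posterior(wlda_1d, [np.nan])


class TestLinearSVM:
    def test_max_margin_midpoint_1d(self):
        m = clf.fit_linear_svm([[-1.0], [1.0]], ["a", "b"], C=1000.0,
                               labels=("a", "b"))
        boundary = -m.bias / m.weight_vector[0]
        assert boundary == pytest.approx(0.0, abs=1e-3)
        assert clf.predict_svm(m, [-1.0]) == "a"
        assert clf.predict_svm(m, [1.0]) == "b"

    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.standard_normal((40, 2)),
                       rng.standard_normal((40, 2)) + 6])
        y = np.array(["a"] * 40 + ["b"] * 40)
        m = clf.fit_linear_svm(X, y, C=1.0, labels=("a", "b"))
        assert np.all(clf.predict_svm(m, X) == y)

    def test_label_swap_mirrors_predictions(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.standard_normal((30, 3)),
                       rng.standard_normal((30, 3)) + 2])
        y1 = np.array(["a"] * 30 + ["b"] * 30)
        y2 = np.where(y1 == "a", "b", "a")
        Xt = rng.standard_normal((50, 3))
        p1 = clf.predict_svm(clf.fit_linear_svm(X, y1, C=1.0), Xt)
        p2 = clf.predict_svm(clf.fit_linear_svm(X, y2, C=1.0), Xt)
        assert np.array_equal(np.where(p1 == "a", "b", "a"), p2)

    def test_decision_matches_brute_force(self):
        m = clf.LinearSVMModel(("a", "b"), [2.0, -1.0, 0.5], -0.25, 1.0)
        rng = np.random.default_rng(7)
        for x in rng.standard_normal((10, 3)):
            by_hand = sum(w * xi for w, xi in zip([2.0, -1.0, 0.5], x)) - 0.25
            expected = "b" if by_hand > 0 else "a"
            assert clf.predict_svm(m, x) == expected

    def test_zero_decision_tie_rule(self):
        m = clf.LinearSVMModel(("LBBB", "RBBB"), [1.0], 0.0, 1.0)
        assert clf.predict_svm(m, [0.0]) == "LBBB"  # no NORM: first label
        m2 = clf.LinearSVMModel(("NORM", "LBBB"), [1.0], 0.0, 1.0)
        assert clf.predict_svm(m2, [0.0]) == "NORM"

    def test_deterministic_fit(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 4))
        y = np.array(["a", "b"] * 30)
        m1 = clf.fit_linear_svm(X, y, C=0.5)
        m2 = clf.fit_linear_svm(X, y, C=0.5)
        assert np.array_equal(m1.weight_vector, m2.weight_vector)
        assert m1.bias == m2.bias


@pytest.mark.parametrize("builder", [
    lambda: clf.CentroidModel(("NORM", "LBBB"), np.random.default_rng(0).standard_normal((2, 7))),
    lambda: clf.fit_wlda(np.random.default_rng(1).standard_normal((20, 3)),
                         np.array(["NORM", "RBBB"] * 10), (0.03, 0.6),
                         labels=("NORM", "RBBB")),
    lambda: clf.fit_linear_svm(np.vstack([np.zeros((5, 2)), np.ones((5, 2))]),
                               ["LBBB"] * 5 + ["RBBB"] * 5, C=0.1),
], ids=["centroid", "wlda", "svm"])
def test_serialization_round_trip(tmp_path, builder):
    model = builder()
    path = str(tmp_path / "model.json")
    clf.save_model(model, path)
    back = clf.load_model(path)
    assert type(back) is type(model)
    x = np.random.default_rng(2).standard_normal(
        model.centroids.shape[1] if isinstance(model, clf.CentroidModel)
        else model.means.shape[1] if isinstance(model, clf.WLDAModel)
        else model.weight_vector.shape[0])
    for pred in (clf.predict_centroid if isinstance(model, clf.CentroidModel)
                 else clf.predict_wlda if isinstance(model, clf.WLDAModel)
                 else clf.predict_svm,):
        assert pred(back, x) == pred(model, x)
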