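"""Normalization, the minimum-distance classifier, and the family adapters."""

import numpy as np
import pytest

from anurascore.frame_classifiers import (FAMILIES, ClassifierSpec,
                                          FrameClassifier, ScoreSeries,
                                          apply_normalizer, centroid_distances,
                                          classify_frames, fit_normalizer,
                                          min_distance_predict,
                                          min_distance_train)


class TestNormalizer:
    def test_standardized_input_yields_identity_stats(self, rng):
        x = rng.standard_normal((5000, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        norm = fit_normalizer(x)
        assert np.allclose(norm.mu, 0.0, atol=1e-12)
        assert np.allclose(norm.sigma, 1.0, atol=1e-12)

    def test_two_point_feature(self):
        norm = fit_normalizer(np.array([[1.0], [3.0]]))
        assert norm.mu[0] == pytest.approx(2.0)
        # population standard deviation: sqrt(((1-2)^2 + (3-2)^2)/2) = 1
        assert norm.sigma[0] == pytest.approx(1.0)

    def test_matches_brute_force_column_stats(self, rng):
        x = rng.standard_normal((200, 13)) * 3 + 1
        norm = fit_normalizer(x)
        for j in range(13):
            col = x[:, j]
            assert norm.mu[j] == pytest.approx(sum(col) / 200, abs=1e-12)
            var = sum((v - norm.mu[j]) ** 2 for v in col) / 200
            assert norm.sigma[j] == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.empty((0, 13)))

    def test_apply_examples_and_self_normalization(self, rng):
        norm = fit_normalizer(np.array([[1.0], [5.0]]))  # mu 3, sigma 2
        assert apply_normalizer(np.array([[5.0]]), norm)[0, 0] == pytest.approx(1.0)
        assert apply_normalizer(np.array([[3.0]]), norm)[0, 0] == pytest.approx(0.0)
        x = rng.standard_normal((300, 4)) * 7 - 2
        z = apply_normalizer(x, fit_normalizer(x))
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        norm = fit_normalizer(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError):
            apply_normalizer(np.zeros((5, 4)), norm)


class TestMinimumDistance:
    def test_single_frame_per_class_centroids(self):
        x = np.array([[0.0, 1.0], [2.0, 3.0]])
        model = min_distance_train(x, np.array([0, 1]))
        assert np.array_equal(model.centroids, x)

    def test_two_frame_centroid(self):
        model = min_distance_train(np.array([[0.0, 0.0], [2.0, 2.0]]),
                                   np.array([1, 1]))
        assert np.allclose(model.centroids[0], [1.0, 1.0])

    def test_per_class_means_match_brute_force(self, rng):
        x = rng.standard_normal((120, 5))
        y = rng.integers(0, 4, 120)
        model = min_distance_train(x, y, classes=range(4))
        for k in range(4):
            assert np.allclose(model.centroids[k], x[y == k].mean(axis=0),
                               atol=1e-12)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            min_distance_train(np.zeros((3, 2)), np.array([0, 0, 1]),
                               classes=[0, 1, 2])

    def test_3_4_5_distance(self):
        model = min_distance_train(np.array([[3.0, 4.0]]), np.array([0]))
        d = centroid_distances(np.array([0.0, 0.0]), model)
        assert d[0, 0] == pytest.approx(5.0)

    def test_frame_on_centroid_is_assigned_there(self):
        model = min_distance_train(np.array([[0.0, 0.0], [5.0, 5.0]]),
                                   np.array([0, 1]))
        label, scores = min_distance_predict(np.array([5.0, 5.0]), model)
        assert label == 1 and np.argmax(scores) == 1

    def test_matches_exhaustive_search(self, rng):
        centroids = rng.standard_normal((5, 13))
        model = min_distance_train(centroids, np.arange(5))
        frames = rng.standard_normal((100, 13))
        labels, scores = min_distance_predict(frames, model)
        for i in range(100):
            d = [np.sqrt(((frames[i] - c) ** 2).sum()) for c in centroids]
            assert labels[i] == int(np.argmin(d))
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)


def _blobs(rng, n_per_class=60, n_classes=5, spread=0.3):
    centers = rng.standard_normal((n_classes, 4)) * 6
    x = np.vstack([c + spread * rng.standard_normal((n_per_class, 4))
                   for c in centers])
    y = np.repeat(np.arange(n_classes), n_per_class)
    return x, y


class TestFamilies:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_score_contract(self, family, rng):
        x, y = _blobs(rng)
        clf = FrameClassifier(ClassifierSpec(family, seed=0)).fit(
            x, y, classes=range(5))
        series = classify_frames(rng.standard_normal((40, 4)), clf)
        assert series.scores.shape == (40, 5)        # C+1 columns for C=4
        assert np.all(series.scores >= -1e-12) and np.all(series.scores <= 1 + 1e-12)
        assert np.allclose(series.scores.sum(axis=1), 1.0, atol=1e-6)
        # label/score consistency under the lowest-index tie rule
        assert np.array_equal(series.labels, np.argmax(series.scores, axis=1))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_blobs_classified_perfectly(self, family, rng):
        x, y = _blobs(rng, spread=0.05)
        clf = FrameClassifier(ClassifierSpec(family, seed=0)).fit(
            x, y, classes=range(5))
        scores = clf.predict_scores(x)
        assert np.mean(np.argmax(scores, axis=1) == y) == 1.0

    def test_single_class_training_scores_one(self, rng):
        x = rng.standard_normal((30, 4))
        clf = FrameClassifier(ClassifierSpec("DecTr")).fit(
            x, np.full(30, 2), classes=range(5))
        scores = clf.predict_scores(rng.standard_normal((10, 4)))
        assert np.all(scores[:, 2] == 1.0)
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_unfitted_classifier_raises(self):
        with pytest.raises(RuntimeError):
            FrameClassifier(ClassifierSpec("kNN")).predict_scores(np.zeros((1, 4)))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("SVM")

    def test_maxlik_boundary_converges_to_likelihood_ratio_threshold(self):
        # two 1-D unit-variance Gaussians at 0 and 2: analytic boundary at 1
        rng = np.random.default_rng(77)
        n = 4000
        x = np.concatenate([rng.normal(0.0, 1.0, n),
                            rng.normal(2.0, 1.0, n)])[:, None]
        y = np.repeat([0, 1], n)
        clf = FrameClassifier(
            ClassifierSpec("MaxLik", params={"n_components": 1}, seed=0)
        ).fit(x, y, classes=[0, 1])
        grid = np.linspace(0.0, 2.0, 2001)[:, None]
        pred = np.argmax(clf.predict_scores(grid), axis=1)
        boundary = grid[np.argmax(pred == 1), 0]
        assert abs(boundary - 1.0) < 3.0 / np.sqrt(n)


class TestScoreSeries:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ScoreSeries(scores=np.array([[0.5, 0.2]]), labels=np.array([0]),
                        hop_s=0.01, class_ids=(0, 1))

    def test_from_scores_derives_argmax_labels(self):
        s = np.array([[0.2, 0.8], [0.5, 0.5], [0.9, 0.1]])
        series = ScoreSeries.from_scores(s, hop_s=0.01, class_ids=(0, 1))
        assert series.labels.tolist() == [1, 0, 0]   # tie breaks low
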