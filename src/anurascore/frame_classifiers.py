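"""Frame-level classification of MFCC features.

Frames are z-scored with training-set statistics, then classified into C+1
classes (C call classes plus silence/noise, class 0) by one of eight
pluggable families.  Every family emits, per frame, both a hard label and a
score row over the C+1 classes; score rows are non-negative and sum to 1 so
the downstream score-series stage can treat all families uniformly.

The minimum-distance (nearest class centroid, Euclidean) and the
maximum-likelihood (per-class Gaussian mixture) classifiers are implemented
here; the remaining six families are adapters over scikit-learn estimators
with their library defaults, except where a default is stated as part of the
method (kNN with k=1; a feed-forward net with one 10-neuron hidden layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .mfcc import FrameFeatureMatrix

__all__ = [
    "FAMILIES", "Normalizer", "CentroidModel", "ClassifierSpec", "ScoreSeries",
    "fit_normalizer", "apply_normalizer",
    "min_distance_train", "min_distance_predict", "centroid_distances",
    "FrameClassifier", "classify_frames", "FrameStage",
]

FAMILIES = ("MinDis", "MaxLik", "DecTr", "kNN", "LogReg", "Neur", "Discr", "Bayes")

#: lower bound on per-feature standard deviation, so constant features in
#: tiny synthetic sets do not produce infinities
SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class Normalizer:
    """Per-feature z-scoring statistics (training-set mean and sd)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma entries must be strictly positive")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FrameFeatureMatrix):
        return features.values
    if isinstance(features, (list, tuple)):
        return np.vstack([_as_matrix(f) for f in features])
    return np.asarray(features, dtype=float)


def fit_normalizer(features) -> Normalizer:
    """Column mean/sd over all training frames (population sd, floored).

    ``features`` may be an array, a FrameFeatureMatrix, or a collection of
    either; frames are pooled.
    """
    x = _as_matrix(features)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two training frames")
    mu = x.mean(axis=0)
    sigma = np.maximum(x.std(axis=0, ddof=0), SIGMA_FLOOR)
    return Normalizer(mu=mu, sigma=sigma)


def apply_normalizer(features, normalizer: Normalizer) -> np.ndarray:
    x = _as_matrix(features)
    if x.shape[-1] != normalizer.mu.size:
        raise ValueError("feature dimension does not match the normalizer")
    return (x - normalizer.mu) / normalizer.sigma


@dataclass(frozen=True)
class CentroidModel:
    """Per-class mean of the normalized features."""

    centroids: np.ndarray            # n_classes x D
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.centroids.shape[0] != len(self.class_ids):
            raise ValueError("one centroid per class required")


def min_distance_train(features: np.ndarray, labels: np.ndarray,
                       classes=None) -> CentroidModel:
    x = _as_matrix(features)
    y = np.asarray(labels)
    class_ids = tuple(classes) if classes is not None else tuple(np.unique(y))
    centroids = np.empty((len(class_ids), x.shape[1]))
    for i, cid in enumerate(class_ids):
        mask = y == cid
        if not mask.any():
            raise ValueError(f"no training frames for class {cid}")
        centroids[i] = x[mask].mean(axis=0)
    return CentroidModel(centroids=centroids, class_ids=class_ids)


def centroid_distances(frames: np.ndarray, model: CentroidModel) -> np.ndarray:
    """Euclidean distance of each frame to each class centroid (n x classes)."""
    x = np.atleast_2d(np.asarray(frames, dtype=float))
    return np.sqrt(((x[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2))


def min_distance_predict(frames: np.ndarray,
                         model: CentroidModel) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels and softmax(-distance) score rows.

    ``frames`` may be a single D-vector or an n x D matrix.  Ties in distance
    break to the lowest class index.  The softmax of negative Euclidean
    distances preserves the ranking and sums to 1, giving the non-probabilistic
    family a score row the score-series stage can consume.
    """
    d = centroid_distances(frames, model)
    scores = softmax(-d, axis=1)
    labels = np.asarray(model.class_ids)[np.argmin(d, axis=1)]
    if np.asarray(frames).ndim == 1:
        return labels[0], scores[0]
    return labels, scores


@dataclass(frozen=True)
class ClassifierSpec:
    """Family tag plus family-specific hyperparameters.

    Recognized families: MinDis, MaxLik, DecTr, kNN, LogReg, Neur, Discr,
    Bayes.  ``params`` overrides the adapter defaults (e.g. ``{"k": 5}`` for
    kNN or ``{"n_components": 1}`` for MaxLik).
    """

    family: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


@dataclass
class ScoreSeries:
    """Per-frame, per-class scores for one recording.

    ``scores[i, k]`` is the feasibility that frame i belongs to class
    ``class_ids[k]``; rows sum to 1.  ``labels`` is the row-wise argmax with
    lowest-index tie-breaking (0 = silence/noise).
    """

    scores: np.ndarray
    labels: np.ndarray
    hop_s: float
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.class_ids):
            raise ValueError("scores must be n_frames x n_classes")
        if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("score rows must sum to 1")

    @classmethod
    def from_scores(cls, scores: np.ndarray, hop_s: float,
                    class_ids) -> "ScoreSeries":
        scores = np.asarray(scores, dtype=float)
        class_ids = tuple(class_ids)
        labels = np.asarray(class_ids)[np.argmax(scores, axis=1)]
        return cls(scores=scores, labels=labels, hop_s=hop_s, class_ids=class_ids)

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]

    def class_column(self, class_id: int) -> np.ndarray:
        return self.scores[:, self.class_ids.index(class_id)]


class _MaxLikEstimator:
    """Per-class Gaussian mixture (default 2 components, full covariance).

    Classification is by maximum class-conditional likelihood (no priors);
    score rows are likelihoods normalized to sum 1, computed stably in the
    log domain.
    """

    def __init__(self, n_components: int = 2, seed: int | None = None,
                 reg_covar: float = 1e-6):
        self.n_components = n_components
        self.seed = seed
        self.reg_covar = reg_covar
        self.models_: list[GaussianMixture] = []
        self.classes_: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_MaxLikEstimator":
        self.classes_ = np.unique(y)
        self.models_ = []
        for cid in self.classes_:
            xc = x[y == cid]
            if xc.shape[0] < 2:
                # a single exemplar: degenerate Gaussian at that point with
                # the regularization floor as covariance
                xc = np.vstack([xc, xc])
            gmm = GaussianMixture(
                n_components=min(self.n_components, xc.shape[0]),
                covariance_type="full", reg_covar=self.reg_covar,
                random_state=self.seed)
            gmm.fit(xc)
            self.models_.append(gmm)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        loglik = np.column_stack([m.score_samples(x) for m in self.models_])
        return np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))


class FrameClassifier:
    """Uniform fit/score interface over the eight classifier families.

    ``fit`` takes normalized features and integer labels; ``predict_scores``
    returns an ``n x (C+1)`` matrix aligned with the ``classes`` passed at
    fit time (columns of classes unseen in training are zero).
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._model = None
        self.classes_: tuple[int, ...] | None = None
        self._observed: np.ndarray | None = None

    def _build(self):
        p, seed = dict(self.spec.params), self.spec.seed
        family = self.spec.family
        if family == "MaxLik":
            return _MaxLikEstimator(n_components=p.pop("n_components", 2), seed=seed)
        if family == "DecTr":
            return DecisionTreeClassifier(random_state=seed, **p)
        if family == "kNN":
            return KNeighborsClassifier(n_neighbors=p.pop("k", 1), **p)
        if family == "LogReg":
            return LogisticRegression(max_iter=p.pop("max_iter", 1000), **p)
        if family == "Neur":
            return MLPClassifier(hidden_layer_sizes=p.pop("hidden_layer_sizes", (10,)),
                                 random_state=seed,
                                 max_iter=p.pop("max_iter", 200), **p)
        if family == "Discr":
            return LinearDiscriminantAnalysis(**p)
        if family == "Bayes":
            return GaussianNB(**p)
        raise AssertionError(self.spec.family)

    def fit(self, features: np.ndarray, labels: np.ndarray,
            classes=None, validation=None) -> "FrameClassifier":
        # `validation` is accepted for adapters that can use a held-out set;
        # none of the current families do, so it is unused.
        x = _as_matrix(features)
        y = np.asarray(labels)
        self.classes_ = tuple(classes) if classes is not None else tuple(np.unique(y))
        self._observed = np.unique(y)
        if self.spec.family == "MinDis":
            self._model = min_distance_train(x, y, classes=tuple(self._observed))
        elif self._observed.size == 1:
            self._model = "degenerate"   # single-class training set
        else:
            self._model = self._build().fit(x, y)
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier has not been fitted")
        x = _as_matrix(features)
        full = np.zeros((x.shape[0], len(self.classes_)))
        col = {cid: k for k, cid in enumerate(self.classes_)}
        if self._model == "degenerate":
            full[:, col[int(self._observed[0])]] = 1.0
            return full
        if self.spec.family == "MinDis":
            _, scores = min_distance_predict(x, self._model)
            observed = self._model.class_ids
        else:
            scores = self._model.predict_proba(x)
            observed = self._model.classes_
        for k, cid in enumerate(observed):
            full[:, col[int(cid)]] = scores[:, k]
        return full


def classify_frames(features, classifier: FrameClassifier,
                    hop_s: float = 0.010) -> ScoreSeries:
    """Score every frame of a (normalized) feature matrix."""
    scores = classifier.predict_scores(features)
    return ScoreSeries.from_scores(scores, hop_s=hop_s,
                                   class_ids=classifier.classes_)


class FrameStage:
    """Normalizer + frame classifier, fit jointly on training recordings."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.normalizer: Normalizer | None = None
        self.classifier: FrameClassifier | None = None

    def fit(self, feature_matrices: list[FrameFeatureMatrix],
            frame_labels: list[np.ndarray], classes=None) -> "FrameStage":
        self.normalizer = fit_normalizer(feature_matrices)
        x = np.vstack([apply_normalizer(fm, self.normalizer)
                       for fm in feature_matrices])
        y = np.concatenate([np.asarray(l) for l in frame_labels])
        self.classifier = FrameClassifier(self.spec).fit(x, y, classes=classes)
        return self

    def classify(self, feature_matrix: FrameFeatureMatrix) -> ScoreSeries:
        if self.classifier is None:
            raise RuntimeError("frame stage has not been fitted")
        x = apply_normalizer(feature_matrix, self.normalizer)
        hop_s = feature_matrix.config.hop_ms / 1000.0
        return classify_frames(x, self.classifier, hop_s=hop_s)
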