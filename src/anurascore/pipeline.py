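"""Cross-validation orchestration of the two-stage classification procedure.

A k-fold plan (default k=7) rotates roles cyclically: in iteration t, fold t
is the test set, fold t+1 the validation set, and the remaining k-2 folds the
training set, so after k iterations every recording has been used k-2 times
for training, once for validation and once for testing.

Per iteration the frame stage (normalizer + frame classifier) is fitted on
the training folds' ROI-labelled frames only; score series are then produced
for all recordings of the iteration, the recording-labelling method (frame
counting, or a second-stage classifier on LFCC features) is fitted on the
training folds, and the test fold is evaluated.  Overall performance is the
mean of the per-iteration metric vectors; pooled per-recording predictions
(one per recording after the full rotation) are kept for bootstrap analysis.

``joint_grid`` sweeps all (score method x frame classifier) pairs — the nine
recording-labelling methods (counting plus eight classifier families) against
the eight frame families — reusing each fitted frame stage across the nine
score methods.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .frame_classifiers import FAMILIES, ClassifierSpec, FrameStage, ScoreSeries
from .metrics import MetricVector, confusion_matrix, global_metrics
from .mfcc import FrameFeatureMatrix, MFCCConfig, extract_mfcc
from .score_series import (LFCCConfig, SecondStage, UnclassifiableRecordingError,
                           count_classify, lfcc)
from .synth import AudioRecording, label_frames

__all__ = ["FoldPlan", "make_folds", "TwoStageResult", "GridResult",
           "run_two_stage", "run_score_methods", "joint_grid"]


@dataclass(frozen=True)
class FoldPlan:
    """Fold assignment and cyclic role rotation for k-fold cross-validation."""

    k: int
    assignment: np.ndarray          # fold index per recording
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.assignment, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")

    @property
    def n_recordings(self) -> int:
        return self.assignment.size

    def roles(self, iteration: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train, validation, test) recording indices for one iteration."""
        test_fold = iteration % self.k
        val_fold = (iteration + 1) % self.k
        test = np.flatnonzero(self.assignment == test_fold)
        val = np.flatnonzero(self.assignment == val_fold)
        train = np.flatnonzero((self.assignment != test_fold)
                               & (self.assignment != val_fold))
        return train, val, test


def make_folds(n_recordings: int, k: int = 7, seed: int = 0) -> FoldPlan:
    """Random unstratified fold assignment with near-equal fold sizes."""
    if n_recordings < k:
        raise ValueError("need at least as many recordings as folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_recordings)
    assignment = np.empty(n_recordings, dtype=int)
    assignment[perm] = np.arange(n_recordings) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


@dataclass
class _IterationOutputs:
    """Frame-stage products of one CV iteration (shared by score methods)."""

    iteration: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    series: dict[int, ScoreSeries]
    fitted_ids: set[int]            # recordings whose data entered any fit


@dataclass
class TwoStageResult:
    """Per-iteration and mean metrics of one (score, frame) method pair."""

    frame_spec: ClassifierSpec
    score_method: str
    per_iteration: list[MetricVector]
    pooled_true: np.ndarray
    pooled_pred: np.ndarray         # 0 marks an unclassifiable recording
    fitted_ids: list[set[int]] = field(repr=False, default_factory=list)

    @property
    def mean(self) -> MetricVector:
        stack = np.vstack([mv.as_array() for mv in self.per_iteration])
        return MetricVector(*stack.mean(axis=0))

    @property
    def pooled(self) -> MetricVector:
        n_classes = int(self.pooled_true.max())
        pred = _effective_predictions(self.pooled_true, self.pooled_pred, n_classes)
        return global_metrics(confusion_matrix(self.pooled_true, pred, n_classes))


def _effective_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                           n_classes: int) -> np.ndarray:
    """Map unclassifiable predictions (0) to a guaranteed-wrong class.

    A recording the counting rule could not label is scored as an error
    against every class; tallying it as (true mod C) + 1 realizes that
    conservatively inside an ordinary confusion matrix.
    """
    pred = np.asarray(y_pred, dtype=int).copy()
    bad = pred == 0
    pred[bad] = (np.asarray(y_true, dtype=int)[bad] % n_classes) + 1
    return pred


def _method_name(method) -> str:
    return method if isinstance(method, str) else method.family


def _frame_stage_outputs(recordings: list[AudioRecording], plan: FoldPlan,
                         frame_spec: ClassifierSpec, mfcc_config: MFCCConfig,
                         seed: int,
                         features: list[FrameFeatureMatrix] | None = None,
                         ) -> list[_IterationOutputs]:
    if features is None:
        features = [extract_mfcc(rec, mfcc_config) for rec in recordings]
    frame_labels = [label_frames(rec, mfcc_config.window_ms, mfcc_config.hop_ms)
                    for rec in recordings]
    n_classes = max(int(r.class_label) for r in recordings)
    classes = list(range(n_classes + 1))
    seeds = np.random.SeedSequence(seed).generate_state(plan.k) % (2 ** 31)

    outputs = []
    for it in range(plan.k):
        train, val, test = plan.roles(it)
        spec = dataclasses.replace(frame_spec, seed=int(seeds[it]))
        stage = FrameStage(spec).fit(
            [features[i] for i in train],
            [frame_labels[i] for i in train],
            classes=classes)
        needed = np.concatenate([train, test])
        series = {int(i): stage.classify(features[i]) for i in needed}
        outputs.append(_IterationOutputs(
            iteration=it, train=train, val=val, test=test, series=series,
            fitted_ids=set(int(i) for i in train)))
    return outputs


def _evaluate_score_method(recordings: list[AudioRecording],
                           outputs: list[_IterationOutputs],
                           frame_spec: ClassifierSpec, score_method,
                           lfcc_config: LFCCConfig, seed: int) -> TwoStageResult:
    labels = np.array([int(r.class_label) for r in recordings])
    n_classes = int(labels.max())
    per_iter, fitted = [], []
    pooled_true = np.empty(0, dtype=int)
    pooled_pred = np.empty(0, dtype=int)
    seeds = np.random.SeedSequence(seed).generate_state(len(outputs)) % (2 ** 31)

    for out in outputs:
        if isinstance(score_method, str):
            if score_method != "counting":
                raise ValueError(f"unknown score method {score_method!r}")
            preds = []
            for i in out.test:
                try:
                    preds.append(count_classify(out.series[int(i)]))
                except UnclassifiableRecordingError:
                    preds.append(0)
            preds = np.array(preds, dtype=int)
            iteration_fitted = set(out.fitted_ids)
        else:
            spec = dataclasses.replace(score_method, seed=int(seeds[out.iteration]))
            train_feats = [lfcc(out.series[int(i)], lfcc_config) for i in out.train]
            stage = SecondStage(spec, lfcc_config).fit(
                train_feats, labels[out.train],
                classes=list(range(1, n_classes + 1)))
            test_feats = [lfcc(out.series[int(i)], lfcc_config) for i in out.test]
            preds = stage.predict(test_feats)
            iteration_fitted = set(out.fitted_ids) | set(int(i) for i in out.train)

        true = labels[out.test]
        cm = confusion_matrix(true, _effective_predictions(true, preds, n_classes),
                              n_classes)
        per_iter.append(global_metrics(cm))
        fitted.append(iteration_fitted)
        pooled_true = np.concatenate([pooled_true, true])
        pooled_pred = np.concatenate([pooled_pred, preds])

    return TwoStageResult(frame_spec=frame_spec,
                          score_method=_method_name(score_method),
                          per_iteration=per_iter, pooled_true=pooled_true,
                          pooled_pred=pooled_pred, fitted_ids=fitted)


def run_two_stage(recordings: list[AudioRecording], plan: FoldPlan,
                  frame_spec: ClassifierSpec,
                  score_method: str | ClassifierSpec = "counting",
                  mfcc_config: MFCCConfig = MFCCConfig(),
                  lfcc_config: LFCCConfig = LFCCConfig(),
                  seed: int = 0) -> TwoStageResult:
    """Full cross-validated run of one (score method, frame classifier) pair.

    ``score_method`` is either the string ``"counting"`` or a
    :class:`ClassifierSpec` for the second-stage classifier.
    """
    outputs = _frame_stage_outputs(recordings, plan, frame_spec, mfcc_config, seed)
    return _evaluate_score_method(recordings, outputs, frame_spec, score_method,
                                  lfcc_config, seed)


def run_score_methods(recordings: list[AudioRecording], plan: FoldPlan,
                      frame_spec: ClassifierSpec, score_methods,
                      mfcc_config: MFCCConfig = MFCCConfig(),
                      lfcc_config: LFCCConfig = LFCCConfig(),
                      seed: int = 0,
                      features: list[FrameFeatureMatrix] | None = None,
                      ) -> dict[str, TwoStageResult]:
    """Evaluate several score methods over one shared fitted frame stage."""
    outputs = _frame_stage_outputs(recordings, plan, frame_spec, mfcc_config,
                                   seed, features=features)
    return {
        _method_name(m): _evaluate_score_method(recordings, outputs, frame_spec,
                                                m, lfcc_config, seed)
        for m in score_methods
    }


@dataclass
class GridResult:
    """Metric tensor of the joint (score method x frame classifier) sweep."""

    score_names: tuple[str, ...]    # counting first, then the 8 families
    frame_names: tuple[str, ...]
    metrics: np.ndarray             # n_score x n_frame x 10 (NaN on failure)
    results: dict[tuple[str, str], TwoStageResult] = field(repr=False,
                                                           default_factory=dict)
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def median_summary(self) -> np.ndarray:
        """Median over the ten metrics per cell (n_score x n_frame)."""
        return np.median(self.metrics, axis=2)

    @property
    def improvement(self) -> np.ndarray:
        """Improvement over counting per (score family, frame family, metric)."""
        return self.metrics[1:] - self.metrics[:1]

    def to_records(self) -> list[dict]:
        """Long-format rows: score_method, frame_method, metric, value."""
        from .metrics import METRIC_NAMES
        rows = []
        for i, sname in enumerate(self.score_names):
            for j, fname in enumerate(self.frame_names):
                for k, mname in enumerate(METRIC_NAMES):
                    rows.append({"score_method": sname, "frame_method": fname,
                                 "metric": mname,
                                 "value": float(self.metrics[i, j, k])})
        return rows


def joint_grid(recordings: list[AudioRecording], plan: FoldPlan,
               frame_families=FAMILIES, score_families=FAMILIES,
               mfcc_config: MFCCConfig = MFCCConfig(),
               lfcc_config: LFCCConfig = LFCCConfig(),
               seed: int = 0) -> GridResult:
    """Sweep all (score, frame) pairs; counting is always the first score row.

    Individual cell failures are recorded and the sweep continues (the cell
    is NaN in the tensor).
    """
    score_methods = ["counting"] + [ClassifierSpec(f) for f in score_families]
    score_names = tuple(_method_name(m) for m in score_methods)
    frame_names = tuple(frame_families)
    metrics = np.full((len(score_methods), len(frame_names), 10), np.nan)
    results: dict[tuple[str, str], TwoStageResult] = {}
    failures: list[tuple[str, str, str]] = []

    features = [extract_mfcc(rec, mfcc_config) for rec in recordings]
    for j, fam in enumerate(frame_names):
        try:
            outputs = _frame_stage_outputs(recordings, plan, ClassifierSpec(fam),
                                           mfcc_config, seed, features=features)
        except Exception as exc:   # frame stage down for this family
            failures.extend((s, fam, repr(exc)) for s in score_names)
            continue
        for i, method in enumerate(score_methods):
            try:
                res = _evaluate_score_method(recordings, outputs,
                                             ClassifierSpec(fam), method,
                                             lfcc_config, seed)
            except Exception as exc:
                failures.append((score_names[i], fam, repr(exc)))
                continue
            metrics[i, j] = res.mean.as_array()
            results[(score_names[i], fam)] = res
    return GridResult(score_names=score_names, frame_names=frame_names,
                      metrics=metrics, results=results, failures=failures)
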