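"""Bootstrap confidence intervals and paired outperformance probabilities.

The resampling unit is the recording: from S test-set (true, predicted)
pairs, Nb datasets of size S are drawn with replacement and the ten-metric
vector is recomputed on each, giving an empirical distribution per metric.
Confidence intervals are plain percentile intervals.  To compare two
classification methods the same resample indices are applied to both (paired
design); the outperformance probability of method 1 over method 2 for metric
k is the fraction of resamples with a strictly positive difference — two
identical methods therefore score 0, not 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import METRIC_NAMES, _global_metric_array, confusion_matrix

__all__ = ["BootstrapResult", "OutperformanceResult",
           "bootstrap_metrics", "outperformance"]


@dataclass(frozen=True)
class BootstrapResult:
    n_resamples: int
    gamma: float
    metric_samples: np.ndarray      # Nb x 10
    ci_low: np.ndarray              # 10
    ci_high: np.ndarray             # 10
    mean_original: np.ndarray       # metrics of the un-resampled dataset
    mean_resampled: np.ndarray      # mean over the bootstrap distribution
    seed: int

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            name: {"mean": float(self.mean_original[k]),
                   "mean_resampled": float(self.mean_resampled[k]),
                   "ci_low": float(self.ci_low[k]),
                   "ci_high": float(self.ci_high[k])}
            for k, name in enumerate(METRIC_NAMES)
        }


@dataclass(frozen=True)
class OutperformanceResult:
    delta_samples: np.ndarray       # Nb x 10, method1 - method2
    prob_outperform: np.ndarray     # 10, Pr[delta > 0]
    delta_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    seed: int

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            name: {"delta_mean": float(self.delta_mean[k]),
                   "ci_low": float(self.ci_low[k]),
                   "ci_high": float(self.ci_high[k]),
                   "prob_outperform": float(self.prob_outperform[k])}
            for k, name in enumerate(METRIC_NAMES)
        }


def _resampled_counts(pair_codes: np.ndarray, idx: np.ndarray,
                      n_classes: int) -> np.ndarray:
    """Count matrices (Nb x C x C) of resampled prediction pairs."""
    nb = idx.shape[0]
    ncc = n_classes * n_classes
    codes = pair_codes[idx] + (np.arange(nb) * ncc)[:, None]
    flat = np.bincount(codes.ravel(), minlength=nb * ncc)
    return flat.reshape(nb, n_classes, n_classes)


def _check_pairs(y_true, y_pred, n_classes):
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    confusion_matrix(t, p, n_classes)   # validates ranges/shapes
    return t, p


def bootstrap_metrics(y_true, y_pred, n_classes: int,
                      n_resamples: int = 10000, gamma: float = 0.95,
                      seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap of the ten-metric vector over recordings."""
    t, p = _check_pairs(y_true, y_pred, n_classes)
    s = t.size
    if s < 2:
        raise ValueError("need at least two recordings to resample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, s, size=(n_resamples, s))
    pair_codes = (t - 1) * n_classes + (p - 1)
    samples = _global_metric_array(_resampled_counts(pair_codes, idx, n_classes))
    alpha = (1.0 - gamma) / 2.0
    ci_low = np.quantile(samples, alpha, axis=0)
    ci_high = np.quantile(samples, 1.0 - alpha, axis=0)
    original = _global_metric_array(
        np.bincount(pair_codes, minlength=n_classes ** 2)
        .reshape(n_classes, n_classes))
    return BootstrapResult(n_resamples=n_resamples, gamma=gamma,
                           metric_samples=samples, ci_low=ci_low,
                           ci_high=ci_high, mean_original=original,
                           mean_resampled=samples.mean(axis=0), seed=seed)


def outperformance(y_true, y_pred_1, y_pred_2, n_classes: int,
                   n_resamples: int = 10000, gamma: float = 0.95,
                   seed: int = 0) -> OutperformanceResult:
    """Paired bootstrap comparison of two methods on the same recordings.

    ``prob_outperform[k]`` estimates Pr[metric_k(method1) > metric_k(method2)]
    under recording resampling; the same resamples are used for both methods.
    """
    t, p1 = _check_pairs(y_true, y_pred_1, n_classes)
    t2, p2 = _check_pairs(y_true, y_pred_2, n_classes)
    if p1.size != p2.size:
        raise ValueError("both methods must cover the same recordings")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, t.size, size=(n_resamples, t.size))
    codes1 = (t - 1) * n_classes + (p1 - 1)
    codes2 = (t - 1) * n_classes + (p2 - 1)
    m1 = _global_metric_array(_resampled_counts(codes1, idx, n_classes))
    m2 = _global_metric_array(_resampled_counts(codes2, idx, n_classes))
    delta = m1 - m2
    alpha = (1.0 - gamma) / 2.0
    return OutperformanceResult(
        delta_samples=delta,
        prob_outperform=(delta > 0).mean(axis=0),
        delta_mean=delta.mean(axis=0),
        ci_low=np.quantile(delta, alpha, axis=0),
        ci_high=np.quantile(delta, 1.0 - alpha, axis=0),
        seed=seed)
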