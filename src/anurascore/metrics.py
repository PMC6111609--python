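"""Multiclass confusion matrix and the ten global performance metrics.

Per class (one-vs-rest collapse of the C x C count matrix ``m_ij``, with
``m_i`` the i-th row total and ``e_i`` the i-th column total):

    SNS_i = m_ii / m_i                    sensitivity (recall)
    SPC_i = TN_i / (m - m_i)              specificity
    PRC_i = m_ii / e_i                    precision
    NPV_i = TN_i / (m - e_i)              negative predictive value
    F1_i  = 2 PRC_i SNS_i / (PRC_i+SNS_i)
    GM_i  = sqrt(SNS_i SPC_i)
    BM_i  = SNS_i + SPC_i - 1             bookmaker informedness
    MK_i  = PRC_i + NPV_i - 1             markedness

Global values are macro averages (equal class weight), accuracy is
trace/total, and the multiclass Matthews correlation coefficient is the
Gorodkin R_K statistic.  MCC, BM and MK, which live in [-1, 1], are reported
normalized to [0, 1] via (mu + 1) / 2.

Zero-division conventions (never hit on well-populated data, needed for
synthetic edge cases): classes with no true instance are excluded from the
SNS/F1/GM/BM macro averages; PRC_i with an empty predicted column is 0; F1_i
with PRC+SNS = 0 is 0; an undefined R_K denominator gives MCC 0.

The internal computations broadcast over leading axes, so a stack of
bootstrap-resampled count matrices is scored in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "METRIC_NAMES", "ConfusionMatrix", "MetricVector",
    "confusion_matrix", "per_class_metrics", "global_metrics",
    "reconstruct_counts", "format_percent_matrix",
]

METRIC_NAMES = ("SNS", "SPC", "PRC", "NPV", "ACC", "F1", "GM", "MCCn", "BMn", "MKn")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts ``m_ij``: true class i (row) labelled as class j (column)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def row_totals(self) -> np.ndarray:       # m_i: true-class sizes
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:       # e_i: predicted-class sizes
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricVector:
    """The ten global metrics, all in [0, 1]."""

    sns: float
    spc: float
    prc: float
    npv: float
    acc: float
    f1: float
    gm: float
    mcc_n: float
    bm_n: float
    mk_n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sns, self.spc, self.prc, self.npv, self.acc,
                         self.f1, self.gm, self.mcc_n, self.bm_n, self.mk_n])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(METRIC_NAMES, self.as_array()))


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Tally labels in 1..C into a C x C count matrix."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if np.any((t < 1) | (t > n_classes)) or np.any((p < 1) | (p > n_classes)):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    counts = np.bincount((t - 1) * n_classes + (p - 1),
                         minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    return np.divide(num, den, out=np.zeros(np.broadcast_shapes(np.shape(num), den.shape)),
                     where=den != 0)


def _per_class_arrays(counts: np.ndarray) -> dict[str, np.ndarray]:
    """Per-class metric arrays; broadcasts over leading axes of ``counts``."""
    c = np.asarray(counts, dtype=float)
    diag = np.diagonal(c, axis1=-2, axis2=-1)
    m_i = c.sum(axis=-1)
    e_i = c.sum(axis=-2)
    m = c.sum(axis=(-2, -1))[..., None]
    tn = m - m_i - e_i + diag
    sns = _safe_div(diag, m_i)
    spc = _safe_div(tn, m - m_i)
    prc = _safe_div(diag, e_i)
    npv = _safe_div(tn, m - e_i)
    f1 = _safe_div(2.0 * prc * sns, prc + sns)
    gm = np.sqrt(sns * spc)
    return {"SNS": sns, "SPC": spc, "PRC": prc, "NPV": npv, "F1": f1,
            "GM": gm, "BM": sns + spc - 1.0, "MK": prc + npv - 1.0,
            "_m_i": m_i, "_e_i": e_i}


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, np.ndarray]:
    """Raw (unnormalized) per-class metrics, one entry per class."""
    arrays = _per_class_arrays(cm.counts)
    return {k: v for k, v in arrays.items() if not k.startswith("_")}


def _gorodkin_mcc(counts: np.ndarray) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    t_k = c.sum(axis=-1)            # true-class totals
    p_k = c.sum(axis=-2)            # predicted-class totals
    s = c.sum(axis=(-2, -1))
    trace = np.diagonal(c, axis1=-2, axis2=-1).sum(axis=-1)
    cov = trace * s - (t_k * p_k).sum(axis=-1)
    den = np.sqrt(s ** 2 - (p_k ** 2).sum(axis=-1)) * \
        np.sqrt(s ** 2 - (t_k ** 2).sum(axis=-1))
    return np.where(den > 0, cov / np.where(den > 0, den, 1.0), 0.0)


def _global_metric_array(counts: np.ndarray) -> np.ndarray:
    """Ten global metrics; ``counts`` may carry leading batch axes.

    Returns an array of shape ``batch + (10,)`` ordered as METRIC_NAMES.
    """
    a = _per_class_arrays(counts)
    has_true = a["_m_i"] > 0        # classes absent from the truth are excluded

    def macro(x, mask):
        return (x * mask).sum(axis=-1) / np.maximum(mask.sum(axis=-1), 1)

    c = np.asarray(counts, dtype=float)
    acc = _safe_div(np.diagonal(c, axis1=-2, axis2=-1).sum(axis=-1),
                    c.sum(axis=(-2, -1)))
    all_classes = np.ones_like(has_true)
    out = np.stack([
        macro(a["SNS"], has_true),
        macro(a["SPC"], has_true),
        macro(a["PRC"], all_classes),
        macro(a["NPV"], all_classes),
        acc,
        macro(a["F1"], has_true),
        macro(a["GM"], has_true),
        (_gorodkin_mcc(counts) + 1.0) / 2.0,
        (macro(a["BM"], has_true) + 1.0) / 2.0,
        (macro(a["MK"], all_classes) + 1.0) / 2.0,
    ], axis=-1)
    return out


def global_metrics(cm: ConfusionMatrix) -> MetricVector:
    """Macro-averaged global metric vector of a confusion matrix."""
    values = _global_metric_array(cm.counts)
    mv = MetricVector(*(float(v) for v in values))
    return mv


def reconstruct_counts(percent_matrix, class_totals) -> ConfusionMatrix:
    """Invert a row-percentage confusion matrix back to integer counts.

    Published confusion matrices are often printed as row percentages; given
    the true class totals, counts are recovered by largest-remainder rounding
    so every row sums exactly to its class total.
    """
    pct = np.asarray(percent_matrix, dtype=float)
    totals = np.asarray(class_totals, dtype=int)
    if pct.ndim != 2 or pct.shape[0] != pct.shape[1] or pct.shape[0] != totals.size:
        raise ValueError("need a square percentage matrix and one total per row")
    if np.any(totals <= 0):
        raise ValueError("class totals must be positive")
    if np.any(np.abs(pct.sum(axis=1) - 100.0) > 0.1):
        raise ValueError("each percentage row must sum to 100 (within 0.1)")
    counts = np.zeros_like(pct, dtype=np.int64)
    for i, total in enumerate(totals):
        exact = pct[i] / 100.0 * total
        base = np.floor(exact).astype(np.int64)
        remainder = exact - base
        short = int(total - base.sum())
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
        counts[i] = base
    return ConfusionMatrix(counts)


def format_percent_matrix(cm: ConfusionMatrix, decimals: int = 2) -> np.ndarray:
    """Row-percentage view of a confusion matrix (the printed-table format)."""
    c = cm.counts.astype(float)
    return np.round(_safe_div(c, c.sum(axis=1, keepdims=True)) * 100.0, decimals)
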