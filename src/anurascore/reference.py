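"""Published reference results for the four-class anuran call study.

The original 868-recording dataset (369 natterjack mating calls, 63
natterjack release calls, 419 midwife-toad mating calls, 17 midwife-toad
distress calls) is not publicly deposited, but the study that introduced the
score-series method printed its confusion matrices as row percentages.
Together with the class totals these determine the integer count matrices,
from which every global metric can be recomputed — the validation route used
by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionMatrix, reconstruct_counts

__all__ = [
    "CLASS_TOTALS", "CLASS_NAMES",
    "COUNTING_KNN_PERCENT", "MINDIS_DECTR_PERCENT",
    "counting_knn_confusion", "mindis_dectr_confusion",
]

CLASS_NAMES = (
    "natterjack mating call",
    "natterjack release call",
    "midwife-toad mating call",
    "midwife-toad distress call",
)

#: number of recordings per true class
CLASS_TOTALS = np.array([369, 63, 419, 17])

#: row-percentage confusion matrix: kNN frame classifier + frame counting
COUNTING_KNN_PERCENT = np.array([
    [99.46,  0.54,  0.00,  0.00],
    [30.16, 65.08,  4.77,  0.00],
    [ 5.97,  0.00, 94.03,  0.00],
    [ 0.00,  0.00,  0.00, 100.00],
])

#: row-percentage confusion matrix: minimum-distance second stage on the
#: score series of a decision-tree frame classifier
MINDIS_DECTR_PERCENT = np.array([
    [96.48,  2.98,  0.27,  0.27],
    [ 3.17, 95.24,  1.59,  0.00],
    [ 1.19,  0.24, 98.33,  0.24],
    [ 0.00,  0.00,  0.00, 100.00],
])


def counting_knn_confusion() -> ConfusionMatrix:
    """Integer counts of the counting-baseline (kNN frames) result."""
    return reconstruct_counts(COUNTING_KNN_PERCENT, CLASS_TOTALS)


def mindis_dectr_confusion() -> ConfusionMatrix:
    """Integer counts of the best two-stage (MinDis on DecTr scores) result."""
    return reconstruct_counts(MINDIS_DECTR_PERCENT, CLASS_TOTALS)
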