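"""Recording-level labelling from frame-classifier output.

Two routes are provided.  The counting baseline labels a recording with the
class that owns the most frames (silence/noise frames excluded).  The
score-series route instead treats the C per-class score series as signals:
each series is summarized by linear-frequency cepstral coefficients (LFCC) —
whole-series energy spectral density, a 20-filter triangular filterbank with
linearly spaced edges from 0 to the series Nyquist, log energies, orthonormal
DCT-II, keep c1..c13 — and the concatenated 13*C vector is classified by a
second-stage classifier from the same eight families.

Unlike the audio MFCC chain there is no pre-emphasis, no band restriction, no
Mel warping and no liftering: score series are not sounds.  A score series
that is identically zero has zero energy in every filter, i.e. minus infinity
log energy; log energies are floored (default log(1e-12)) so every recording
still yields a finite feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct

from .frame_classifiers import (ClassifierSpec, FrameClassifier, Normalizer,
                                ScoreSeries, apply_normalizer, fit_normalizer)
from .mfcc import _triangular_weights, inverse_cepstrum, next_pow2

__all__ = [
    "LFCCConfig", "LFCCFeatureVector", "UnclassifiableRecordingError",
    "count_classify", "score_series_esd", "linear_filter_centers_hz",
    "linear_filterbank_log_energies", "linlog_cepstrum", "lfcc",
    "reconstruct_filterbank", "SecondStage", "score_classify",
]


class UnclassifiableRecordingError(ValueError):
    """Raised by the counting rule when every frame is silence/noise."""


@dataclass(frozen=True)
class LFCCConfig:
    n_filters: int = 20
    n_ceps_full: int = 20
    n_ceps_kept: int = 13
    log_floor: float = 1e-12

    def __post_init__(self) -> None:
        if not 0 < self.n_ceps_kept <= self.n_ceps_full <= self.n_filters:
            raise ValueError("need 0 < D <= n_ceps_full <= n_filters")


@dataclass
class LFCCFeatureVector:
    """Concatenated per-class LFCC blocks (length D*C) for one recording."""

    values: np.ndarray
    class_block_order: tuple[int, ...]
    provenance: str | None = None
    config: LFCCConfig = field(repr=False, default_factory=LFCCConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.config.n_ceps_kept * len(self.class_block_order)
        if self.values.shape != (expected,):
            raise ValueError(f"expected a length-{expected} vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LFCC vector contains non-finite entries")


def count_classify(series: ScoreSeries) -> int:
    """Label = call class with the most frames; ties go to the lowest index.

    Silence/noise frames (label 0) never vote.  Raises
    :class:`UnclassifiableRecordingError` when no call frame exists.
    """
    if series.n_frames < 1:
        raise ValueError("empty score series")
    call_ids = [cid for cid in series.class_ids if cid != 0]
    counts = np.array([(series.labels == cid).sum() for cid in call_ids])
    if counts.sum() == 0:
        raise UnclassifiableRecordingError("all frames are silence/noise")
    return int(call_ids[int(np.argmax(counts))])


def score_series_esd(series: np.ndarray) -> np.ndarray:
    """Whole-series squared-magnitude one-sided spectrum (no windowing).

    FFT length is the next power of two at or above the series length.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("score series must have at least 2 frames")
    nfft = next_pow2(x.shape[-1])
    return np.abs(np.fft.rfft(x, n=nfft, axis=-1)) ** 2


def _linear_edges_hz(config: LFCCConfig, hop_s: float) -> np.ndarray:
    nyquist = 1.0 / (2.0 * hop_s)
    return np.linspace(0.0, nyquist, config.n_filters + 2)


def linear_filter_centers_hz(config: LFCCConfig = LFCCConfig(),
                             hop_s: float = 0.010) -> np.ndarray:
    """Centers of the linearly spaced filters, in Hz of the score series."""
    return _linear_edges_hz(config, hop_s)[1:-1]


def linear_filterbank_log_energies(esd: np.ndarray,
                                   config: LFCCConfig = LFCCConfig(),
                                   hop_s: float = 0.010) -> np.ndarray:
    """Log energies of the linear triangular filterbank, floored.

    Filter edges are equally spaced from 0 Hz to the score-series Nyquist
    frequency ``1/(2*hop_s)``.  All-zero spectra land on ``log(log_floor)``
    rather than minus infinity.
    """
    esd = np.asarray(esd, dtype=float)
    nfft = 2 * (esd.shape[-1] - 1)
    sample_rate = 1.0 / hop_s
    fb = _triangular_weights(_linear_edges_hz(config, hop_s), nfft, sample_rate)
    energies = esd @ fb.T
    if config.log_floor > 0.0:
        return np.log(np.maximum(energies, config.log_floor))
    return np.log(energies)


def linlog_cepstrum(log_energies: np.ndarray,
                    config: LFCCConfig = LFCCConfig()) -> np.ndarray:
    """All ``n_ceps_full`` orthonormal DCT-II coefficients (c0 included)."""
    le = np.asarray(log_energies, dtype=float)
    if not np.all(np.isfinite(le)):
        raise ValueError("log energies must be finite")
    return dct(le, type=2, norm="ortho", axis=-1)[..., :config.n_ceps_full]


def lfcc(series: ScoreSeries, config: LFCCConfig = LFCCConfig(),
         provenance: str | None = None) -> LFCCFeatureVector:
    """13*C LFCC summary of a recording's score series.

    Only the C call-class columns are used (the silence column is redundant:
    rows sum to 1).  Per class: ESD -> linear log filterbank -> DCT-II ->
    keep c1..cD; blocks are concatenated in class order.
    """
    call_ids = tuple(cid for cid in series.class_ids if cid != 0)
    if not call_ids:
        raise ValueError("score series has no call-class columns")
    blocks = []
    for cid in call_ids:
        esd = score_series_esd(series.class_column(cid))
        log_fbe = linear_filterbank_log_energies(esd, config, hop_s=series.hop_s)
        coeffs = linlog_cepstrum(log_fbe, config)
        blocks.append(coeffs[1:config.n_ceps_kept + 1])
    return LFCCFeatureVector(values=np.concatenate(blocks),
                             class_block_order=call_ids,
                             provenance=provenance, config=config)


def reconstruct_filterbank(coefficients: np.ndarray,
                           reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Rebuild a log filterbank vector from its first n cepstral coefficients.

    ``coefficients`` are the first ``n`` (1 <= n <= len(reference)) of the
    full orthonormal DCT-II coefficients (c0 first); higher coefficients are
    zeroed.  Returns the reconstruction and its RMSE against ``reference`` —
    the truncation-accuracy curve of the cepstral representation.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = coeffs.shape[-1]
    if not 1 <= n <= reference.shape[-1]:
        raise ValueError("need 1 <= n <= len(reference) coefficients")
    recon = inverse_cepstrum(coeffs, reference.shape[-1])
    rmse = float(np.sqrt(np.mean((recon - reference) ** 2)))
    return recon, rmse


class SecondStage:
    """Recording-level classifier over LFCC vectors.

    Features are z-scored with training-set statistics (the same
    normalization convention as the frame stage) before classification.
    """

    def __init__(self, spec: ClassifierSpec, config: LFCCConfig = LFCCConfig()):
        self.spec = spec
        self.config = config
        self.normalizer: Normalizer | None = None
        self.classifier: FrameClassifier | None = None

    def fit(self, features: list[LFCCFeatureVector] | np.ndarray,
            labels: np.ndarray, classes=None) -> "SecondStage":
        x = self._stack(features)
        self.normalizer = fit_normalizer(x)
        self.classifier = FrameClassifier(self.spec).fit(
            apply_normalizer(x, self.normalizer), np.asarray(labels),
            classes=classes)
        return self

    def predict(self, features) -> np.ndarray:
        if self.classifier is None:
            raise RuntimeError("second stage has not been fitted")
        x = apply_normalizer(self._stack(features), self.normalizer)
        scores = self.classifier.predict_scores(x)
        return np.asarray(self.classifier.classes_)[np.argmax(scores, axis=1)]

    @staticmethod
    def _stack(features) -> np.ndarray:
        if isinstance(features, np.ndarray):
            return np.atleast_2d(features)
        if isinstance(features, LFCCFeatureVector):
            return features.values[None, :]
        return np.vstack([f.values for f in features])


def score_classify(features: LFCCFeatureVector, model: SecondStage) -> int:
    """Label one recording (class in 1..C) from its LFCC vector."""
    return int(model.predict(features)[0])
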