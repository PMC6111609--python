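"""HTK-dialect Mel-frequency cepstral coefficients.

The extraction chain is: first-order pre-emphasis; 25 ms Hamming frames with a
10 ms hop; energy spectral density per frame (squared-magnitude one-sided FFT,
length the next power of two); a 20-filter triangular filterbank with edges
equally spaced on the Mel scale between 300 and 3700 Hz; natural log of the
filter energies; orthonormal DCT-II; retention of c1..c13 (c0, which carries
overall level, is dropped); and a sine lifter with L=22.

Dialect choices follow HTK where the chain is underspecified: the first
pre-emphasized sample is (1-alpha)*x[0], the spectrum is power (not
magnitude), filterbank energies use the natural log with a 1e-12 floor, and
the trailing partial frame is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct, rfft

from .synth import AudioRecording

__all__ = [
    "MFCCConfig", "FrameFeatureMatrix",
    "preemphasize", "frame_signal", "energy_spectral_density",
    "mel_filterbank", "mel_filter_centers_hz", "mel_filterbank_log_energies",
    "cepstrum", "full_cepstrum", "inverse_cepstrum", "extract_mfcc",
    "hz_to_mel", "mel_to_hz", "next_pow2",
]


@dataclass(frozen=True)
class MFCCConfig:
    preemphasis_alpha: float = 0.97
    window_ms: float = 25.0
    hop_ms: float = 10.0
    window_function: str = "hamming"
    n_filters: int = 20
    band_low_hz: float = 300.0
    band_high_hz: float = 3700.0
    n_ceps_full: int = 20
    n_ceps_kept: int = 13
    lifter_l: int = 22
    log_floor: float = 1e-12  # 0 disables the floor

    def __post_init__(self) -> None:
        if not 0.0 <= self.preemphasis_alpha < 1.0:
            raise ValueError("preemphasis_alpha must be in [0, 1)")
        if not 0.0 < self.hop_ms <= self.window_ms:
            raise ValueError("need 0 < hop_ms <= window_ms")
        if not 0.0 <= self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 <= band_low_hz < band_high_hz")
        if not 0 < self.n_ceps_kept <= self.n_ceps_full <= self.n_filters:
            raise ValueError("need 0 < D <= n_ceps_full <= n_filters")
        if self.window_function != "hamming":
            raise ValueError("only the Hamming window is supported")


@dataclass
class FrameFeatureMatrix:
    """Per-frame MFCC vectors for one recording (n_frames x D)."""

    values: np.ndarray
    frame_times_s: np.ndarray
    config: MFCCConfig = field(repr=False, default_factory=MFCCConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.frame_times_s.size:
            raise ValueError("values must be n_frames x D, one time per frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def preemphasize(signal: np.ndarray, alpha: float = 0.97) -> np.ndarray:
    """y[n] = x[n] - alpha*x[n-1], with y[0] = (1-alpha)*x[0]."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    y = np.empty_like(x)
    y[0] = (1.0 - alpha) * x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return y


def frame_sizes(sample_rate: int, config: MFCCConfig) -> tuple[int, int]:
    """(window, hop) in samples: floor(ms * fs / 1000)."""
    win = int(config.window_ms * sample_rate / 1000.0)
    hop = int(config.hop_ms * sample_rate / 1000.0)
    return win, hop


def frame_signal(signal: np.ndarray, sample_rate: int,
                 config: MFCCConfig = MFCCConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Split into Hamming-windowed frames.

    Returns ``(frames, frame_times_s)`` where ``frames`` is
    ``n_frames x window`` and times mark frame starts.  Trailing samples that
    do not fill a window are dropped; frame count is
    ``floor((N - win)/hop) + 1``.
    """
    x = np.asarray(signal, dtype=float)
    win, hop = frame_sizes(sample_rate, config)
    if x.size < win:
        raise ValueError(f"signal of {x.size} samples shorter than one {win}-sample window")
    n_frames = (x.size - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(win)[None, :]
    times = hop * np.arange(n_frames) / sample_rate
    return frames, times


def energy_spectral_density(frame: np.ndarray, nfft: int | None = None) -> np.ndarray:
    """Squared-magnitude one-sided spectrum, zero-padded to the next power of two.

    Accepts a single frame or a stack of frames (last axis = time); output
    length along the last axis is ``nfft/2 + 1``.
    """
    x = np.asarray(frame, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty frame")
    if nfft is None:
        nfft = next_pow2(x.shape[-1])
    spec = rfft(x, n=nfft, axis=-1)
    return np.abs(spec) ** 2


def mel_filterbank(nfft: int, sample_rate: int,
                   config: MFCCConfig = MFCCConfig()) -> np.ndarray:
    """Triangular Mel filterbank weights, ``n_filters x (nfft/2 + 1)``.

    The ``n_filters + 2`` edge frequencies are equally spaced on the Mel scale
    between ``band_low_hz`` and ``band_high_hz``; triangles are evaluated at
    the FFT bin frequencies and are not area-normalized (HTK style).
    """
    if config.band_high_hz > sample_rate / 2.0 + 1e-9:
        raise ValueError("filterbank band exceeds the Nyquist frequency")
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(config.band_low_hz),
                                     hz_to_mel(config.band_high_hz),
                                     config.n_filters + 2))
    return _triangular_weights(edges_hz, nfft, float(sample_rate))


def _triangular_weights(edges_hz: np.ndarray, nfft: int, sample_rate: float) -> np.ndarray:
    bin_hz = np.arange(nfft // 2 + 1) * sample_rate / nfft
    n_filters = edges_hz.size - 2
    weights = np.zeros((n_filters, bin_hz.size))
    for k in range(n_filters):
        lo, mid, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        rising = (bin_hz - lo) / (mid - lo)
        falling = (hi - bin_hz) / (hi - mid)
        weights[k] = np.clip(np.minimum(rising, falling), 0.0, None)
    return weights


def mel_filter_centers_hz(config: MFCCConfig = MFCCConfig()) -> np.ndarray:
    edges = mel_to_hz(np.linspace(hz_to_mel(config.band_low_hz),
                                  hz_to_mel(config.band_high_hz),
                                  config.n_filters + 2))
    return edges[1:-1]


def _log_floored(energies: np.ndarray, floor: float) -> np.ndarray:
    if floor > 0.0:
        return np.log(np.maximum(energies, floor))
    return np.log(energies)


def mel_filterbank_log_energies(esd: np.ndarray, sample_rate: int,
                                config: MFCCConfig = MFCCConfig()) -> np.ndarray:
    """Natural-log Mel filterbank energies of one or more ESD vectors."""
    esd = np.asarray(esd, dtype=float)
    nfft = 2 * (esd.shape[-1] - 1)
    fb = mel_filterbank(nfft, sample_rate, config)
    return _log_floored(esd @ fb.T, config.log_floor)


def cepstrum(log_energies: np.ndarray,
             config: MFCCConfig = MFCCConfig()) -> np.ndarray:
    """Orthonormal DCT-II of the log filterbank energies, liftered.

    Keeps c1..cD (c0 is discarded) and applies the sine lifter
    ``c'_n = (1 + (L/2) sin(pi n / L)) c_n``.  ``lifter_l = 0`` disables
    liftering.
    """
    le = np.asarray(log_energies, dtype=float)
    if not np.all(np.isfinite(le)):
        raise ValueError("log energies must be finite")
    coeffs = dct(le, type=2, norm="ortho", axis=-1)[..., :config.n_ceps_full]
    kept = coeffs[..., 1:config.n_ceps_kept + 1]
    if config.lifter_l > 0:
        n = np.arange(1, config.n_ceps_kept + 1)
        kept = kept * (1.0 + (config.lifter_l / 2.0) * np.sin(np.pi * n / config.lifter_l))
    return kept


def full_cepstrum(log_energies: np.ndarray,
                  config: MFCCConfig = MFCCConfig()) -> np.ndarray:
    """All ``n_ceps_full`` DCT-II coefficients (c0 included, no lifter)."""
    le = np.asarray(log_energies, dtype=float)
    return dct(le, type=2, norm="ortho", axis=-1)[..., :config.n_ceps_full]


def inverse_cepstrum(coeffs: np.ndarray, n_out: int) -> np.ndarray:
    """Inverse orthonormal DCT-II, zero-padding missing high coefficients."""
    c = np.asarray(coeffs, dtype=float)
    padded = np.zeros(c.shape[:-1] + (n_out,))
    padded[..., :c.shape[-1]] = c
    return idct(padded, type=2, norm="ortho", axis=-1)


def extract_mfcc(recording: AudioRecording,
                 config: MFCCConfig = MFCCConfig()) -> FrameFeatureMatrix:
    """Full chain: pre-emphasis, framing, ESD, Mel log filterbank, cepstrum."""
    emphasized = preemphasize(recording.samples, config.preemphasis_alpha)
    frames, times = frame_signal(emphasized, recording.sample_rate, config)
    esd = energy_spectral_density(frames)
    log_fbe = mel_filterbank_log_energies(esd, recording.sample_rate, config)
    values = cepstrum(log_fbe, config)
    return FrameFeatureMatrix(values=values, frame_times_s=times, config=config)
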