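"""MFCC chain: each step against closed forms plus an independent reference."""

import numpy as np
import pytest

from anurascore.mfcc import (MFCCConfig, cepstrum, energy_spectral_density,
                             extract_mfcc, frame_signal, full_cepstrum,
                             hz_to_mel, inverse_cepstrum, mel_filter_centers_hz,
                             mel_filterbank, mel_filterbank_log_energies,
                             mel_to_hz, next_pow2, preemphasize)
from anurascore.synth import AudioRecording


class TestPreemphasis:
    def test_impulse(self):
        assert np.allclose(preemphasize([1.0, 0.0, 0.0], 0.97),
                           [0.03, -0.97, 0.0])

    def test_constant_signal_attenuated_to_dc_gain(self):
        y = preemphasize(np.full(10, 5.0), 0.97)
        assert np.allclose(y, (1 - 0.97) * 5.0)

    def test_alpha_zero_is_identity(self):
        x = np.arange(6, dtype=float)
        assert np.array_equal(preemphasize(x, 0.0), x)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            preemphasize(np.array([]), 0.97)


class TestFraming:
    def test_frame_length_1102_at_44khz(self):
        frames, _ = frame_signal(np.zeros(44100), 44100, MFCCConfig())
        assert frames.shape[1] == 1102

    def test_five_second_signal_gives_498_frames(self):
        frames, times = frame_signal(np.zeros(220500), 44100, MFCCConfig())
        assert frames.shape[0] == (220500 - 1102) // 441 + 1 == 498
        # strictly increasing with the 10 ms hop step
        assert np.allclose(np.diff(times), 0.010)

    def test_exact_window_gives_single_frame(self):
        frames, _ = frame_signal(np.zeros(1102), 44100, MFCCConfig())
        assert frames.shape[0] == 1

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            frame_signal(np.zeros(1101), 44100, MFCCConfig())

    def test_hamming_window_applied(self):
        frames, _ = frame_signal(np.ones(1102), 44100, MFCCConfig())
        assert np.allclose(frames[0], np.hamming(1102))


class TestEnergySpectralDensity:
    def test_zero_frame(self):
        assert np.all(energy_spectral_density(np.zeros(100)) == 0.0)

    def test_unit_impulse_is_flat(self):
        x = np.zeros(64)
        x[0] = 1.0
        assert np.allclose(energy_spectral_density(x), 1.0)

    def test_parseval(self, rng):
        x = rng.standard_normal(700)
        esd = energy_spectral_density(x)
        nfft = next_pow2(700)
        # one-sided bookkeeping: interior bins count twice
        total = esd[0] + esd[-1] + 2.0 * esd[1:-1].sum()
        assert total == pytest.approx(nfft * np.sum(x ** 2), rel=1e-9)


class TestMelFilterbank:
    def test_centers_match_closed_form(self):
        centers = mel_filter_centers_hz(MFCCConfig())
        lo, hi = 2595 * np.log10(1 + 300 / 700), 2595 * np.log10(1 + 3700 / 700)
        mels = lo + (hi - lo) * np.arange(1, 21) / 21.0
        expected = 700 * (10 ** (mels / 2595) - 1)
        assert np.max(np.abs(centers - expected)) < 1e-6

    def test_mel_scale_round_trip(self):
        f = np.array([300.0, 1000.0, 3700.0])
        assert np.allclose(mel_to_hz(hz_to_mel(f)), f)

    def test_tone_at_filter_center_dominates_that_filter(self):
        config = MFCCConfig()
        fs = 44100
        f10 = mel_filter_centers_hz(config)[9]
        t = np.arange(1102) / fs
        frame = np.sin(2 * np.pi * f10 * t) * np.hamming(1102)
        esd = energy_spectral_density(frame)
        energies = mel_filterbank(2048, fs, config) @ esd
        assert np.argmax(energies) == 9

    def test_zero_esd_hits_log_floor(self):
        out = mel_filterbank_log_energies(np.zeros(1025), 44100, MFCCConfig())
        assert np.allclose(out, np.log(1e-12))

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            mel_filterbank(2048, 6000, MFCCConfig())   # 3700 > 3000


class TestCepstrum:
    def test_constant_log_energies_give_zero_coefficients(self):
        out = cepstrum(np.full(20, 3.7), MFCCConfig())
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_sine_lifter_gain_at_n1(self):
        le = np.zeros(20)
        le[0] = 1.0
        plain = cepstrum(le, MFCCConfig(lifter_l=0))
        liftered = cepstrum(le, MFCCConfig())
        expected = 1.0 + 11.0 * np.sin(np.pi / 22.0)
        assert liftered[0] / plain[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.5655, abs=5e-4)

    def test_dct_round_trip_is_identity(self, rng):
        le = rng.standard_normal(20)
        coeffs = full_cepstrum(le, MFCCConfig())
        assert np.max(np.abs(inverse_cepstrum(coeffs, 20) - le)) < 1e-9

    def test_nonfinite_input_rejected(self):
        le = np.full(20, -np.inf)
        with pytest.raises(ValueError):
            cepstrum(le, MFCCConfig())


class TestExtract:
    def test_deterministic_and_shape(self, rng):
        samples = rng.standard_normal(220500) * 0.1
        rec = AudioRecording(samples=samples, sample_rate=44100, class_label=1)
        a = extract_mfcc(rec)
        b = extract_mfcc(rec)
        assert a.values.shape == (498, 13)
        assert np.array_equal(a.values, b.values)

    def test_gain_invariance_without_floor(self, rng):
        config = MFCCConfig(log_floor=0.0)
        x = rng.standard_normal(22050) * 0.05
        a = extract_mfcc(AudioRecording(x, 44100, 1), config)
        b = extract_mfcc(AudioRecording(10.0 * x, 44100, 1), config)
        # the 2*ln(g) level shift lives entirely in the discarded c0
        assert np.max(np.abs(a.values - b.values)) < 1e-8

    def test_gain_shifts_log_energies_by_2_ln_g(self, rng):
        config = MFCCConfig(log_floor=0.0)
        x = rng.standard_normal(4096) * 0.05
        esd = energy_spectral_density(x)
        base = mel_filterbank_log_energies(esd, 44100, config)
        scaled = mel_filterbank_log_energies(energy_spectral_density(3.0 * x),
                                             44100, config)
        assert np.allclose(scaled - base, 2.0 * np.log(3.0), atol=1e-9)


def _reference_mfcc(samples, fs, config):
    """Independent per-step reference implementation (plain loops/formulas)."""
    import math
    x = np.asarray(samples, dtype=float)
    y = np.empty_like(x)
    y[0] = (1 - config.preemphasis_alpha) * x[0]
    for n in range(1, x.size):
        y[n] = x[n] - config.preemphasis_alpha * x[n - 1]
    win = int(config.window_ms * fs / 1000)
    hop = int(config.hop_ms * fs / 1000)
    ham = np.array([0.54 - 0.46 * math.cos(2 * math.pi * i / (win - 1))
                    for i in range(win)])
    nfft = 1
    while nfft < win:
        nfft *= 2
    mel = lambda f: 2595.0 * math.log10(1.0 + f / 700.0)
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    edges = [imel(mel(config.band_low_hz)
                  + (mel(config.band_high_hz) - mel(config.band_low_hz))
                  * i / (config.n_filters + 1))
             for i in range(config.n_filters + 2)]
    out = []
    n_frames = (x.size - win) // hop + 1
    for fi in range(n_frames):
        frame = y[fi * hop: fi * hop + win] * ham
        spec = np.fft.rfft(frame, nfft)
        esd = (spec.real ** 2 + spec.imag ** 2)
        fbe = []
        for k in range(config.n_filters):
            acc = 0.0
            for b in range(esd.size):
                f = b * fs / nfft
                if edges[k] <= f <= edges[k + 1]:
                    w = (f - edges[k]) / (edges[k + 1] - edges[k])
                elif edges[k + 1] < f <= edges[k + 2]:
                    w = (edges[k + 2] - f) / (edges[k + 2] - edges[k + 1])
                else:
                    w = 0.0
                acc += w * esd[b]
            fbe.append(math.log(max(acc, config.log_floor)))
        ceps = []
        for n in range(1, config.n_ceps_kept + 1):
            c = sum(fbe[m] * math.cos(math.pi * n * (m + 0.5) / config.n_filters)
                    for m in range(config.n_filters))
            c *= math.sqrt(2.0 / config.n_filters)
            lift = 1.0 + (config.lifter_l / 2.0) * math.sin(
                math.pi * n / config.lifter_l)
            ceps.append(c * lift)
        out.append(ceps)
    return np.array(out)


def test_extract_matches_independent_reference(rng):
    config = MFCCConfig()
    fs = 44100
    samples = rng.standard_normal(int(0.12 * fs)) * 0.1
    rec = AudioRecording(samples=samples, sample_rate=fs, class_label=1)
    ours = extract_mfcc(rec, config).values
    ref = _reference_mfcc(samples, fs, config)
    assert ours.shape == ref.shape
    assert np.max(np.abs(ours - ref)) < 1e-6
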