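import warnings

import numpy as np
import pytest

from anurascore.synth import CallTemplate, SynthConfig, generate_dataset

# sklearn convergence chatter (MLP at small max_iter, LogReg on tiny folds)
# is expected in the scaled-down test runs
warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


def fast_templates() -> dict[int, CallTemplate]:
    """Short-call templates for low-sample-rate, short-recording test runs."""
    return {
        1: CallTemplate(carrier_hz=1500.0, pulse_rate_hz=15.0,
                        call_duration_ms=400.0, calls_per_recording=1),
        2: CallTemplate(carrier_hz=900.0, pulse_rate_hz=40.0,
                        call_duration_ms=150.0, calls_per_recording=1),
        3: CallTemplate(carrier_hz=2600.0, pulse_rate_hz=6.0,
                        call_duration_ms=350.0, calls_per_recording=1),
        4: CallTemplate(carrier_hz=3300.0, pulse_rate_hz=25.0,
                        call_duration_ms=250.0, calls_per_recording=1),
    }


def fast_config(n_recordings: int, seed: int = 0, duration_s: float = 1.0,
                sample_rate: int = 8000, snr_db: float = 10.0,
                proportions=(0.25, 0.25, 0.25, 0.25)) -> SynthConfig:
    return SynthConfig(n_recordings=n_recordings,
                       class_proportions=proportions,
                       class_templates=fast_templates(),
                       recording_duration_s=duration_s,
                       noise_snr_db=snr_db, sample_rate=sample_rate, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_noisefree_dataset():
    """28 noise-free recordings, exactly 7 per class, 8 kHz.

    Balanced by drawing from a larger pool so every cross-validation role
    sees every class — the fixture is meant to be perfectly separable.
    """
    pool = generate_dataset(fast_config(80, seed=3, snr_db=np.inf))
    by_class = {c: [r for r in pool if r.class_label == c] for c in (1, 2, 3, 4)}
    return [r for c in (1, 2, 3, 4) for r in by_class[c][:7]]


@pytest.fixture(scope="session")
def small_noisy_dataset():
    return generate_dataset(fast_config(24, seed=5, snr_db=10.0))
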