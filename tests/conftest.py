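import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from drowsyfuse import synthgen
from drowsyfuse.sigio import SignalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eeg_record():
    spec = synthgen.EEGSynthSpec(
        "alert", duration_s=20.0, fs=128.0,
        band_weights={"delta": 1, "theta": 1, "alpha": 1, "beta": 1},
        noise_sd=0.2, seed=5,
    )
    return synthgen.gen_eeg(spec, n_channels=2)


@pytest.fixture
def ecg_record_with_truth():
    spec = synthgen.ECGSynthSpec(
        duration_s=60.0, fs=256.0, mean_rr_ms=800.0, rr_jitter_sd_ms=20.0, seed=3
    )
    return synthgen.gen_ecg(spec)


@pytest.fixture(scope="session")
def eeg_preset_table():
    """200 epochs of alert/fatigued preset EEG through the full
    preprocess -> feature-extraction path. Session-scoped: extraction is
    the most expensive fixture in the suite (~1 min)."""
    from drowsyfuse import preprocess, sigio
    from drowsyfuse.eeg_features import extract_eeg_features
    from drowsyfuse.sigio import FeatureTable

    parts = []
    for state, seed in (("alert", 10), ("fatigued", 11)):
        spec = synthgen.eeg_preset(state, duration_s=500.0, seed=seed)
        rec = preprocess.preprocess_eeg(synthgen.gen_eeg(spec, 2))
        epochs = sigio.epoch_signal(rec, 5.0)
        epochs.labels = np.array([state] * epochs.n_epochs)
        parts.append(extract_eeg_features(epochs))
    values = np.vstack([p.values for p in parts])
    labels = np.concatenate([p.labels for p in parts])
    return FeatureTable(values, parts[0].feature_names, labels)


@pytest.fixture
def tone_record():
    def make(freq_hz, fs=256.0, duration_s=10.0, modality="EEG"):
        t = np.arange(int(duration_s * fs)) / fs
        return SignalRecord(
            np.sin(2 * np.pi * freq_hz * t)[None, :], fs, ["tone"], modality
        )

    return make
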