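"""Signal containers, file I/O, epoching, and run configuration.

Signals travel as :class:`SignalRecord` (channels x samples with a sampling
rate), are cut into fixed-length :class:`EpochSet` windows, and feature
extractors emit :class:`FeatureTable` rows (one per epoch).

File formats: CSV with a mandatory header row of channel names, one row
per sample (time implicit as row index / fs); NPZ for lossless round
trips; feature tables as CSV with a trailing ``label`` column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

ALERT = "alert"
FATIGUED = "fatigued"

_MODALITIES = ("EEG", "ECG")


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass
class SignalRecord:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz, > 0.
    channel_names : sequence of str
        Unique, one per channel.
    modality : {"EEG", "ECG"}
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    modality: str = "EEG"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select_channels(self, names: Sequence[str]) -> "SignalRecord":
        """Return a record restricted to ``names``, in the requested order."""
        idx = []
        for name in names:
            if name not in self.channel_names:
                raise KeyError(f"channel {name!r} not in {self.channel_names}")
            idx.append(self.channel_names.index(name))
        return SignalRecord(self.data[idx], self.fs, list(names), self.modality)


@dataclass
class EpochSet:
    """Fixed-length windows cut from a SignalRecord."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    epoch_len_s: float
    fs: float
    channel_names: Sequence[str] = field(default_factory=list)
    modality: str = "EEG"
    labels: Optional[np.ndarray] = None  # per-epoch, e.g. "alert"/"fatigued"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        n = round(self.epoch_len_s * self.fs)
        if abs(self.epoch_len_s * self.fs - n) > 1e-9:
            raise ValueError("epoch_len_s * fs must be an integer sample count")
        if self.epochs.shape[0] and self.epochs.shape[2] != n:
            raise ValueError("epoch sample count inconsistent with epoch_len_s")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.epochs.shape[0]:
                raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class FeatureTable:
    """Per-epoch numeric feature vectors with optional state labels."""

    values: np.ndarray  # (n_rows, n_features)
    feature_names: Sequence[str]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.feature_names = list(self.feature_names)
        if self.values.size and self.values.shape[1] != len(self.feature_names):
            raise ValueError("row length must match feature_names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("one label per row required")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path: str) -> None:
        # 17 significant digits: round-trips float64 exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=float), list(df.columns), labels)


def read_signal(
    path: str,
    fs: float,
    modality: str = "EEG",
    channels: Optional[Sequence[str]] = None,
) -> SignalRecord:
    """Read a CSV (header = channel names) or NPZ signal file.

    ``channels`` optionally selects a named subset in the given order,
    e.g. ``["P3", "P4"]`` from a 32-channel file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            data = z["data"]
            names = [str(s) for s in z["channel_names"]]
            fs = float(z["fs"]) if "fs" in z else fs
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if df.isna().any().any():
            raise FormatError(f"{path}: ragged or missing values")
        names = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=float).T
    rec = SignalRecord(data, fs, names, modality)
    if channels is not None:
        rec = rec.select_channels(channels)
    return rec


def write_signal(rec: SignalRecord, path: str) -> None:
    """Write a SignalRecord as CSV (one column per channel) or NPZ."""
    if path.endswith(".npz"):
        np.savez(
            path,
            data=rec.data,
            fs=rec.fs,
            channel_names=np.array(rec.channel_names),
        )
    else:
        pd.DataFrame(rec.data.T, columns=list(rec.channel_names)).to_csv(
            path, index=False, float_format="%.17g"
        )


def epoch_signal(
    rec: SignalRecord, epoch_len_s: float = 5.0, overlap_frac: float = 0.0
) -> EpochSet:
    """Cut a record into fixed-length epochs with fractional overlap.

    Epochs tile the record from t=0 with stride
    ``epoch_len_s * (1 - overlap_frac)``; a trailing partial epoch is
    dropped. Raises ValueError if the record is shorter than one epoch.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    n_epoch = round(epoch_len_s * rec.fs)
    if abs(epoch_len_s * rec.fs - n_epoch) > 1e-9:
        raise ValueError("epoch_len_s * fs must be an integer sample count")
    if rec.n_samples < n_epoch:
        raise ValueError(
            f"record ({rec.n_samples} samples) shorter than one epoch ({n_epoch})"
        )
    stride = max(1, round(n_epoch * (1 - overlap_frac)))
    starts = range(0, rec.n_samples - n_epoch + 1, stride)
    blocks = np.stack([rec.data[:, s : s + n_epoch] for s in starts])
    return EpochSet(
        blocks, epoch_len_s, rec.fs, list(rec.channel_names), rec.modality
    )


DEFAULT_CONFIG = {
    "fs": {"eeg": 128.0, "ecg": 256.0},
    "channels": ["P3", "P4"],
    "epoch_len_s": 5.0,
    "overlap_frac": 0.0,
    "preprocess": {
        "eeg": {"low_hz": 0.15, "high_hz": 40.0, "notch_hz": 50.0,
                "notch_q": 30.0, "order": 4},
        "ecg": {"low_hz": 0.1, "high_hz": 30.0, "order": 4},
    },
    "entropy": {"m": 2, "r": 0.2, "n_fuzzy": 2},
    "qrs": {"sim_threshold": 0.3, "kernel_len": 15, "refractory_ms": 250.0},
    "fusion": {"window_s": 5, "persist_s": 3.0, "dictionary": "listed"},
    "seed": 0,
}


def load_config(path: Optional[str] = None) -> dict:
    """Load YAML run configuration, merged over the defaults."""
    cfg = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_copy(d: dict) -> dict:
    return {k: _deep_copy(v) if isinstance(v, dict) else v for k, v in d.items()}


def _deep_update(base: dict, other: dict) -> None:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
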