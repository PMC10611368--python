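"""Synthetic EEG, ECG, label-stream, and fixture-image generators.

Everything downstream (preprocessing, feature extraction, classification,
fusion) is exercisable on the output of this module alone. Generators are
pure functions of their spec, including the seed.

EEG is synthesised as a sum of band-limited noise components (filtered
white noise per canonical band) so that entropy features stay
non-degenerate; expected band powers are proportional to the requested
band weights. ECG is a train of PQRST-like Gaussian-bump templates at
beat times with controllable mean RR, Gaussian jitter, and a slow
sinusoidal drift. The alert/fatigued EEG presets are conventions for
separability testing only, not physiological claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.signal as sps

from drowsyfuse.sigio import ALERT, FATIGUED, SignalRecord

#: Canonical EEG bands (Hz): delta, theta, alpha, beta.
EEG_BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: Label alphabet per fusion row: (normal, abnormal).
ROW_ALPHABETS: Tuple[Tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5), (6, 7))


@dataclass
class EEGSynthSpec:
    """Parameters for synthetic EEG generation."""

    state: str = ALERT
    duration_s: float = 10.0
    fs: float = 128.0
    band_weights: Dict[str, float] = field(
        default_factory=lambda: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0}
    )
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in (ALERT, FATIGUED):
            raise ValueError(f"state must be {ALERT!r} or {FATIGUED!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        unknown = set(self.band_weights) - set(EEG_BANDS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band weights must be >= 0")
        top = max(high for _, high in EEG_BANDS.values())
        if self.fs < 2 * top:
            raise ValueError(f"fs must be >= {2 * top} Hz (2x highest band edge)")


@dataclass
class ECGSynthSpec:
    """Parameters for synthetic ECG generation."""

    duration_s: float = 60.0
    fs: float = 256.0
    mean_rr_ms: float = 800.0
    rr_jitter_sd_ms: float = 20.0
    rr_drift: float = 0.0  # relative amplitude of slow sinusoidal RR modulation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 300 <= self.mean_rr_ms <= 2000:
            raise ValueError("mean_rr_ms must be in [300, 2000]")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if self.rr_jitter_sd_ms < 0:
            raise ValueError("rr_jitter_sd_ms must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


@dataclass
class ScenarioScript:
    """Ordered (duration_s, row_labels) segments for a 4-row label stream."""

    segments: List[Tuple[int, Tuple[int, int, int, int]]]
    seed: int = 0

    def __post_init__(self) -> None:
        for dur, labels in self.segments:
            if dur < 0:
                raise ValueError("segment duration must be >= 0")
            if len(labels) != 4:
                raise ValueError("row_labels must have one label per fusion row")
            for row, lab in enumerate(labels):
                if lab not in ROW_ALPHABETS[row]:
                    raise ValueError(
                        f"label {lab} not in row-{row + 1} alphabet {ROW_ALPHABETS[row]}"
                    )


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: Tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise via 4th-order Butterworth."""
    white = rng.standard_normal(n)
    low, high = band
    high = min(high, 0.999 * fs / 2)
    if low <= 0:
        sos = sps.butter(4, high, btype="lowpass", fs=fs, output="sos")
    else:
        sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_eeg(spec: EEGSynthSpec, n_channels: int = 2) -> SignalRecord:
    """Generate ``n_channels`` of synthetic EEG per ``spec``.

    Each channel is an independent sum of per-band noise components scaled
    to ``sqrt(weight)`` (expected power proportional to the weight) plus
    white noise of sd ``noise_sd``.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    data = np.zeros((n_channels, n))
    for ch in range(n_channels):
        for band_name, band in EEG_BANDS.items():
            w = spec.band_weights.get(band_name, 0.0)
            if w > 0:
                data[ch] += np.sqrt(w) * _band_noise(rng, n, spec.fs, band)
        if spec.noise_sd > 0:
            data[ch] += spec.noise_sd * rng.standard_normal(n)
    # P3/P4 naming for the first two channels by convention
    names = ["P3", "P4"][:n_channels] + [f"CH{i + 1}" for i in range(2, n_channels)]
    return SignalRecord(data, spec.fs, names, "EEG")


def eeg_preset(state: str, duration_s: float = 10.0, fs: float = 128.0,
               seed: int = 0) -> EEGSynthSpec:
    """Convention presets for separability tests (config-overridable).

    Fatigued: theta/alpha-dominant, weak beta, less broadband noise.
    Alert: beta-dominant with more broadband noise.
    """
    if state == FATIGUED:
        weights = {"delta": 1.0, "theta": 3.0, "alpha": 2.5, "beta": 0.5}
        noise_sd = 0.1
    elif state == ALERT:
        weights = {"delta": 1.0, "theta": 0.8, "alpha": 1.0, "beta": 3.0}
        noise_sd = 0.4
    else:
        raise ValueError(f"unknown state {state!r}")
    return EEGSynthSpec(state, duration_s, fs, weights, noise_sd, seed)


# PQRST template: (offset_ms from R, amplitude, width_ms) per bump.
_PQRST = (
    (-200.0, 0.15, 25.0),   # P
    (-35.0, -0.12, 10.0),   # Q
    (0.0, 1.00, 12.0),      # R
    (35.0, -0.20, 10.0),    # S
    (250.0, 0.30, 60.0),    # T
)


def gen_ecg(spec: ECGSynthSpec) -> Tuple[SignalRecord, np.ndarray]:
    """Generate a synthetic single-lead ECG and its true R-peak times.

    Beat-to-beat intervals are ``mean_rr_ms`` perturbed by
    N(0, rr_jitter_sd_ms^2) plus a slow (0.1 Hz) sinusoidal drift of
    relative amplitude ``rr_drift``. Returns (record, r_times_seconds).
    """
    rng = np.random.default_rng(spec.seed)
    mean_rr_s = spec.mean_rr_ms / 1000.0
    jitter_s = spec.rr_jitter_sd_ms / 1000.0

    r_times = []
    t = 0.4  # first beat offset so the P wave fits
    while t < spec.duration_s - 0.3:
        r_times.append(t)
        drift = spec.rr_drift * np.sin(2 * np.pi * 0.1 * t)
        rr = mean_rr_s * (1.0 + drift) + jitter_s * rng.standard_normal()
        rr = max(rr, 0.3)  # physiological floor
        t += rr
    r_times = np.asarray(r_times)

    n = int(round(spec.duration_s * spec.fs))
    time = np.arange(n) / spec.fs
    sig = np.zeros(n)
    for r in r_times:
        for off_ms, amp, width_ms in _PQRST:
            mu = r + off_ms / 1000.0
            sd = width_ms / 1000.0
            lo = max(0, int((mu - 5 * sd) * spec.fs))
            hi = min(n, int((mu + 5 * sd) * spec.fs) + 1)
            if lo < hi:
                sig[lo:hi] += amp * np.exp(-0.5 * ((time[lo:hi] - mu) / sd) ** 2)
    rec = SignalRecord(sig[None, :], spec.fs, ["ECG"], "ECG")
    return rec, r_times


def gen_label_stream(script: ScenarioScript) -> np.ndarray:
    """Expand a scenario script into a 4-row label matrix (one column/second)."""
    cols: List[Sequence[int]] = []
    for dur, labels in script.segments:
        cols.extend([labels] * int(dur))
    if not cols:
        return np.zeros((4, 0), dtype=int)
    return np.asarray(cols, dtype=int).T


def gen_images(
    n_per_class: int,
    classes: Sequence[int] = (0, 1),
    size: int = 64,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render trivially separable fixture images, one geometric motif per class.

    Motifs cycle through: centered disc, horizontal bar, vertical bar,
    ring. Positions and brightness jitter slightly per image. Returns
    (images uint8 (n, size, size, 3), labels int array).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if size < 8:
        raise ValueError("size must be >= 8 px")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    images, labels = [], []
    for ci, cls in enumerate(classes):
        motif = ci % 4
        for _ in range(n_per_class):
            img = np.zeros((size, size), dtype=float)
            cx = size / 2 + rng.uniform(-size / 10, size / 10)
            cy = size / 2 + rng.uniform(-size / 10, size / 10)
            bright = rng.uniform(0.7, 1.0)
            if motif == 0:  # disc
                mask = (xx - cx) ** 2 + (yy - cy) ** 2 < (size / 5) ** 2
            elif motif == 1:  # horizontal bar
                mask = np.abs(yy - cy) < size / 10
            elif motif == 2:  # vertical bar
                mask = np.abs(xx - cx) < size / 10
            else:  # ring
                r2 = (xx - cx) ** 2 + (yy - cy) ** 2
                mask = (r2 < (size / 4) ** 2) & (r2 > (size / 6) ** 2)
            img[mask] = bright
            img += 0.05 * rng.random((size, size))
            rgb = np.clip(img * 255, 0, 255).astype(np.uint8)
            images.append(np.stack([rgb] * 3, axis=-1))
            labels.append(cls)
    return np.stack(images), np.asarray(labels, dtype=int)
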