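"""R-peak detection by sinusoid matched filtering and HRV statistics.

The QRS kernel is ``sin`` evaluated at 15 equally spaced phases from
1.5*pi to 3.5*pi (a single positive lobe flanked by negative half-lobes).
Detection correlates the locally z-scored signal with the unit-norm
kernel, picks correlation maxima above a similarity threshold separated
by a refractory period, and snaps each to the nearest signal maximum.

HRV statistics keep the source formulas verbatim, including the
nonstandard moment denominators: RMSSD and SDRR divide by N-1, while
skewness and kurtosis divide by N*SDRR^k with SDRR computed using N-1
(a "textbook" variant with standard denominators is available behind a
flag but off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.signal as sps

from drowsyfuse.sigio import EpochSet, FeatureTable, SignalRecord

logger = logging.getLogger(__name__)

HRV_FEATURES = ("rmssd", "avrr", "sdrr", "skew", "kurt")


@dataclass
class QRSConfig:
    """Matched-filter configuration.

    kernel_phase spans (1.5*pi, 3.5*pi); 15 taps; similarity threshold
    0.3; refractory 250 ms (~240 bpm ceiling).
    """

    kernel_phase: tuple = (1.5 * np.pi, 3.5 * np.pi)
    kernel_len: int = 15
    sim_threshold: float = 0.3
    refractory_ms: float = 250.0
    snap_ms: float = 50.0
    resample_kernel: bool = False  # duration-matched kernel (~60 ms) for high fs

    def __post_init__(self) -> None:
        if self.kernel_len < 3:
            raise ValueError("kernel_len must be >= 3")
        if not 0 < self.sim_threshold < 1:
            raise ValueError("sim_threshold must be in (0, 1)")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be > 0")


@dataclass
class RPeakSeries:
    """Detected R-peak sample positions (strictly ascending)."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class RRSeries:
    """Successive R-peak intervals in milliseconds."""

    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if np.any(self.intervals_ms <= 0):
            raise ValueError("RR intervals must be > 0")

    @property
    def N(self) -> int:
        return len(self.intervals_ms)


@dataclass
class HRVFeatures:
    rmssd: float
    avrr: float
    sdrr: float
    skew: float  # nan when sdrr == 0
    kurt: float  # excess kurtosis; nan when sdrr == 0

    def as_array(self) -> np.ndarray:
        return np.array([self.rmssd, self.avrr, self.sdrr, self.skew, self.kurt])


def qrs_kernel(cfg: Optional[QRSConfig] = None, fs: Optional[float] = None) -> np.ndarray:
    """The matched-filter taps: sin over [1.5*pi, 3.5*pi] inclusive.

    With the default 15 taps: tap[0] = tap[14] = -1 and tap[7] = +1.
    If ``cfg.resample_kernel`` and ``fs`` are given, the tap count is
    chosen so the kernel spans ~60 ms at that sampling rate.
    """
    cfg = cfg or QRSConfig()
    n = cfg.kernel_len
    if cfg.resample_kernel and fs is not None:
        n = max(3, int(round(0.060 * fs)) | 1)  # odd, ~60 ms support
    return np.sin(np.linspace(cfg.kernel_phase[0], cfg.kernel_phase[1], n))


def _zscore_local(x: np.ndarray, fs: float, block_s: float = 2.0) -> np.ndarray:
    """Z-score against a centered 2 s moving mean/SD (amplitude-free,
    shift-equivariant away from the edges)."""
    from scipy.ndimage import uniform_filter1d

    block = max(2, int(block_s * fs))
    mean = uniform_filter1d(x, block, mode="nearest")
    sq = uniform_filter1d(x**2, block, mode="nearest")
    sd = np.sqrt(np.clip(sq - mean**2, 0, None))
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def detect_r_peaks(rec: SignalRecord, cfg: Optional[QRSConfig] = None) -> RPeakSeries:
    """Locate R-peaks in a preprocessed single-/first-channel ECG record.

    Computes a sliding normalized correlation between the locally
    z-scored signal and the unit-norm kernel (each window also amplitude
    normalized, so the similarity lies in [-1, 1]), takes correlation
    local maxima above ``sim_threshold`` with refractory spacing, and
    snaps each to the nearest signal maximum within ``snap_ms``.
    """
    cfg = cfg or QRSConfig()
    x = np.asarray(rec.data[0], dtype=float)
    fs = rec.fs
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if not np.any(x):
        logger.warning("all-zero signal: no peaks")
        return RPeakSeries(np.array([], dtype=int), fs)

    kernel = qrs_kernel(cfg, fs)
    kernel = kernel / np.linalg.norm(kernel)
    z = _zscore_local(x, fs)

    # normalized cross-correlation: dot with unit-norm kernel over the
    # window's own norm -> cosine similarity in [-1, 1]
    num = np.correlate(z, kernel, mode="same")
    win = np.ones(len(kernel))
    denom = np.sqrt(np.clip(np.correlate(z**2, win, mode="same"), 1e-12, None))
    sim = num / denom

    refractory = max(1, int(cfg.refractory_ms / 1000.0 * fs))
    cand, _ = sps.find_peaks(sim, height=cfg.sim_threshold, distance=refractory)
    if len(cand) == 0:
        logger.warning("no peaks above similarity threshold %.2f", cfg.sim_threshold)
        return RPeakSeries(np.array([], dtype=int), fs)

    snap = max(1, int(cfg.snap_ms / 1000.0 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - snap), min(len(x), c + snap + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # unique() guarantees ascending; enforce refractory after snapping
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
    return RPeakSeries(np.asarray(keep), fs)


def rr_intervals(peaks: RPeakSeries) -> RRSeries:
    """Successive peak-index differences in milliseconds; N = len - 1."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks for RR intervals")
    diffs = np.diff(peaks.indices) / peaks.fs * 1000.0
    return RRSeries(diffs)


def hrv_features(rr: RRSeries, textbook: bool = False) -> HRVFeatures:
    """The five HRV statistics from an RR series (N >= 4).

    rmssd = sqrt(sum(diff(RR)^2) / (N-1)); avrr = mean; sdrr = sample SD;
    skew = sum((RR-avrr)^3) / (N * sdrr^3); kurt (excess) analogous.
    With ``textbook=True``, skew/kurt use the conventional 1/N central
    moments over the biased SD instead.
    """
    x = rr.intervals_ms
    n = rr.N
    if n < 4:
        raise ValueError("need N >= 4 RR intervals (kurtosis)")
    d = np.diff(x)
    rmssd = float(np.sqrt(np.sum(d**2) / (n - 1)))
    avrr = float(np.sum(x) / n)
    sdrr = float(np.sqrt(np.sum((x - avrr) ** 2) / (n - 1)))
    if sdrr == 0:
        logger.warning("sdrr == 0: skew/kurt undefined")
        return HRVFeatures(rmssd, avrr, sdrr, float("nan"), float("nan"))
    if textbook:
        sd_b = float(np.sqrt(np.mean((x - avrr) ** 2)))
        skew = float(np.mean((x - avrr) ** 3) / sd_b**3)
        kurt = float(np.mean((x - avrr) ** 4) / sd_b**4 - 3.0)
    else:
        skew = float(np.sum((x - avrr) ** 3) / (n * sdrr**3))
        kurt = float(np.sum((x - avrr) ** 4) / (n * sdrr**4) - 3.0)
    return HRVFeatures(rmssd, avrr, sdrr, skew, kurt)


def extract_ecg_features(
    epochs: EpochSet, cfg: Optional[QRSConfig] = None
) -> FeatureTable:
    """Per-epoch R-peak detection + HRV; undefined rows dropped and logged.

    Note: at the default 5 s epoch length an epoch holds only a handful
    of beats, so HRV moments are noisy; longer epochs give stabler rows.
    """
    if epochs.modality != "ECG":
        raise ValueError("extract_ecg_features requires ECG epochs")
    cfg = cfg or QRSConfig()
    rows, keep = [], []
    for i in range(epochs.n_epochs):
        rec = SignalRecord(
            epochs.epochs[i, :1], epochs.fs, [epochs.channel_names[0]], "ECG"
        )
        try:
            peaks = detect_r_peaks(rec, cfg)
            rr = rr_intervals(peaks)
            feats = hrv_features(rr)
            row = feats.as_array()
        except ValueError:
            row = np.full(5, np.nan)
        rows.append(row)
        if np.all(np.isfinite(row)):
            keep.append(i)
        else:
            logger.warning("epoch %d dropped: undefined HRV feature", i)
    values = np.asarray(rows, dtype=float)[keep]
    labels = epochs.labels[keep] if epochs.labels is not None else None
    return FeatureTable(values.reshape(len(keep), 5), list(HRV_FEATURES), labels)
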