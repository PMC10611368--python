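"""Per-channel EEG features: four band powers and four entropies.

Band power is the area under the Welch power spectral density between
the canonical band edges (delta 0-4, theta 4-8, alpha 8-12, beta
12-30 Hz), integrated trapezoidally.

Entropies follow the standard literature definitions: sample entropy
excludes self-matches (Richman-Moorman), approximate entropy includes
them (Pincus), and fuzzy entropy replaces the hard tolerance with an
exponential membership function on mean-subtracted templates. The
tolerance ``r`` is a fraction of the series standard deviation, so all
three are invariant to amplitude scaling. Degenerate inputs (no matches,
constant series) yield ``nan`` rather than infinities; downstream
extraction flags and excludes those rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.signal as sps

from drowsyfuse.sigio import EpochSet, FeatureTable
from drowsyfuse.synthgen import EEG_BANDS

logger = logging.getLogger(__name__)

#: Spectral-entropy band: the EEG passband.
SPECTRAL_BAND = (0.15, 40.0)

ENTROPY_FEATURES = ("fuzzy_en", "sample_en", "spectral_en", "approx_en")
BAND_FEATURES = tuple(EEG_BANDS)  # delta, theta, alpha, beta
ALL_FEATURES = BAND_FEATURES + ENTROPY_FEATURES


@dataclass
class EntropyConfig:
    m: int = 2          # embedding (template) length
    r: float = 0.2      # tolerance as a fraction of the series SD
    n_fuzzy: int = 2    # fuzzy membership exponent

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.n_fuzzy < 1:
            raise ValueError("n_fuzzy must be >= 1")


def _welch_psd(x: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    # 1 s segments, 50% overlap, Hann window; falls back to one segment
    nperseg = min(len(x), int(fs))
    return sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                     window="hann")


def band_power(x: np.ndarray, fs: float, band: Tuple[float, float]) -> float:
    """Area under the Welch PSD between ``band`` edges (trapezoidal)."""
    low, high = band
    if low < 0 or high > fs / 2 or low >= high:
        raise ValueError(f"band {band} outside [0, fs/2={fs / 2}]")
    x = np.asarray(x, dtype=float)
    freqs, psd = _welch_psd(x, fs)
    mask = (freqs >= low) & (freqs <= high)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """All sliding templates of length m: shape (n - m + 1, m)."""
    n = len(x)
    return np.lib.stride_tricks.sliding_window_view(x, m) if n >= m else np.empty((0, m))


def _chebyshev_pdist_max(a: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distance matrix; fine for epoch-scale n."""
    return np.max(np.abs(a[:, None, :] - a[None, :, :]), axis=-1)


def sample_entropy(x: np.ndarray, cfg: Optional[EntropyConfig] = None) -> float:
    """Sample entropy -ln(A/B), self-matches excluded.

    A counts template pairs of length m+1 within Chebyshev distance
    r*SD(x); B the same for length m, both over the first N-m templates.
    Returns nan if the series is constant or no pairs match.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    m = cfg.m
    if len(x) < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples")
    sd = x.std()
    if sd == 0:
        return float("nan")
    tol = cfg.r * sd

    n_templ = len(x) - m  # so both m- and (m+1)-templates exist
    tm = _embed(x, m)[:n_templ]
    tm1 = _embed(x, m + 1)[:n_templ]
    db = _chebyshev_pdist_max(tm)
    da = _chebyshev_pdist_max(tm1)
    iu = np.triu_indices(n_templ, k=1)
    b = int(np.count_nonzero(db[iu] <= tol))
    a = int(np.count_nonzero(da[iu] <= tol))
    if a == 0 or b == 0:
        logger.warning("sample_entropy undefined: A=%d, B=%d", a, b)
        return float("nan")
    return float(-np.log(a / b))


def approximate_entropy(x: np.ndarray, cfg: Optional[EntropyConfig] = None) -> float:
    """Approximate entropy Phi^m - Phi^{m+1}, self-matches included."""
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    m = cfg.m
    if len(x) < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples")
    sd = x.std()
    tol = cfg.r * sd

    def phi(mm: int) -> float:
        templ = _embed(x, mm)
        d = _chebyshev_pdist_max(templ)
        # self-matches (diagonal zeros) counted, so counts >= 1
        counts = np.count_nonzero(d <= tol, axis=1)
        return float(np.mean(np.log(counts / templ.shape[0])))

    return phi(m) - phi(m + 1)


def fuzzy_entropy(x: np.ndarray, cfg: Optional[EntropyConfig] = None) -> float:
    """Fuzzy entropy -ln(phi^{m+1}/phi^m) with exponential membership.

    Templates are mean-subtracted; distances map through
    mu(d) = exp(-(d / (r*SD))^n_fuzzy); phi averages mu over distinct
    template pairs. Returns nan for a constant series.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    m = cfg.m
    if len(x) < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples")
    sd = x.std()
    if sd == 0:
        return float("nan")
    tol = cfg.r * sd

    def phi(mm: int) -> float:
        templ = _embed(x, mm)[: len(x) - m]
        templ = templ - templ.mean(axis=1, keepdims=True)
        d = _chebyshev_pdist_max(templ)
        mu = np.exp(-((d / tol) ** cfg.n_fuzzy))
        iu = np.triu_indices(templ.shape[0], k=1)
        return float(np.mean(mu[iu]))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return float("nan")
    return float(-np.log(p_m1 / p_m))


def spectral_entropy(
    x: np.ndarray,
    fs: float,
    band: Tuple[float, float] = SPECTRAL_BAND,
) -> float:
    """Normalized Shannon entropy of the PSD over ``band``.

    The PSD bins inside the band are normalized to a probability
    distribution; the Shannon entropy (natural log) is divided by
    log(#bins) so the result lies in [0, 1]. Zero signal -> nan.

    Uses up to 4 s Welch segments (vs 1 s for band power): a narrowband
    signal needs fine bin spacing for its concentration to register.
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(len(x), int(4 * fs))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                           window="hann")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    p = psd[mask]
    total = p.sum()
    if total <= 0 or len(p) < 2:
        return float("nan")
    p = p / total
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / np.log(len(p)))


def channel_features(
    x: np.ndarray, fs: float, cfg: Optional[EntropyConfig] = None
) -> Dict[str, float]:
    """The 8 features for one epoch of one channel."""
    cfg = cfg or EntropyConfig()
    feats = {name: band_power(x, fs, EEG_BANDS[name]) for name in BAND_FEATURES}
    feats["fuzzy_en"] = fuzzy_entropy(x, cfg)
    feats["sample_en"] = sample_entropy(x, cfg)
    feats["spectral_en"] = spectral_entropy(x, fs)
    feats["approx_en"] = approximate_entropy(x, cfg)
    return feats


def extract_eeg_features(
    epochs: EpochSet, cfg: Optional[EntropyConfig] = None
) -> FeatureTable:
    """One row per epoch, 8 features per channel (e.g. ``P3_delta`` ...).

    Rows containing undefined (non-finite) features are dropped and
    logged rather than propagated into training.
    """
    if epochs.modality != "EEG":
        raise ValueError("extract_eeg_features requires EEG epochs")
    cfg = cfg or EntropyConfig()
    names = [
        f"{ch}_{feat}" for ch in epochs.channel_names for feat in ALL_FEATURES
    ]
    rows, keep = [], []
    for i in range(epochs.n_epochs):
        row = []
        for c in range(epochs.epochs.shape[1]):
            fd = channel_features(epochs.epochs[i, c], epochs.fs, cfg)
            row.extend(fd[f] for f in ALL_FEATURES)
        rows.append(row)
        if np.all(np.isfinite(row)):
            keep.append(i)
        else:
            logger.warning("epoch %d dropped: undefined entropy feature", i)
    values = np.asarray(rows, dtype=float)[keep]
    labels = epochs.labels[keep] if epochs.labels is not None else None
    return FeatureTable(values.reshape(len(keep), len(names)), names, labels)
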