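"""Noise-reduction filters for EEG and ECG records.

EEG: 0.15-40 Hz band-pass plus a 50 Hz power-line notch.
ECG: 0.1-30 Hz band-pass plus linear detrending.

All filters are zero-phase (applied forward and backward), preserve the
record's shape and sampling rate, and operate on the continuous record
before epoching so edge transients stay out of the analysis windows.
"""

from __future__ import annotations

import numpy as np
import scipy.signal as sps

from drowsyfuse.sigio import SignalRecord

EEG_BAND = (0.15, 40.0)
ECG_BAND = (0.1, 30.0)
NOTCH_HZ = 50.0
NOTCH_Q = 30.0
FILTER_ORDER = 4


def _check_edge(edge: float, fs: float, what: str) -> None:
    if not 0 < edge < fs / 2:
        raise ValueError(f"{what} {edge} Hz outside (0, fs/2={fs / 2}) Hz")


def bandpass(
    rec: SignalRecord,
    low_hz: float,
    high_hz: float,
    order: int = FILTER_ORDER,
) -> SignalRecord:
    """Zero-phase Butterworth band-pass, per channel."""
    _check_edge(low_hz, rec.fs, "low edge")
    _check_edge(high_hz, rec.fs, "high edge")
    if low_hz >= high_hz:
        raise ValueError("low_hz must be < high_hz")
    sos = sps.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos"
    )
    # the sub-Hz low edge has multi-second transients: even-extend by the
    # full record so the slow poles settle before the kept samples
    out = sps.sosfiltfilt(
        sos, rec.data, axis=-1, padtype="even", padlen=rec.n_samples - 1
    )
    return SignalRecord(out, rec.fs, list(rec.channel_names), rec.modality)


def notch(rec: SignalRecord, center_hz: float = NOTCH_HZ, q: float = NOTCH_Q) -> SignalRecord:
    """Zero-phase IIR notch at ``center_hz`` (power-line removal)."""
    _check_edge(center_hz, rec.fs, "notch center")
    b, a = sps.iirnotch(center_hz, q, fs=rec.fs)
    out = sps.filtfilt(b, a, rec.data, axis=-1)
    return SignalRecord(out, rec.fs, list(rec.channel_names), rec.modality)


def detrend(rec: SignalRecord) -> SignalRecord:
    """Remove the per-channel best-fit linear trend (baseline offset)."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to detrend")
    out = sps.detrend(rec.data, axis=-1, type="linear")
    return SignalRecord(out, rec.fs, list(rec.channel_names), rec.modality)


def preprocess_eeg(
    rec: SignalRecord,
    low_hz: float = EEG_BAND[0],
    high_hz: float = EEG_BAND[1],
    notch_hz: float = NOTCH_HZ,
    notch_q: float = NOTCH_Q,
    order: int = FILTER_ORDER,
) -> SignalRecord:
    """EEG composite: band-pass then power-line notch."""
    out = bandpass(rec, low_hz, high_hz, order)
    if notch_hz < rec.fs / 2:
        out = notch(out, notch_hz, notch_q)
    return out


def preprocess_ecg(
    rec: SignalRecord,
    low_hz: float = ECG_BAND[0],
    high_hz: float = ECG_BAND[1],
    order: int = FILTER_ORDER,
) -> SignalRecord:
    """ECG composite: band-pass then linear detrend."""
    return detrend(bandpass(rec, low_hz, high_hz, order))


def tone_attenuation_db(
    fs: float, tone_hz: float, pipeline, duration_s: float = 10.0
) -> float:
    """Attenuation (dB) of a unit sinusoid at ``tone_hz`` through ``pipeline``.

    Utility for verifying filter responses; ``pipeline`` maps
    SignalRecord -> SignalRecord. RMS is measured over the central half
    to ignore filter edge effects.
    """
    t = np.arange(int(duration_s * fs)) / fs
    rec = SignalRecord(np.sin(2 * np.pi * tone_hz * t)[None, :], fs, ["tone"])
    out = pipeline(rec)
    n = rec.n_samples
    sl = slice(n // 4, 3 * n // 4)
    rms_in = np.sqrt(np.mean(rec.data[0, sl] ** 2))
    rms_out = np.sqrt(np.mean(out.data[0, sl] ** 2))
    if rms_out == 0:
        return np.inf
    return 20 * np.log10(rms_in / rms_out)
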