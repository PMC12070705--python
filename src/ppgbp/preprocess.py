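"""Signal conditioning: band-pass, mains notch, [0, 1] normalization, PSD.

The PPG channel is band-passed 0.05–30 Hz and the ECG channel 0.05–140 Hz,
each followed by a 48–52 Hz band-stop against 50 Hz mains interference.
All filters are Butterworth, realised as second-order sections (the 0.05 Hz
low cut at a 500 Hz sampling rate is numerically stiff in transfer-function
form) and applied forward-backward so the conditioned waveform is
zero-phase: fiducial indices are not shifted by filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, InvalidArgumentError
from .signal import Signal


@dataclass
class FilterSpec:
    """Band-pass specification; ``notch_band`` documents the companion
    band-stop stage applied after the band-pass."""

    low_cut: float
    high_cut: float
    order: int = 4
    notch_band: Tuple[float, float] = (48.0, 52.0)

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 <= self.low_cut < self.high_cut):
            raise InvalidArgumentError(
                f"need 0 <= low_cut < high_cut, got ({self.low_cut}, {self.high_cut})")
        if self.high_cut >= nyq:
            raise InvalidArgumentError(
                f"high_cut {self.high_cut} Hz must be below Nyquist {nyq} Hz")
        lo, hi = self.notch_band
        if not (0 < lo < hi < nyq):
            raise InvalidArgumentError(
                f"notch band {self.notch_band} must lie inside (0, {nyq}) Hz")
        if self.order < 1:
            raise InvalidArgumentError("filter order must be >= 1")


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    return sps.butter(spec.order, [spec.low_cut, spec.high_cut],
                      btype="bandpass", fs=fs, output="sos")


def _bandstop_sos(band: Tuple[float, float], order: int, fs: float) -> np.ndarray:
    return sps.butter(order, list(band), btype="bandstop", fs=fs, output="sos")


def _apply_sos(sos: np.ndarray, sig: Signal) -> np.ndarray:
    # Even-symmetric padding of a few seconds keeps the forward-backward
    # transient of the 0.05 Hz corner small when a record ends mid-beat.
    padlen = min(len(sig) - 1, int(round(3.0 * sig.fs)))
    return sps.sosfiltfilt(sos, sig.samples, padtype="even", padlen=padlen)


def bandpass(sig: Signal, spec: FilterSpec) -> Signal:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    spec.validate(sig.fs)
    return sig.with_samples(_apply_sos(_bandpass_sos(spec, sig.fs), sig))


def notch(sig: Signal, band: Tuple[float, float] = (48.0, 52.0), order: int = 4) -> Signal:
    """Zero-phase Butterworth band-stop over ``band`` (mains rejection)."""
    nyq = sig.fs / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise InvalidArgumentError(f"notch band {band} must lie inside (0, {nyq}) Hz")
    return sig.with_samples(_apply_sos(_bandstop_sos(band, order, sig.fs), sig))


def frequency_response(sos: np.ndarray, freqs: np.ndarray, fs: float,
                       zero_phase: bool = True) -> np.ndarray:
    """|H(f)| of a designed SOS filter; squared when applied forward-backward."""
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    mag = np.abs(h)
    return mag ** 2 if zero_phase else mag


def bandpass_response(spec: FilterSpec, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Amplitude response of the band-pass stage as actually applied
    (forward-backward, hence magnitude squared)."""
    return frequency_response(_bandpass_sos(spec, fs), freqs, fs)


def notch_response(band: Tuple[float, float], order: int, freqs: np.ndarray,
                   fs: float) -> np.ndarray:
    return frequency_response(_bandstop_sos(band, order, fs), freqs, fs)


def normalize(sig: Signal) -> Signal:
    """Affine rescaling of the samples onto [0, 1].

    S_N = (S - S_min) / (S_max - S_min).  Order-preserving, idempotent.
    A constant signal has no dynamic range and raises
    :class:`DegenerateSignalError` rather than silently returning zeros.
    """
    s = sig.samples
    lo, hi = float(np.min(s)), float(np.max(s))
    if hi <= lo:
        raise DegenerateSignalError("cannot normalize a constant signal")
    return sig.with_samples((s - lo) / (hi - lo))


def psd(sig: Signal, segment_seconds: Optional[float] = 4.0) -> Tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density.

    Segment length defaults to 4 s (or the whole record when shorter),
    Hann window, 50% overlap — scipy's defaults otherwise.
    """
    n = len(sig)
    nperseg = n if segment_seconds is None else min(n, int(round(segment_seconds * sig.fs)))
    if nperseg < 2:
        raise InvalidArgumentError("record shorter than one PSD segment")
    freqs, power = sps.welch(sig.samples, fs=sig.fs, nperseg=nperseg)
    return freqs, power


def condition(sig: Signal, spec: FilterSpec, notch_order: int = 4,
              do_normalize: bool = True) -> Signal:
    """Full conditioning chain: band-pass, mains band-stop, then [0,1]
    normalization (normalization happens after filtering, before fiducial
    detection)."""
    out = bandpass(sig, spec)
    out = notch(out, spec.notch_band, order=notch_order)
    if do_normalize:
        out = normalize(out)
    return out
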