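"""Fiducial detection: PPG systolic peaks, feet (valleys), dicrotic
notches, ECG R-peaks, and per-beat outlier rejection.

The dicrotic notch is located through the first derivative of the PPG.
With the default ``zero_crossing`` rule the notch is the minus-to-plus sign
change of the derivative between the systolic peak and the next foot — the
local minimum separating the systolic and diastolic waves.  The alternate
``derivative_peak`` rule takes the local maximum of the derivative in the
same interval (the steepest point of the diastolic rise) instead.  Beats
with no qualifying extremum keep the notch unset; an index is never
fabricated.

"Valley" throughout means the beat foot: the minimum preceding the
systolic upstroke, not the trough after the notch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .errors import EmptyResultError, InsufficientSignalError, InvalidArgumentError
from .signal import BeatFiducials, RPeaks, Signal

logger = logging.getLogger(__name__)


def detect_peaks_valleys(ppg: Signal, min_distance_s: float = 0.25,
                         prominence: float = 0.5) -> List[BeatFiducials]:
    """Detect systolic peaks and the feet between them.

    Peaks are prominence-gated local maxima at least ``min_distance_s``
    apart; each beat's foot is the minimum between the previous peak (or
    record start) and the current peak.  Emits one
    :class:`BeatFiducials` per peak that has a following foot, so a record
    with ``k`` peaks yields ``k - 1`` complete beats.
    """
    x = ppg.samples
    distance = max(1, int(round(min_distance_s * ppg.fs)))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence)
    if peaks.size < 2:
        raise InsufficientSignalError(
            f"found {peaks.size} systolic peaks; at least 2 beats required")
    feet = []
    prev = 0
    for p in peaks:
        feet.append(prev + int(np.argmin(x[prev:p + 1])))
        prev = p
    beats = []
    for k in range(len(peaks) - 1):
        if feet[k] < peaks[k] < feet[k + 1]:
            beats.append(BeatFiducials(valley_idx=feet[k], peak_idx=int(peaks[k]),
                                       next_valley_idx=feet[k + 1]))
    if len(beats) < 1:
        raise InsufficientSignalError("no complete foot-peak-foot beat found")
    return beats


def count_peaks(ppg: Signal, min_distance_s: float = 0.25,
                prominence: float = 0.5) -> int:
    """Number of systolic peaks in the record (pulse count)."""
    distance = max(1, int(round(min_distance_s * ppg.fs)))
    peaks, _ = sps.find_peaks(ppg.samples, distance=distance, prominence=prominence)
    return int(peaks.size)


def detect_notch(ppg: Signal, beats: Sequence[BeatFiducials],
                 method: str = "zero_crossing") -> List[BeatFiducials]:
    """Set the dicrotic notch on each beat via the PPG first derivative.

    ``zero_crossing``: first minus-to-plus sign change of the central-
    difference derivative strictly inside (peak, next valley) — the local
    minimum between systolic and diastolic waves.  ``derivative_peak``:
    largest interior local maximum of the derivative in the same interval.
    Beats with no qualifying extremum are returned with the notch unset.
    """
    if method not in ("zero_crossing", "derivative_peak"):
        raise InvalidArgumentError(f"unknown notch method {method!r}")
    deriv = np.gradient(ppg.samples)
    out: List[BeatFiducials] = []
    for b in beats:
        notch_idx: Optional[int] = None
        lo, hi = b.peak_idx + 1, b.next_valley_idx  # interior samples
        if hi - lo >= 3:
            d = deriv[lo:hi]
            if method == "zero_crossing":
                crossings = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))
                if crossings.size:
                    cand = lo + int(crossings[0]) + 1
                    # require a genuine diastolic rise after the minimum
                    if np.any(d[crossings[0] + 1:] > 0):
                        notch_idx = cand
            else:
                interior = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
                if interior.size:
                    notch_idx = lo + int(interior[np.argmax(d[interior])])
        if notch_idx is not None and not (b.peak_idx < notch_idx < b.next_valley_idx):
            notch_idx = None
        out.append(BeatFiducials(valley_idx=b.valley_idx, peak_idx=b.peak_idx,
                                 next_valley_idx=b.next_valley_idx,
                                 notch_idx=notch_idx))
    return out


def detect_r_peaks(ecg: Signal, min_distance_s: float = 0.25,
                   height_frac: float = 0.5,
                   rr_bounds_s: Tuple[float, float] = (0.25, 2.0)) -> RPeaks:
    """Detect ECG R-peaks: local maxima above ``height_frac`` of the record
    maximum, at least ``min_distance_s`` apart.  R-R intervals outside
    ``rr_bounds_s`` after detection flag the shorter-prominence peak for
    removal."""
    x = ecg.samples
    rng_amp = float(np.max(x) - np.min(x))
    if rng_amp <= 0:
        raise InsufficientSignalError("flat ECG signal")
    height = np.min(x) + height_frac * rng_amp
    distance = max(1, int(round(min_distance_s * ecg.fs)))
    peaks, props = sps.find_peaks(x, height=height, distance=distance)
    if peaks.size < 2:
        raise InsufficientSignalError(
            f"found {peaks.size} R-peaks; at least 2 required")
    # Drop peaks creating sub-physiological intervals (keep the taller one).
    keep = list(peaks)
    lo_s, hi_s = rr_bounds_s
    changed = True
    while changed and len(keep) >= 2:
        changed = False
        for i in range(len(keep) - 1):
            rr = (keep[i + 1] - keep[i]) / ecg.fs
            if rr < lo_s:
                drop = i if x[keep[i]] < x[keep[i + 1]] else i + 1
                del keep[drop]
                changed = True
                break
    if len(keep) < 2:
        raise InsufficientSignalError("fewer than 2 R-peaks after interval gating")
    return RPeaks(indices=np.asarray(keep, dtype=int), fs=ecg.fs)


@dataclass
class RejectionLog:
    """Record of outlier-beat removals (index into the input list, reason)."""

    removed: List[Tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.removed)


def reject_outlier_beats(beats: Sequence[BeatFiducials], ppg: Signal,
                         mad_factor: float = 3.0) -> Tuple[List[BeatFiducials], RejectionLog]:
    """Remove beats whose peak-to-peak interval or systolic amplitude lies
    outside median ± ``mad_factor`` robust scale units across the record.

    The scale is the MAD-based robust sigma (1.4826·MAD) with a
    measurement-resolution floor — one sample period for intervals, 1% of
    the median for amplitudes — so a clean record, whose beat-to-beat
    spread is quantization-dominated and whose MAD is vanishingly small,
    rejects nothing.
    """
    if len(beats) < 3:
        raise InvalidArgumentError("need at least 3 beats for outlier rejection")
    x = ppg.samples
    # Interval criterion: each beat's nearest peak-to-peak spacing.  Peaks
    # are sharp (sample-accurate) where feet are soft, and taking the
    # nearer neighbour makes the gate insensitive to gaps left by
    # previously removed beats, so a second pass is a no-op; a spurious
    # extra detection still shows up as a short spacing on both sides.
    peaks = np.array([b.peak_idx for b in beats], dtype=float)
    gaps = np.diff(peaks)
    ppi = np.minimum(np.concatenate([[np.inf], gaps]),
                     np.concatenate([gaps, [np.inf]]))
    amp = np.array([x[b.peak_idx] - x[b.valley_idx] for b in beats])

    log = RejectionLog()
    keep = np.ones(len(beats), dtype=bool)
    floors = {"peak_to_peak_interval": 1.0,  # one sample period
              "systolic_amplitude": 0.01 * float(np.abs(np.median(amp)))}
    for name, series in (("peak_to_peak_interval", ppi), ("systolic_amplitude", amp)):
        med = np.median(series)
        scale = max(1.4826 * float(np.median(np.abs(series - med))), floors[name])
        bad = np.abs(series - med) > mad_factor * scale
        for i in np.flatnonzero(bad & keep):
            log.removed.append((int(i), f"{name} outside median ± {mad_factor}·MAD"))
        keep &= ~bad
    kept = [b for b, k in zip(beats, keep) if k]
    if not kept:
        raise EmptyResultError("all beats rejected as outliers")
    if log.removed:
        logger.info("rejected %d of %d beats: %s", len(log), len(beats), log.removed)
    return kept, log
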