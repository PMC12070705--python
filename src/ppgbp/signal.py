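"""Core waveform and fiducial containers.

A :class:`Signal` is a uniformly sampled single-channel waveform (PPG, one
of its derivatives, or single-lead ECG).  :class:`BeatFiducials` holds the
per-beat landmark indices (foot/valley, systolic peak, dicrotic notch,
next foot) that the morphological features are computed from, and
:class:`RPeaks` the ECG R-wave sample indices used for heart rate and
pulse transit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError

PPG = "PPG"
PPG_D1 = "PPG_d1"
PPG_D2 = "PPG_d2"
ECG = "ECG"

_KINDS = (PPG, PPG_D1, PPG_D2, ECG)


@dataclass
class Signal:
    """Uniformly sampled waveform.

    Parameters
    ----------
    samples : array of float, arbitrary units
    fs : sampling rate in Hz
    kind : one of ``PPG``, ``PPG_d1``, ``PPG_d2``, ``ECG``
    subject_id, phase : optional provenance labels carried through the
        pipeline unchanged.
    """

    samples: np.ndarray
    fs: float
    kind: str = PPG
    subject_id: Optional[str] = None
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidArgumentError("signal must be a 1-D array with at least 2 samples")
        if self.kind not in _KINDS:
            raise InvalidArgumentError(f"unknown signal kind {self.kind!r}; expected one of {_KINDS}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, kind: Optional[str] = None) -> "Signal":
        """Copy of this signal with new samples (labels preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass
class BeatFiducials:
    """Landmark sample indices of one PPG beat.

    ``valley_idx`` is the beat foot (onset), ``next_valley_idx`` the foot of
    the following beat.  ``notch_idx`` is the dicrotic notch and is ``None``
    for beats where no notch is detectable (e.g. absent diastolic wave) —
    absence is represented, never fabricated.
    """

    valley_idx: int
    peak_idx: int
    next_valley_idx: int
    notch_idx: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.valley_idx < self.peak_idx < self.next_valley_idx):
            raise InvalidArgumentError(
                f"fiducial ordering violated: valley {self.valley_idx} < peak "
                f"{self.peak_idx} < next valley {self.next_valley_idx} required")
        if self.notch_idx is not None and not (self.peak_idx < self.notch_idx < self.next_valley_idx):
            raise InvalidArgumentError(
                f"notch {self.notch_idx} must lie strictly between peak "
                f"{self.peak_idx} and next valley {self.next_valley_idx}")

    def shifted(self, k: int) -> "BeatFiducials":
        return BeatFiducials(
            valley_idx=self.valley_idx + k,
            peak_idx=self.peak_idx + k,
            next_valley_idx=self.next_valley_idx + k,
            notch_idx=None if self.notch_idx is None else self.notch_idx + k,
        )


@dataclass
class RPeaks:
    """ECG R-wave peak indices on a common time base."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise InvalidArgumentError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    @property
    def intervals(self) -> np.ndarray:
        """R-R intervals in seconds."""
        return np.diff(self.indices) / self.fs


def write_signal(sig: Signal, path: str | Path) -> None:
    """Write a signal as two-column delimited text (time_s, amplitude)."""
    data = np.column_stack([sig.times, sig.samples])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t",
               header="time_s\tamplitude", comments="")


def read_signal(path: str | Path, kind: str = PPG) -> Signal:
    """Read a two-column (time_s, amplitude) delimited-text signal.

    The sampling rate is recovered from the median time step.
    """
    data = np.loadtxt(path, skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise InvalidArgumentError(f"{path}: expected two columns (time_s, amplitude)")
    dt = np.median(np.diff(data[:, 0]))
    if dt <= 0:
        raise InvalidArgumentError(f"{path}: time column must be increasing")
    return Signal(samples=data[:, 1], fs=1.0 / dt, kind=kind)


def fiducials_to_rows(beats: Sequence[BeatFiducials]) -> list[dict]:
    """Beat fiducials as plain dict rows (CSV-exportable)."""
    return [
        {"beat_id": i, "valley_idx": b.valley_idx, "peak_idx": b.peak_idx,
         "notch_idx": -1 if b.notch_idx is None else b.notch_idx,
         "next_valley_idx": b.next_valley_idx}
        for i, b in enumerate(beats)
    ]
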