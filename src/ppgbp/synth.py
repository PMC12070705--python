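"""Synthetic PPG/ECG cohort generator.

No recordings accompany the analysis this package implements, so every
downstream stage is exercised against simulated 30-s, 500 Hz two-channel
records with known ground truth.  Each PPG beat is the sum of two Gaussian
lobes — a systolic wave and a smaller, later diastolic wave — whose local
minimum in between is an explicit dicrotic notch; the ECG channel is a
train of narrow Gaussian R-waves, each preceding its beat's systolic peak
by the configured pulse transit time (PTT).  Smoking-phase presets modulate
heart rate, beat amplitude, notch timing, baseline drift and PTT, emulating
the acute changes seen across before/during/after smoking measurements.

Cohort generation ties waveform morphology to blood pressure through an
explicit generative law,

    SBP = a0 + a1/PTT + a2*AI + eps,   DBP = b0 + b1/PTT + b2*AI + eps,

with AI the augmentation index (systolic over diastolic wave amplitude) and
eps Gaussian.  The law makes no physiological claim beyond the inverse
PTT–BP relation; its purpose is a recoverable signal for end-to-end tests.

Seeding: one root seed; per-subject generators are spawned from
``numpy.random.SeedSequence(root).spawn(n_subjects)`` so any subject's
record is reproducible independently of cohort size or iteration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import default_config
from .errors import InvalidArgumentError
from .signal import ECG, PPG, BeatFiducials, RPeaks, Signal

HABITS = ("NC", "EC", "SH")
SMOKER_CLASSES = ("LS", "MS", "HS", "HSS")
PHASES = ("before", "during", "after_5", "after_10", "after_20", "after_30", "after_40")

#: Reserved (non-feature) columns of a cohort table, in schema order.
META_COLUMNS = ["subject_id", "habit", "phase", "provenance", "sbp_ref", "dbp_ref"]


@dataclass
class BeatModel:
    """Two-Gaussian pulse template.

    Centers are fractions of the beat period, widths are seconds.
    ``notch_offset`` shifts the diastolic lobe (and with it the notch)
    later in the beat.
    """

    systolic_amp: float = 1.0
    diastolic_amp: float = 0.45
    systolic_center: float = 0.16
    diastolic_center: float = 0.46
    systolic_width: float = 0.05
    diastolic_width: float = 0.06
    notch_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.systolic_center < self.diastolic_center + self.notch_offset < 1.0):
            raise InvalidArgumentError(
                "need 0 < systolic_center < diastolic_center (+offset) < 1")
        if not (0.0 <= self.diastolic_amp < self.systolic_amp):
            raise InvalidArgumentError("diastolic_amp must be in [0, systolic_amp)")
        if self.systolic_width <= 0 or self.diastolic_width <= 0:
            raise InvalidArgumentError("widths must be positive")

    def render(self, t_rel: np.ndarray, period: float) -> np.ndarray:
        """Template amplitude at times ``t_rel`` (s) relative to beat onset."""
        t = np.asarray(t_rel, dtype=float)
        cs = self.systolic_center * period
        cd = (self.diastolic_center + self.notch_offset) * period
        out = self.systolic_amp * np.exp(-0.5 * ((t - cs) / self.systolic_width) ** 2)
        if self.diastolic_amp > 0:
            out = out + self.diastolic_amp * np.exp(-0.5 * ((t - cd) / self.diastolic_width) ** 2)
        return out

    def _periodized(self, t_rel: np.ndarray, period: float) -> np.ndarray:
        """Template plus its immediate periodic neighbours (for landmark
        analysis near the beat foot, where the previous beat's tail matters)."""
        return (self.render(t_rel, period)
                + self.render(t_rel + period, period)
                + self.render(t_rel - period, period))

    def landmarks(self, period: float, resolution: float = 5e-5) -> Dict[str, Optional[float]]:
        """Continuous-time landmark positions of one beat of the periodic
        pulse train: foot, systolic peak, dicrotic notch, diastolic peak
        (seconds relative to beat onset; notch/diastolic peak are ``None``
        when the template has no inter-wave minimum), plus the amplitudes
        needed for the augmentation index."""
        t = np.arange(-0.4 * period, 1.05 * period, resolution)
        w = self._periodized(t, period)
        half = int(round(0.5 * period / resolution))
        origin = int(round(0.4 * period / resolution))
        # systolic peak: maximum in [0, 0.5 T)
        seg = slice(origin, origin + half)
        i_peak = origin + int(np.argmax(w[seg]))
        # foot: minimum in [-0.3 T, t_peak]
        lo = int(round(0.1 * period / resolution))
        i_foot = lo + int(np.argmin(w[lo:i_peak + 1]))
        t_peak, t_foot = t[i_peak], t[i_foot]
        # notch: first interior local minimum after the systolic peak
        t_notch = t_dias = None
        tail = w[i_peak:]
        d = np.diff(tail)
        rising = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))  # local minima
        if rising.size:
            i_notch = i_peak + int(rising[0]) + 1
            falling = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0))
            falling = falling[falling > rising[0]]
            if falling.size and t[i_notch] < period:
                i_dias = i_peak + int(falling[0]) + 1
                t_notch, t_dias = t[i_notch], t[i_dias]
        amp_foot = w[i_foot]
        result: Dict[str, Optional[float]] = {
            "t_foot": float(t_foot), "t_peak": float(t_peak),
            "t_notch": None if t_notch is None else float(t_notch),
            "t_dias": None if t_dias is None else float(t_dias),
            "systolic_amp": float(w[i_peak] - amp_foot),
            "diastolic_amp": None,
        }
        if t_dias is not None:
            i_dias = int(round((t_dias + 0.4 * period) / resolution))
            result["diastolic_amp"] = float(w[i_dias] - amp_foot)
        return result


@dataclass
class PhasePreset:
    """Morphology modulation for one smoking phase.

    ``hr_shift`` raises heart rate (bpm); ``amp_modulation_depth`` applies a
    slow sinusoidal beat-amplitude modulation (the amplitude fluctuation
    seen during smoking); ``notch_shift`` relocates the dicrotic notch later
    in the beat (fraction of the period); ``baseline_drift_amp`` adds
    low-frequency baseline wander; ``ptt_shift`` (s) shortens or lengthens
    the pulse transit time, the handle through which a phase moves blood
    pressure under the generative law.
    """

    phase: str = "before"
    hr_shift: float = 0.0
    amp_modulation_depth: float = 0.0
    notch_shift: float = 0.0
    baseline_drift_amp: float = 0.0
    ptt_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InvalidArgumentError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not (0.0 <= self.amp_modulation_depth < 1.0):
            raise InvalidArgumentError("amp_modulation_depth must be in [0, 1)")


def phase_preset(name: str, config: Optional[dict] = None) -> PhasePreset:
    """The configured preset for a phase name."""
    cfg = config or default_config()
    try:
        params = cfg["synth"]["phase_presets"][name]
    except KeyError as exc:
        raise InvalidArgumentError(f"no preset configured for phase {name!r}") from exc
    return PhasePreset(phase=name, **params)


@dataclass
class SubjectSpec:
    """One synthetic subject: identity, smoking labels and resting
    physiology.  ``ptt_p`` is the R-peak to systolic-peak transit time and
    ``diastolic_amp`` the relative diastolic wave height — the two latents
    the generative blood-pressure law acts on."""

    subject_id: str
    habit: str = "NC"
    smoker_class: str = "LS"
    baseline_hr: float = 80.0
    baseline_sbp: float = 120.0
    baseline_dbp: float = 75.0
    rng_seed: int = 0
    ptt_p: float = 0.25
    diastolic_amp: float = 0.45

    def __post_init__(self) -> None:
        if self.habit not in HABITS:
            raise InvalidArgumentError(f"habit must be one of {HABITS}")
        if self.smoker_class not in SMOKER_CLASSES:
            raise InvalidArgumentError(f"smoker_class must be one of {SMOKER_CLASSES}")
        if not (40.0 <= self.baseline_hr <= 180.0):
            raise InvalidArgumentError("baseline_hr must be within [40, 180] bpm")
        if not (self.baseline_sbp > self.baseline_dbp > 0):
            raise InvalidArgumentError("need SBP > DBP > 0")


@dataclass
class NoiseSpec:
    """Additive disturbances: 50 Hz mains interference plus white Gaussian
    noise at a signal-to-noise ratio in dB (relative to the clean AC RMS)."""

    mains_amp: float = 0.02
    mains_freq: float = 50.0
    snr_db: Optional[float] = 30.0


@dataclass
class RecordTruth:
    """Ground truth accompanying one generated record: per-beat fiducial
    indices, R-peak indices, and the generative latents."""

    beats: List[BeatFiducials]
    r_peaks: RPeaks
    latents: Dict[str, float] = field(default_factory=dict)


@dataclass
class BPLaw:
    """Linear-in-(1/PTT, AI) generative blood-pressure law."""

    sbp: Tuple[float, float, float] = (35.0, 20.0, 3.0)
    dbp: Tuple[float, float, float] = (28.0, 11.0, 1.5)
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not any(self.sbp) and not any(self.dbp):
            warnings.warn("degenerate blood-pressure law: all coefficients zero",
                          stacklevel=3)

    def mean_bp(self, ptt: float, ai: float) -> Tuple[float, float]:
        a0, a1, a2 = self.sbp
        b0, b1, b2 = self.dbp
        return a0 + a1 / ptt + a2 * ai, b0 + b1 / ptt + b2 * ai

    @classmethod
    def from_config(cls, config: Optional[dict] = None) -> "BPLaw":
        cfg = (config or default_config())["synth"]["bp_law"]
        return cls(sbp=tuple(cfg["sbp"]), dbp=tuple(cfg["dbp"]),
                   noise_sd=float(cfg["noise_sd_mmhg"]))


def _argmin_window(x: np.ndarray, lo: int, hi: int) -> int:
    lo = max(lo, 0)
    hi = min(hi, x.size)
    return lo + int(np.argmin(x[lo:hi]))


def _argmax_window(x: np.ndarray, lo: int, hi: int) -> int:
    lo = max(lo, 0)
    hi = min(hi, x.size)
    return lo + int(np.argmax(x[lo:hi]))


def generate_record(spec: SubjectSpec, preset: PhasePreset,
                    duration: float = 30.0, fs: float = 500.0,
                    noise: Optional[NoiseSpec] = None,
                    beat: Optional[BeatModel] = None,
                    config: Optional[dict] = None,
                    ) -> Tuple[Signal, Signal, RecordTruth]:
    """Render one two-channel record for a subject under a phase preset.

    Returns the PPG channel, the ECG channel (equal length) and the exact
    ground-truth fiducials.  ``noise=None`` renders a noise-free record.
    """
    cfg = (config or default_config())["synth"]
    if fs < 100.0:
        raise InvalidArgumentError(f"fs must be >= 100 Hz, got {fs}")
    hr = spec.baseline_hr + preset.hr_shift
    if hr <= 0:
        raise InvalidArgumentError("effective heart rate must be positive")
    period = 60.0 / hr
    if duration < 2.0 * period:
        raise InvalidArgumentError(
            f"duration {duration}s holds fewer than two beats at {hr:.0f} bpm")

    beat_cfg = cfg["beat"]
    base = beat if beat is not None else BeatModel(
        systolic_amp=beat_cfg["systolic_amp"],
        diastolic_amp=spec.diastolic_amp,
        systolic_center=beat_cfg["systolic_center"],
        diastolic_center=beat_cfg["diastolic_center"],
        # widths are configured as fractions of the beat period so the
        # pulse shape (and notch visibility) is heart-rate invariant
        systolic_width=beat_cfg["systolic_width_frac"] * period,
        diastolic_width=beat_cfg["diastolic_width_frac"] * period,
        notch_offset=beat_cfg["notch_offset"],
    )
    model = replace(base, notch_offset=base.notch_offset + preset.notch_shift)
    marks = model.landmarks(period)
    t_peak_rel = marks["t_peak"]

    ptt_p = spec.ptt_p + preset.ptt_shift
    if ptt_p <= 0:
        raise InvalidArgumentError("effective PTT must be positive")
    # First beat placed so that its R-wave falls inside the record.
    t0 = max(0.0, ptt_p - t_peak_rel) + 0.05
    onsets = np.arange(t0, duration, period)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.rng_seed)

    f_mod = cfg["amp_modulation_freq"]
    mod = 1.0 + preset.amp_modulation_depth * np.sin(2 * np.pi * f_mod * onsets)

    ppg = np.zeros(n)
    margin = 0.45 * period
    for onset, m in zip(onsets, mod):
        lo = max(0, int(np.floor((onset - margin) * fs)))
        hi = min(n, int(np.ceil((onset + period + margin) * fs)))
        ppg[lo:hi] += m * model.render(t[lo:hi] - onset, period)

    # ECG: narrow Gaussian R-waves, one per beat, PTT before the PPG peak.
    r_times = onsets + t_peak_rel - ptt_p
    r_times = r_times[(r_times >= 0) & (r_times < duration)]
    ecg = np.zeros(n)
    r_w = cfg["ecg_r_width"]
    for rt in r_times:
        lo = max(0, int(np.floor((rt - 6 * r_w) * fs)))
        hi = min(n, int(np.ceil((rt + 6 * r_w) * fs)))
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - rt) / r_w) ** 2)

    # Ground-truth fiducials from the pristine composite.
    peaks_rel = onsets + t_peak_rel
    peaks_rel = peaks_rel[peaks_rel < duration - 1.0 / fs]
    half = int(round(0.25 * period * fs))
    peak_idx = [_argmax_window(ppg, int(round(p * fs)) - half, int(round(p * fs)) + half + 1)
                for p in peaks_rel]
    foot_idx = [_argmin_window(ppg, int(round((onset + marks["t_foot"]) * fs)) - half,
                               pk + 1)
                for onset, pk in zip(onsets, peak_idx)]
    notch_win = int(round(0.08 * period * fs))
    beats: List[BeatFiducials] = []
    truth_beat_count = len(peak_idx)
    for k in range(len(peak_idx) - 1):
        notch_i: Optional[int] = None
        if marks["t_notch"] is not None:
            center = int(round((onsets[k] + marks["t_notch"]) * fs))
            cand = _argmin_window(ppg, center - notch_win, center + notch_win + 1)
            if peak_idx[k] < cand < foot_idx[k + 1]:
                notch_i = cand
        if foot_idx[k] < peak_idx[k] < foot_idx[k + 1]:
            beats.append(BeatFiducials(valley_idx=foot_idx[k], peak_idx=peak_idx[k],
                                       next_valley_idx=foot_idx[k + 1],
                                       notch_idx=notch_i))

    # Disturbances (added after truth extraction).
    drift_f = cfg["drift_freq"]
    if preset.baseline_drift_amp:
        ppg = ppg + preset.baseline_drift_amp * np.sin(2 * np.pi * drift_f * t)
    if noise is not None:
        for chan in ("ppg", "ecg"):
            arr = ppg if chan == "ppg" else ecg
            arr += noise.mains_amp * np.sin(2 * np.pi * noise.mains_freq * t)
            if noise.snr_db is not None:
                rms = float(np.sqrt(np.mean((arr - arr.mean()) ** 2)))
                sd = rms / (10.0 ** (noise.snr_db / 20.0))
                arr += rng.normal(0.0, sd, size=n)

    ai = np.nan
    if marks["diastolic_amp"]:
        ai = marks["systolic_amp"] / marks["diastolic_amp"]
    truth = RecordTruth(
        beats=beats,
        r_peaks=RPeaks(indices=np.round(r_times * fs).astype(int), fs=fs),
        latents={"hr": hr, "period": period, "ptt_p": ptt_p,
                 "ptt_f": ptt_p - (t_peak_rel - marks["t_foot"]),
                 "ai": ai, "n_peaks": truth_beat_count,
                 "systolic_amp": marks["systolic_amp"],
                 "diastolic_amp": marks["diastolic_amp"] or np.nan},
    )
    ppg_sig = Signal(ppg, fs=fs, kind=PPG, subject_id=spec.subject_id, phase=preset.phase)
    ecg_sig = Signal(ecg, fs=fs, kind=ECG, subject_id=spec.subject_id, phase=preset.phase)
    return ppg_sig, ecg_sig, truth


def _draw(rng: np.random.Generator, params: Sequence[float]) -> float:
    """Draw from a clipped normal given (mean, sd[, lo, hi])."""
    mean, sd = params[0], params[1]
    value = rng.normal(mean, sd)
    if len(params) >= 4:
        value = float(np.clip(value, params[2], params[3]))
    return float(value)


def make_subjects(n_subjects: int, rng_seed: int,
                  config: Optional[dict] = None) -> List[SubjectSpec]:
    """Draw a cohort of subject specifications from the configured
    demographic distributions (heart rate, PTT, diastolic wave height)."""
    if n_subjects < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    cfg = (config or default_config())["synth"]
    children = np.random.SeedSequence(rng_seed).spawn(n_subjects)
    subjects = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(seed)
        hr = _draw(rng, cfg["heart_rate_bpm"])
        sbp = _draw(rng, cfg["sbp_mmhg"] + [80.0, 200.0])
        dbp = _draw(rng, cfg["dbp_mmhg"] + [40.0, min(sbp - 10.0, 120.0)])
        subjects.append(SubjectSpec(
            subject_id=f"S{i:03d}",
            habit=str(rng.choice(HABITS)),
            smoker_class=str(rng.choice(SMOKER_CLASSES)),
            baseline_hr=hr, baseline_sbp=sbp, baseline_dbp=dbp,
            rng_seed=seed,
            ptt_p=_draw(rng, cfg["ptt_p_s"]),
            diastolic_amp=_draw(rng, cfg["diastolic_amp"]),
        ))
    return subjects


def generate_cohort(n_subjects: int = 84,
                    phases: Optional[Sequence[PhasePreset | str]] = None,
                    bp_law: Optional[BPLaw] = None,
                    rng_seed: int = 0,
                    duration: Optional[float] = None,
                    fs: Optional[float] = None,
                    noise: Optional[NoiseSpec] = "config",  # type: ignore[assignment]
                    config: Optional[dict] = None):
    """Generate a cohort feature table: one row per subject and phase.

    Each row carries the subject labels, the reference blood pressures
    implied by the generative law applied to that window's true PTT and
    augmentation index, and the full extracted feature vector (the record is
    rendered, conditioned, fiducial-detected and featurized exactly as a
    measured record would be).

    Returns a pandas DataFrame whose first columns are ``META_COLUMNS``.
    """
    import pandas as pd

    from .pipeline import extract_window_features

    cfg = config or default_config()
    scfg = cfg["synth"]
    duration = scfg["duration"] if duration is None else duration
    fs = scfg["fs"] if fs is None else fs
    if isinstance(noise, str):  # "config" sentinel
        ncfg = scfg["noise"]
        noise = NoiseSpec(mains_amp=ncfg["mains_amp"], mains_freq=ncfg["mains_freq"],
                          snr_db=ncfg["snr_db"])
    law = bp_law if bp_law is not None else BPLaw.from_config(cfg)
    presets = [phase_preset(p, cfg) if isinstance(p, str) else p
               for p in (phases or ["before"])]

    jit = scfg["window_jitter"]
    subjects = make_subjects(n_subjects, rng_seed, cfg)
    rows = []
    for spec in subjects:
        bp_rng = np.random.default_rng(spec.rng_seed + 1)
        for preset in presets:
            # per-window nuisance variability around the phase preset
            eff = replace(
                preset,
                hr_shift=preset.hr_shift + bp_rng.normal(0.0, jit["hr_sd"]),
                ptt_shift=preset.ptt_shift + bp_rng.normal(0.0, jit["ptt_sd"]),
                amp_modulation_depth=float(np.clip(
                    preset.amp_modulation_depth + bp_rng.normal(0.0, jit["amp_mod_sd"]),
                    0.0, 0.95)),
                baseline_drift_amp=abs(
                    preset.baseline_drift_amp + bp_rng.normal(0.0, jit["drift_sd"])),
            )
            ppg, ecg, truth = generate_record(spec, eff, duration=duration,
                                              fs=fs, noise=noise, config=cfg)
            sbp_mu, dbp_mu = law.mean_bp(truth.latents["ptt_p"], truth.latents["ai"])
            eps_s, eps_d = bp_rng.normal(0.0, law.noise_sd, size=2) if law.noise_sd > 0 else (0.0, 0.0)
            feats = extract_window_features(ppg, ecg, config=cfg)
            row = {"subject_id": spec.subject_id, "habit": spec.habit,
                   "phase": eff.phase, "provenance": "measured",
                   "sbp_ref": sbp_mu + eps_s, "dbp_ref": dbp_mu + eps_d}
            row.update(feats)
            rows.append(row)
    table = pd.DataFrame(rows)
    return table[META_COLUMNS + [c for c in table.columns if c not in META_COLUMNS]]
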