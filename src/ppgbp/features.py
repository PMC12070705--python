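"""Morphological and statistical feature extraction.

Per beat, the morphological features are: systolic amplitude (sa), the
diastolic-wave amplitude (Da, measured at the diastolic peak after the
notch), systolic and diastolic areas (SA foot→notch, DA notch→next foot,
trapezoidal, above the beat foot), their ratio IPA = SA/DA, systolic and
diastolic times, pulse interval, stiffness index sa/DT, peak-to-peak
interval and the pulse rate 60/PPI, full width at half maximum,
sa/DT ratio, the augmentation index AI = sa/Da, plus the instantaneous
heart rate 60/T_PP from the enclosing ECG R-R interval and the pulse
transit times from the R-peak to the beat foot (PTT_f) and systolic peak
(PTT_p).

A 30-s window is summarized by four statistics (mean, sample standard
deviation, bias-corrected skewness, Pearson non-excess kurtosis) of each
beat-wise series, plus window scalars: zero-crossing rates of the PPG, its
first and second derivatives and the ECG, and the Shannon energy entropy
E = −Σ y²·ln(y²) of the (scaled) PPG and derivatives.  The standard
registry preset emits exactly 65 named features: 16 beat-feature families
(the stiffness index and the sa/DT ratio share one definition and enter
once) × 4 statistics + the PPG entropy; the full preset adds the alias,
the four zero-crossing rates and the derivative entropies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as spstats

from .config import default_config
from .errors import InvalidArgumentError
from .signal import BeatFiducials, RPeaks, Signal

logger = logging.getLogger(__name__)

STAT_NAMES = ("mean", "std", "skewness", "kurtosis")


@dataclass
class BeatFeatures:
    """Morphological features of a single beat.  Entries that require a
    dicrotic notch (Da, SA, DA, IPA, AI) or a neighbouring beat (PPI, PR)
    are NaN when not computable and are excluded from aggregation."""

    systolic_amplitude: float
    diastolic_amplitude: float
    systolic_area: float
    diastolic_area: float
    inflection_point_area: float
    systolic_time: float
    diastolic_time: float
    pulse_interval: float
    stiffness_index: float
    peak_to_peak_interval: float
    pulse_rate: float
    fwhm: float
    sa_dt_ratio: float
    augmentation_index: float
    heart_rate: float
    ptt_f: float
    ptt_p: float

BEAT_FEATURE_NAMES = tuple(f.name for f in dc_fields(BeatFeatures))


def zero_crossing_rate(y: np.ndarray | Signal, semantics: str = "sign_change") -> float:
    """Zero-crossing rate of a sampled signal, in [0, 1].

    ``sign_change`` (default): fraction of adjacent sample pairs with a
    strict sign change, count{y[n]·y[n−1] < 0} / (N−1).
    ``negative_fraction``: fraction of negative samples, count{y[n] < 0}/N.
    """
    x = y.samples if isinstance(y, Signal) else np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise InvalidArgumentError("zero-crossing rate needs at least 2 samples")
    if semantics == "sign_change":
        return float(np.count_nonzero(x[1:] * x[:-1] < 0) / (n - 1))
    if semantics == "negative_fraction":
        return float(np.count_nonzero(x < 0) / n)
    raise InvalidArgumentError(f"unknown zero-crossing semantics {semantics!r}")


def shannon_entropy(y: np.ndarray | Signal) -> float:
    """Shannon energy entropy E = −Σ y[n]²·ln(y[n]²), with 0·ln 0 = 0.

    Samples are expected in [−1, 1] (enforce by prior normalization or
    scaling); values outside that range make the terms sign-indefinite and
    trigger a warning.
    """
    x = y.samples if isinstance(y, Signal) else np.asarray(y, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        warnings.warn("shannon_entropy: samples outside [-1, 1]; "
                      "entropy terms are not sign-definite", stacklevel=2)
    sq = x.astype(float) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sq > 0.0, sq * np.log(sq), 0.0)
    return float(-np.sum(terms))


def _fwhm(x: np.ndarray, beat: BeatFiducials, fs: float) -> float:
    """Full width at half the systolic amplitude, with linear interpolation
    at the two half-level crossings.  NaN if either crossing is missing."""
    foot = x[beat.valley_idx]
    half = foot + 0.5 * (x[beat.peak_idx] - foot)

    def cross(i0: int, i1: int) -> Optional[float]:
        # first half-level crossing in the segment (the falling edge uses
        # the first drop below half after the peak, so a diastolic wave
        # re-crossing the level does not widen the pulse)
        seg = x[i0:i1 + 1]
        above = seg >= half
        idx = np.flatnonzero(above[1:] != above[:-1])
        if idx.size == 0:
            return None
        i = idx[0]
        y0, y1 = seg[i], seg[i + 1]
        frac = 0.0 if y1 == y0 else (half - y0) / (y1 - y0)
        return (i0 + i + frac)

    left = cross(beat.valley_idx, beat.peak_idx)
    right = cross(beat.peak_idx, beat.next_valley_idx)
    if left is None or right is None or right <= left:
        return np.nan
    return (right - left) / fs


def beat_features(ppg: Signal, beats: Sequence[BeatFiducials],
                  rpeaks: RPeaks) -> List[BeatFeatures]:
    """Per-beat morphological features on a conditioned, normalized PPG,
    with heart rate and pulse transit times from the aligned ECG R-peaks."""
    if rpeaks.fs != ppg.fs:
        raise InvalidArgumentError("PPG and R-peaks must share a time base")
    x = ppg.samples
    fs = ppg.fs
    r = rpeaks.indices
    peak_idx = np.array([b.peak_idx for b in beats])
    out: List[BeatFeatures] = []
    for i, b in enumerate(beats):
        foot = x[b.valley_idx]
        sa = x[b.peak_idx] - foot
        st = (b.peak_idx - b.valley_idx) / fs
        dt = (b.next_valley_idx - b.peak_idx) / fs
        pi = (b.next_valley_idx - b.valley_idx) / fs

        da = s_area = d_area = ipa = ai = np.nan
        if b.notch_idx is not None:
            dias_peak = b.notch_idx + int(np.argmax(x[b.notch_idx:b.next_valley_idx]))
            da = x[dias_peak] - foot
            s_area = float(np.trapezoid(x[b.valley_idx:b.notch_idx + 1] - foot, dx=1.0 / fs))
            d_area = float(np.trapezoid(x[b.notch_idx:b.next_valley_idx + 1] - foot, dx=1.0 / fs))
            ipa = s_area / d_area if d_area != 0 else np.nan
            ai = sa / da if da != 0 else np.nan

        ppi = (peak_idx[i + 1] - peak_idx[i]) / fs if i + 1 < len(beats) else np.nan
        pr = 60.0 / ppi if np.isfinite(ppi) and ppi > 0 else np.nan

        # Enclosing R-R interval -> instantaneous heart rate 60 / T_PP.
        hr = np.nan
        j = int(np.searchsorted(r, b.peak_idx))
        j = min(max(j, 1), len(r) - 1)
        t_pp = (r[j] - r[j - 1]) / fs
        if t_pp > 0:
            hr = 60.0 / t_pp

        k_f = int(np.searchsorted(r, b.valley_idx, side="right")) - 1
        ptt_f = (b.valley_idx - r[k_f]) / fs if k_f >= 0 else np.nan
        k_p = int(np.searchsorted(r, b.peak_idx, side="right")) - 1
        ptt_p = (b.peak_idx - r[k_p]) / fs if k_p >= 0 else np.nan

        out.append(BeatFeatures(
            systolic_amplitude=sa, diastolic_amplitude=da,
            systolic_area=s_area, diastolic_area=d_area,
            inflection_point_area=ipa, systolic_time=st, diastolic_time=dt,
            pulse_interval=pi, stiffness_index=sa / dt if dt > 0 else np.nan,
            peak_to_peak_interval=ppi, pulse_rate=pr,
            fwhm=_fwhm(x, b, fs), sa_dt_ratio=sa / dt if dt > 0 else np.nan,
            augmentation_index=ai, heart_rate=hr, ptt_f=ptt_f, ptt_p=ptt_p))
    return out


def _series_stats(values: np.ndarray, bias_corrected_skew: bool = True,
                  pearson_kurtosis: bool = True) -> Dict[str, float]:
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise InvalidArgumentError(
            f"need >= 3 finite values to aggregate, got {values.size}")
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1))
    # an (effectively) constant series has no defined shape statistics
    if std <= 1e-10 * max(1.0, abs(mean)):
        logger.info("degenerate (constant) beat series; skewness/kurtosis set to 0")
        skew = kurt = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(spstats.skew(values, bias=not bias_corrected_skew))
            kurt = float(spstats.kurtosis(values, fisher=not pearson_kurtosis,
                                          bias=not bias_corrected_skew))
        if not (np.isfinite(skew) and np.isfinite(kurt)):
            logger.info("near-degenerate beat series; skewness/kurtosis set to 0")
            skew = kurt = 0.0
    return {"mean": mean, "std": std, "skewness": skew, "kurtosis": kurt}


def window_scalars(ppg_filtered: Signal, ecg_filtered: Signal, ppg_norm: Signal,
                   zcr_semantics: str = "sign_change") -> Dict[str, float]:
    """Window-level scalars: zero-crossing rates of the (zero-mean,
    band-passed) PPG, its first and second derivatives and the ECG, and
    Shannon energy entropies of the [0,1]-normalized PPG and of its
    derivatives scaled to unit maximum magnitude."""
    d1 = np.gradient(ppg_norm.samples)
    d2 = np.gradient(d1)

    def unit_scale(v: np.ndarray) -> np.ndarray:
        m = np.max(np.abs(v))
        return v / m if m > 0 else v

    return {
        "zcr_ppg": zero_crossing_rate(ppg_filtered.samples, zcr_semantics),
        "zcr_ppg_d1": zero_crossing_rate(d1, zcr_semantics),
        "zcr_ppg_d2": zero_crossing_rate(d2, zcr_semantics),
        "zcr_ecg": zero_crossing_rate(ecg_filtered.samples, zcr_semantics),
        "entropy_ppg": shannon_entropy(ppg_norm.samples),
        "entropy_ppg_d1": shannon_entropy(unit_scale(d1)),
        "entropy_ppg_d2": shannon_entropy(unit_scale(d2)),
    }


def registry_preset(name: str = "standard",
                    config: Optional[dict] = None) -> Dict[str, list]:
    """The named feature-registry preset (lists of beat features,
    statistics and window scalars) from configuration."""
    cfg = config or default_config()
    try:
        preset = cfg["features"]["presets"][name]
    except KeyError as exc:
        raise InvalidArgumentError(f"unknown feature preset {name!r}") from exc
    unknown = set(preset["beat_features"]) - set(BEAT_FEATURE_NAMES)
    if unknown:
        raise InvalidArgumentError(f"preset names unknown beat features: {sorted(unknown)}")
    return preset


def feature_names(preset: Dict[str, list]) -> List[str]:
    """Ordered feature-vector column names for a registry preset."""
    names = [f"{feat}_{stat}" for feat in preset["beat_features"]
             for stat in preset["statistics"]]
    names.extend(preset["window_scalars"])
    return names


def aggregate(beat_series: Sequence[BeatFeatures],
              scalars: Dict[str, float],
              preset: Optional[Dict[str, list]] = None,
              config: Optional[dict] = None) -> Dict[str, float]:
    """Collapse per-beat series into the window feature vector.

    For every beat feature in the registry preset the four statistics are
    computed over the finite per-beat values; the preset's window scalars
    are appended.  Under the standard preset the result has exactly 65
    uniquely named entries.
    """
    if len(beat_series) < 3:
        raise InvalidArgumentError("need at least 3 beats to aggregate")
    cfg = config or default_config()
    fcfg = cfg["features"]
    preset = preset if preset is not None else registry_preset("standard", cfg)
    out: Dict[str, float] = {}
    for feat in preset["beat_features"]:
        values = np.array([getattr(b, feat) for b in beat_series], dtype=float)
        stats = _series_stats(values,
                              bias_corrected_skew=fcfg["skewness_bias_corrected"],
                              pearson_kurtosis=fcfg["kurtosis_convention"] == "pearson")
        for stat in preset["statistics"]:
            out[f"{feat}_{stat}"] = stats[stat]
    for key in preset["window_scalars"]:
        if key not in scalars:
            raise InvalidArgumentError(f"window scalar {key!r} missing")
        out[key] = scalars[key]
    if len(out) != len(feature_names(preset)):
        raise InvalidArgumentError("duplicate feature names in preset")
    return out
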