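import logging

import numpy as np
import pytest

from ppgbp import synth
from ppgbp.config import default_config

logging.getLogger("ppgbp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def record88():
    """Noise-free 30-s record at 88 bpm with ground truth."""
    spec = synth.SubjectSpec(subject_id="S0", baseline_hr=88.0, rng_seed=1)
    return synth.generate_record(spec, synth.PhasePreset(), duration=30.0,
                                 fs=500.0, noise=None)


@pytest.fixture(scope="session")
def conditioned88(record88, cfg):
    """The 88-bpm record conditioned and normalized, with detected beats."""
    from ppgbp import fiducials, preprocess
    from ppgbp.pipeline import _filter_spec

    ppg, ecg, truth = record88
    ppg_n = preprocess.normalize(
        preprocess.notch(preprocess.bandpass(ppg, _filter_spec(cfg, "ppg"))))
    ecg_n = preprocess.normalize(
        preprocess.notch(preprocess.bandpass(ecg, _filter_spec(cfg, "ecg"))))
    beats = fiducials.detect_notch(ppg_n, fiducials.detect_peaks_valleys(ppg_n))
    rpeaks = fiducials.detect_r_peaks(ecg_n)
    return ppg_n, ecg_n, beats, rpeaks, truth


@pytest.fixture(scope="session")
def small_cohort():
    """24-subject single-phase cohort (noise-free BP law for exact checks)."""
    return synth.generate_cohort(n_subjects=24, phases=["before"], rng_seed=5)


def random_feature_table(n_rows: int, n_feats: int = 6, seed: int = 0):
    """Uniform-random cohort-shaped table (well inside any 3-sigma gate)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    data = {
        "subject_id": [f"S{i:03d}" for i in range(n_rows)],
        "habit": ["NC"] * n_rows,
        "phase": ["before"] * n_rows,
        "provenance": ["measured"] * n_rows,
        "sbp_ref": rng.uniform(100, 140, n_rows),
        "dbp_ref": rng.uniform(60, 90, n_rows),
    }
    for j in range(n_feats):
        data[f"f{j}"] = rng.uniform(0, 1, n_rows)
    return pd.DataFrame(data)
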