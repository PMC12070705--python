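"""Phase-wise summaries of predicted blood pressure.

``summarize_phases`` produces one row per (phase, target) with the mean,
standard deviation and mean absolute deviation from each subject's own
"before"-phase prediction (the MAE baseline).  ``subject_trajectories``
lays out per-subject series over the protocol's interval order, with
missing intervals represented explicitly as NaN.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .synth import PHASES

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "phase", "target", "value")


def _check_predictions(predictions: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in predictions.columns]
    if missing:
        raise InvalidArgumentError(f"predictions table lacks columns {missing}")
    unknown = set(predictions["phase"]) - set(PHASES)
    if unknown:
        raise InvalidArgumentError(f"unknown phase labels {sorted(unknown)}")


def summarize_phases(predictions: pd.DataFrame,
                     baseline_phase: str = "before") -> pd.DataFrame:
    """Per-(phase, target) mean / STD / MAE-vs-baseline / n.

    Subjects with no baseline-phase prediction for a target cannot
    contribute an MAE and are excluded from that target's summary (logged).
    """
    _check_predictions(predictions)
    rows = []
    for target, sub in predictions.groupby("target", sort=True):
        base = sub[sub["phase"] == baseline_phase].set_index("subject_id")["value"]
        missing = sorted(set(sub["subject_id"]) - set(base.index))
        if missing:
            logger.info("summarize_phases: excluding subjects without a %r "
                        "baseline for %s: %s", baseline_phase, target, missing)
            sub = sub[~sub["subject_id"].isin(missing)]
        for phase in [p for p in PHASES if p in set(sub["phase"])]:
            values = sub.loc[sub["phase"] == phase].set_index("subject_id")["value"]
            mae = float(np.mean(np.abs(values - base.loc[values.index])))
            rows.append({"phase": phase, "target": target,
                         "mean": float(values.mean()),
                         "std": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                         "mae_vs_baseline": mae, "n": int(len(values))})
    return pd.DataFrame(rows)


def subject_trajectories(predictions: pd.DataFrame,
                         subject_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-subject prediction series over the protocol interval order.

    Returns long form (subject_id, target, phase, value) with every phase
    present in the table enumerated for every requested subject; intervals
    a subject missed appear as NaN rows rather than being dropped.
    """
    _check_predictions(predictions)
    known = set(predictions["subject_id"])
    if subject_ids is None:
        subject_ids = sorted(known)
    else:
        unknown = sorted(set(subject_ids) - known)
        if unknown:
            raise InvalidArgumentError(f"unknown subject ids {unknown}")
    phases = [p for p in PHASES if p in set(predictions["phase"])]
    rows = []
    indexed = predictions.set_index(["subject_id", "target", "phase"])["value"]
    for sid in subject_ids:
        for target in sorted(set(predictions["target"])):
            for phase in phases:
                value = indexed.get((sid, target, phase), np.nan)
                rows.append({"subject_id": sid, "target": target,
                             "phase": phase, "value": float(value)})
    return pd.DataFrame(rows)
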