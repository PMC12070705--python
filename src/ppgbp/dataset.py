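"""Cohort-table operations: cubic-interpolation expansion, outlier-row
removal, train/test splitting.

A cohort table is a pandas DataFrame whose leading columns are the
metadata schema (``subject_id, habit, phase, provenance, sbp_ref,
dbp_ref``) followed by feature columns.  Expansion densifies the table
from its measured size (84 windows by default) to a target size (870 by
default) by fitting one cubic spline per numeric column over row rank —
rows sorted by reference DBP, ties by subject id — and evaluating all
splines on an evenly spaced rank grid.  Interpolated rows carry
``provenance = "interpolated"``; they are not independent samples, and
with the default expand-then-split mode interpolated neighbours of
training rows can land in the test set (the statistically safer
``split_before_expand`` mode is available in configuration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import EmptyResultError, InvalidArgumentError, SchemaError
from .synth import META_COLUMNS

logger = logging.getLogger(__name__)

#: MAD-to-sigma consistency constant for a normal distribution; the
#: outlier gate is median ± factor · 1.4826 · MAD (a robust z-score).
MAD_SCALE = 1.4826


def feature_columns(table: pd.DataFrame) -> List[str]:
    """Feature columns = everything outside the metadata schema."""
    return [c for c in table.columns if c not in META_COLUMNS]


def _check_numeric(table: pd.DataFrame, columns: Sequence[str]) -> None:
    for c in columns:
        if not np.issubdtype(table[c].dtype, np.number):
            raise SchemaError(f"column {c!r} is not numeric")


def expand(table: pd.DataFrame, target_n: int = 870,
           sort_key: Sequence[str] = ("dbp_ref", "subject_id")) -> pd.DataFrame:
    """Expand the table to ``target_n`` rows by per-column cubic splines
    over row rank.

    Rows are first sorted by ``sort_key``.  Each numeric column (features
    and BP references) is interpolated independently over the normalized
    rank axis; label columns are copied from the nearest measured row.
    Measured rows are preserved exactly where the old and new rank grids
    coincide and keep ``provenance = "measured"``.
    """
    n = len(table)
    if target_n < n:
        raise InvalidArgumentError(f"target_n {target_n} < current size {n}")
    numeric = [c for c in table.columns if c not in ("subject_id", "habit", "phase", "provenance")]
    _check_numeric(table, numeric)
    ordered = table.sort_values(list(sort_key), kind="mergesort").reset_index(drop=True)
    if target_n == n:
        return ordered.copy()
    if n < 4:
        raise InvalidArgumentError("need at least 4 rows for cubic interpolation")

    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, target_n)
    nearest = np.clip(np.round(x_new * (n - 1)).astype(int), 0, n - 1)
    coincide = np.isclose(x_new, x_old[nearest], atol=1e-12)

    out = {}
    for c in ("subject_id", "habit", "phase"):
        if c in ordered.columns:
            out[c] = ordered[c].to_numpy()[nearest]
    for c in numeric:
        spline = CubicSpline(x_old, ordered[c].to_numpy())
        values = spline(x_new)
        values[coincide] = ordered[c].to_numpy()[nearest[coincide]]
        out[c] = values
    out["provenance"] = np.where(coincide, "measured", "interpolated")
    expanded = pd.DataFrame(out)

    # Flag spline overshoot beyond 5% of each column's measured range.
    overshoot = {}
    for c in numeric:
        lo, hi = ordered[c].min(), ordered[c].max()
        span = hi - lo
        if span > 0:
            over = np.count_nonzero((expanded[c] < lo - 0.05 * span)
                                    | (expanded[c] > hi + 0.05 * span))
            if over:
                overshoot[c] = int(over)
    if overshoot:
        logger.info("expand: spline overshoot beyond 5%% of the measured "
                    "range in %d columns: %s", len(overshoot), overshoot)
    expanded.attrs["overshoot_flags"] = overshoot
    cols = [c for c in META_COLUMNS if c in expanded.columns] + \
           [c for c in expanded.columns if c not in META_COLUMNS]
    return expanded[cols]


@dataclass
class RowRejectionLog:
    """Identities and reasons of removed cohort rows."""

    removed: List[Tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.removed)


def remove_outlier_rows(table: pd.DataFrame, mad_factor: float = 3.0
                        ) -> Tuple[pd.DataFrame, RowRejectionLog]:
    """Drop rows with any feature outside median ± ``mad_factor`` scale
    units of its column.

    The per-column scale is the MAD-based robust sigma (1.4826·MAD) with a
    sample-std floor capped at 10 robust sigmas: the MAD term resists the
    outliers being gated, the std floor keeps near-degenerate columns
    (tiny MAD, e.g. quantization-dominated spread) from flagging ordinary
    rows, and the cap keeps mass corruption from inflating its own gate.
    Raises when more than half of the rows are flagged — that signals an
    upstream failure, not ordinary outliers.
    """
    if len(table) < 10:
        raise InvalidArgumentError("need at least 10 rows for outlier removal")
    feats = feature_columns(table)
    _check_numeric(table, feats)
    log = RowRejectionLog()
    bad = np.zeros(len(table), dtype=bool)
    for c in feats:
        col = table[c].to_numpy(dtype=float)
        med = np.median(col)
        std = float(np.std(col, ddof=1))
        sigma_r = MAD_SCALE * float(np.median(np.abs(col - med)))
        sigma = std if sigma_r == 0.0 else max(sigma_r, min(std, 10.0 * sigma_r))
        flags = np.abs(col - med) > mad_factor * sigma
        for i in np.flatnonzero(flags & ~bad):
            log.removed.append((int(table.index[i]), f"{c} outside median ± {mad_factor}·MAD"))
        bad |= flags
    if np.count_nonzero(bad) > 0.5 * len(table):
        raise EmptyResultError(
            f"outlier gate flagged {np.count_nonzero(bad)} of {len(table)} rows; "
            "this indicates an upstream failure")
    if log.removed:
        logger.info("removed %d outlier rows: %s", len(log), log.removed)
    return table.loc[~bad].reset_index(drop=True), log


def split(table: pd.DataFrame, train_frac: float = 0.85, rng_seed: int = 0
          ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint, exhaustive train/test split.

    The test size is ``round(n·(1−train_frac))`` with the round-half-up
    convention (870 rows at 85% train → 739 train + 131 test); the train
    partition takes the remainder.
    """
    n = len(table)
    if n < 2:
        raise InvalidArgumentError("need at least 2 rows to split")
    if not (0.0 < train_frac < 1.0):
        raise InvalidArgumentError("train_frac must be in (0, 1)")
    test_n = int(np.floor(n * (1.0 - train_frac) + 0.5))
    train_n = n - test_n
    if test_n == 0 or train_n == 0:
        raise InvalidArgumentError(
            f"split of {n} rows at train_frac={train_frac} leaves an empty partition")
    perm = np.random.default_rng(rng_seed).permutation(n)
    train = table.iloc[np.sort(perm[:train_n])].reset_index(drop=True)
    test = table.iloc[np.sort(perm[train_n:])].reset_index(drop=True)
    return train, test
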