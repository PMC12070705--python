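"""Dimensionality reduction: standardize, PCA, component selection.

The regressors consume true principal-component scores (``component``
mode, 12 components by default).  Because principal components have no
original-variable names, a ``loading_selection`` ranking is also exposed:
original features ordered by their maximal absolute loading across the
retained components, for reporting a named reduced feature set.
"""

from __future__ import annotations

import logging
from typing import List, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .dataset import feature_columns
from .errors import InvalidArgumentError, SchemaError
from .synth import META_COLUMNS

logger = logging.getLogger(__name__)


class FeatureReducer(BaseEstimator, TransformerMixin):
    """Standardize feature columns and project onto principal components.

    Parameters
    ----------
    n_components : retained dimensionality in ``fixed_k`` mode (default 12).
    selection_mode : ``"fixed_k"`` or ``"variance_threshold"``.
    variance_threshold : cumulative explained-variance fraction used when
        ``selection_mode="variance_threshold"`` (minimal k whose cumulative
        ratio reaches the threshold).

    Centering and scaling use training statistics only; constant columns
    are dropped (logged), never an error.  Component signs are pinned so
    the largest-magnitude loading of each component is positive, making
    the decomposition deterministic.
    """

    def __init__(self, n_components: int = 12, selection_mode: str = "fixed_k",
                 variance_threshold: float = 0.95):
        self.n_components = n_components
        self.selection_mode = selection_mode
        self.variance_threshold = variance_threshold

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "FeatureReducer":
        feats = feature_columns(X) if isinstance(X, pd.DataFrame) else \
            [f"f{i}" for i in range(np.asarray(X).shape[1])]
        values = X[feats].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("feature matrix contains non-finite values")
        # relative threshold: a constant column's float std is ~1e-16, not 0
        keep = values.std(axis=0) > 1e-12 * np.maximum(1.0, np.abs(values.mean(axis=0)))
        dropped = [f for f, k in zip(feats, keep) if not k]
        if dropped:
            logger.info("dropping %d constant feature columns: %s", len(dropped), dropped)
        self.feature_names_ = [f for f, k in zip(feats, keep) if k]
        values = values[:, keep]
        if values.shape[1] == 0:
            raise InvalidArgumentError("no non-constant feature columns")

        self.scaler_ = StandardScaler().fit(values)
        scaled = self.scaler_.transform(values)
        self.pca_ = PCA(svd_solver="full").fit(scaled)
        # Sign convention: largest-magnitude loading of each component > 0.
        flip = np.sign(self.pca_.components_[
            np.arange(self.pca_.components_.shape[0]),
            np.argmax(np.abs(self.pca_.components_), axis=1)])
        flip[flip == 0] = 1.0
        self.pca_.components_ *= flip[:, None]
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        self._apply_selection()
        return self

    def _apply_selection(self) -> None:
        p = len(self.feature_names_)
        n_avail = self.explained_variance_ratio_.size
        if self.selection_mode == "fixed_k":
            if self.n_components > p:
                raise InvalidArgumentError(
                    f"n_components {self.n_components} exceeds {p} features")
            self.selected_k_ = min(self.n_components, n_avail)
        elif self.selection_mode == "variance_threshold":
            cum = np.cumsum(self.explained_variance_ratio_)
            reached = np.flatnonzero(cum >= self.variance_threshold - 1e-12)
            self.selected_k_ = int(reached[0]) + 1 if reached.size else n_avail
        else:
            raise InvalidArgumentError(f"unknown selection_mode {self.selection_mode!r}")
        loadings = self.pca_.components_[:self.selected_k_]
        score = np.max(np.abs(loadings), axis=0)
        order = np.argsort(-score, kind="stable")
        self.loading_ranked_features_ = [self.feature_names_[i] for i in order]

    def select(self, mode: Optional[str] = None, k: Optional[int] = None,
               threshold: Optional[float] = None) -> "FeatureReducer":
        """Re-select the retained dimensionality on a fitted model."""
        check_is_fitted(self, "pca_")
        if mode is not None:
            self.selection_mode = mode
        if k is not None:
            self.n_components = k
        if threshold is not None:
            self.variance_threshold = threshold
        self._apply_selection()
        return self

    # -- application -------------------------------------------------------
    def _scores(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_ if f not in X.columns]
            if missing:
                raise SchemaError(f"input lacks fitted feature columns: {missing[:5]}...")
            values = X[self.feature_names_].to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.shape[1] != len(self.feature_names_):
                raise SchemaError("input width does not match fitted schema")
        return self.pca_.transform(self.scaler_.transform(values))[:, :self.selected_k_]

    def transform(self, X) -> pd.DataFrame:
        """Reduced table: ``pc1..pck`` score columns, metadata passed through."""
        scores = self._scores(X)
        out = pd.DataFrame(scores, columns=[f"pc{i+1}" for i in range(scores.shape[1])])
        if isinstance(X, pd.DataFrame):
            for c in META_COLUMNS:
                if c in X.columns:
                    out.insert(0, c, X[c].to_numpy())
        return out

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Map retained-component scores back to (unscaled) feature space."""
        check_is_fitted(self, "pca_")
        k = scores.shape[1]
        back = scores @ self.pca_.components_[:k] + self.pca_.mean_
        return self.scaler_.inverse_transform(back)

    @property
    def cumulative_explained_variance_(self) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return np.cumsum(self.explained_variance_ratio_)

    def to_dict(self) -> dict:
        """JSON-serializable model state (centers, scales, loadings, ratios)."""
        check_is_fitted(self, "pca_")
        return {
            "feature_names": self.feature_names_,
            "center": self.scaler_.mean_.tolist(),
            "scale": self.scaler_.scale_.tolist(),
            "components": self.pca_.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "selected_k": int(self.selected_k_),
            "selection_mode": self.selection_mode,
        }


def score_columns(reduced: pd.DataFrame) -> List[str]:
    """The component-score columns of a reduced table."""
    return [c for c in reduced.columns if c.startswith("pc")]
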