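"""Per-modality preprocessing: log transform, variability filtering,
KNN imputation, quantile normalization and fixed-size feature selection.

Stage order used by :func:`preprocess_view`:

    log_transform -> filter_by_variability (coarse pool) -> knn_impute
    -> quantile_normalize -> select_features (final count)

Imputation precedes quantile normalization because rank-based normalization
is ill-defined on matrices with missing entries.

All operations are available both as functions on :class:`OmicsView` and as
scikit-learn style transformers on plain 2-D arrays.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .view import OmicsView

__all__ = [
    "log_transform",
    "quantile_normalize",
    "filter_by_variability",
    "knn_impute",
    "select_features",
    "preprocess_view",
    "preprocess_dataset",
    "LogTransformer",
    "QuantileNormalizer",
    "VariabilityFilter",
    "NearestNeighborImputer",
]


# ---------------------------------------------------------------------------
# array-level kernels
# ---------------------------------------------------------------------------


def _log2_pseudocount(X: np.ndarray) -> np.ndarray:
    if np.nanmin(X) < 0:
        raise ValueError("log transform requires non-negative values")
    return np.log2(1.0 + X)


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Map every sample (row) onto the mean order-statistic distribution.

    Ties within a row receive the mean of the reference values they span,
    so the result is independent of tie ordering.
    """
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires a complete matrix; impute first")
    n, f = X.shape
    order = np.argsort(X, axis=1, kind="stable")
    ref = np.take_along_axis(X, order, axis=1).mean(axis=0)
    out = np.empty_like(X, dtype=float)
    rows = np.arange(n)[:, None]
    out[rows, order] = ref[None, :]
    for i in range(n):
        vals, inv, counts = np.unique(X[i], return_inverse=True, return_counts=True)
        if len(vals) < f:  # average reference values over tied groups
            sums = np.bincount(inv, weights=out[i])
            out[i] = (sums / counts)[inv]
    return out


def _feature_sd(X: np.ndarray) -> np.ndarray:
    """Per-feature sample SD (ddof=1), ignoring missing entries."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_obs = (~np.isnan(X)).sum(axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
    sd = np.where(n_obs < 2, 0.0, sd)
    return np.nan_to_num(sd, nan=0.0)


def _top_sd_indices(X: np.ndarray, n_keep: int) -> np.ndarray:
    """Indices (ascending) of the n_keep highest-SD features; ties -> earlier index."""
    if not 1 <= n_keep <= X.shape[1]:
        raise ValueError(f"n_keep must be in [1, {X.shape[1]}], got {n_keep}")
    sd = _feature_sd(X)
    ranked = np.lexsort((np.arange(X.shape[1]), -sd))
    return np.sort(ranked[:n_keep])


def _restricted_sq_distances(X: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distance over mutually observed coordinates.

    Pairs sharing no observed coordinate get +inf.
    """
    O = obs.astype(float)
    Xz = np.where(obs, X, 0.0)
    sq = Xz**2
    shared = O @ O.T
    d2 = sq @ O.T + O @ sq.T - 2.0 * (Xz @ Xz.T)
    d2 = np.clip(d2, 0.0, None)
    d2[shared == 0] = np.inf
    return d2


def _knn_impute(X: np.ndarray, k: int) -> np.ndarray:
    n, f = X.shape
    obs = ~np.isnan(X)
    if not (~obs).any():
        return X.copy()
    if k < 1 or k >= n:
        raise ValueError(f"k must be in [1, n_samples-1], got {k}")
    if (obs.sum(axis=1) == 0).any():
        bad = int(np.argmin(obs.sum(axis=1)))
        raise ValueError(f"sample index {bad} has no observed entries")
    empty_cols = np.flatnonzero(obs.sum(axis=0) == 0)
    if empty_cols.size:
        raise ValueError(f"feature index {int(empty_cols[0])} is missing in all samples")

    d2 = _restricted_sq_distances(X, obs)
    out = X.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        d = d2[i].copy()
        d[i] = np.inf
        order = np.argsort(d, kind="stable")  # distance ties -> lower sample index
        for j in np.flatnonzero(~obs[i]):
            donors = [t for t in order if obs[t, j] and np.isfinite(d[t])][:k]
            if not donors:
                raise ValueError(f"no reachable donor for entry ({i}, {j})")
            out[i, j] = X[donors, j].mean()
    return out


# ---------------------------------------------------------------------------
# OmicsView-level operations
# ---------------------------------------------------------------------------


def log_transform(view: OmicsView) -> OmicsView:
    """Replace each observed entry x by log2(1 + x); missing entries preserved."""
    return view.with_values(_log2_pseudocount(view.values))


def quantile_normalize(view: OmicsView) -> OmicsView:
    """Equalize every sample's value distribution to the mean order statistics."""
    return view.with_values(_quantile_normalize(view.values))


def filter_by_variability(view: OmicsView, n_keep: int) -> OmicsView:
    """Keep the n_keep features with largest across-sample SD.

    Surviving features keep their original order; SD ties are broken toward
    the earlier feature index.
    """
    idx = _top_sd_indices(view.values, n_keep)
    return view.with_values(view.values[:, idx], [view.feature_ids[t] for t in idx])


def knn_impute(view: OmicsView, k: int = 5) -> OmicsView:
    """Fill each missing entry with the mean of that feature over the k
    nearest samples (Euclidean distance on mutually observed coordinates;
    donors lacking the feature fall back to the next-nearest sample)."""
    return view.with_values(_knn_impute(view.values, k))


def select_features(view: OmicsView, n_final: int) -> OmicsView:
    """Final fixed-size selection; same SD ranking rule as filter_by_variability."""
    return filter_by_variability(view, n_final)


def preprocess_view(
    view: OmicsView,
    n_coarse: int | None = None,
    k: int = 5,
    n_final: int | None = None,
    log: bool = True,
    quantile: bool = True,
) -> OmicsView:
    """Full per-modality chain; counts are clipped to the available width."""
    if log:
        view = log_transform(view)
    if n_coarse is not None:
        view = filter_by_variability(view, min(n_coarse, view.n_features))
    if view.has_missing():
        view = knn_impute(view, k)
    if quantile:
        view = quantile_normalize(view)
    if n_final is not None:
        view = select_features(view, min(n_final, view.n_features))
    return view


# Default final feature counts per modality (configurable; the real cohorts'
# exact counts are not dictated by the method).
DEFAULT_FINAL_FEATURES = {"mrna": 1000, "meth": 1000, "mirna": 200}


def preprocess_dataset(views, per_modality_config: dict | None = None, k: int = 5):
    """Apply :func:`preprocess_view` to every view.

    per_modality_config maps modality name to a dict of preprocess_view
    keyword arguments; unknown modalities get the full default chain.
    """
    per_modality_config = per_modality_config or {}
    out = []
    for view in views:
        cfg = dict(per_modality_config.get(view.modality, {}))
        cfg.setdefault("k", k)
        cfg.setdefault("n_final", DEFAULT_FINAL_FEATURES.get(view.modality))
        out.append(preprocess_view(view, **cfg))
    return out


# ---------------------------------------------------------------------------
# scikit-learn style transformers (operate on plain 2-D arrays)
# ---------------------------------------------------------------------------


class LogTransformer(TransformerMixin, BaseEstimator):
    """log2(1 + x) on non-negative matrices; stateless."""

    def fit(self, X, y=None):
        np.asarray(X, dtype=float)
        return self

    def transform(self, X):
        return _log2_pseudocount(np.asarray(X, dtype=float))


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Across-sample quantile normalization of the batch it is given.

    Transductive by design: the reference distribution is the mean order
    statistic of the transformed batch itself, so ``transform`` is
    batch-dependent (like the row-wise normalizations it generalizes).
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return _quantile_normalize(np.asarray(X, dtype=float))


class VariabilityFilter(TransformerMixin, BaseEstimator):
    """Keep the ``n_keep`` highest-SD columns seen at fit time."""

    def __init__(self, n_keep: int = 1000):
        self.n_keep = n_keep

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.support_ = _top_sd_indices(X, min(self.n_keep, X.shape[1]))
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


class NearestNeighborImputer(TransformerMixin, BaseEstimator):
    """KNN imputation within the transformed batch (transductive, k=5 default)."""

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return _knn_impute(np.asarray(X, dtype=float), self.k)
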