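"""Transductive multi-omics classifier: per-view GCNs + tensor fusion.

The estimator follows the scikit-learn semi-supervised convention
(cf. ``LabelPropagation``): ``fit(X, y)`` receives *all* samples, with
``y == -1`` marking unlabeled (e.g. test) nodes.  Sample-similarity graphs
are built over all samples of each view; the supervised loss only touches
labeled nodes.  After fitting, ``transduction_`` / ``predict()`` give labels
for every node and ``predict_proba()`` the fused class probabilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .graphs import SampleGraph, SimilarityConfig, build_graph
from .view import OmicsView

__all__ = ["MultiOmicsGCNClassifier"]


def _split_labeled(labeled_idx, y, val_fraction, rng):
    """Stratified carve-out of a validation set from the labeled nodes."""
    train, val = [], []
    for c in np.unique(y[labeled_idx]):
        idx_c = labeled_idx[y[labeled_idx] == c]
        idx_c = rng.permutation(idx_c)
        n_val = int(round(val_fraction * len(idx_c))) if val_fraction > 0 else 0
        if val_fraction > 0:
            n_val = min(max(n_val, 1), len(idx_c) - 1)
        val.extend(idx_c[:n_val])
        train.extend(idx_c[n_val:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(val, dtype=int))


class MultiOmicsGCNClassifier(ClassifierMixin, BaseEstimator):
    """Graph-convolutional multi-omics classifier with label-space fusion.

    Parameters
    ----------
    metric : str
        Similarity metric for graph construction; one of
        ``cosine_similarity``, ``cosine_distance``, ``rbf_similarity``,
        ``rbf_distance``, ``hybrid_similarity``, ``hybrid_distance``.
    gamma : float or "median"
        RBF bandwidth; "median" applies the median heuristic per view.
    beta, alpha : float
        Hybrid similarity/distance mixing weights (ignored otherwise).
    k : int
        Neighbors kept per node during graph sparsification.
    variant : {"full", "no_vcdn", "no_gcn"}
        full = GCNs + tensor-fusion head; no_vcdn = GCNs with average
        fusion; no_gcn = per-view MLPs + tensor-fusion head (no graphs).
    hidden_dim, learning_rate, weight_decay, max_epochs, patience :
        Training hyperparameters (Adam, early stopping on validation loss).
    val_fraction : float
        Fraction of labeled nodes carved out (stratified) for early
        stopping; 0 monitors training loss instead.
    random_state : int
        Seed for weight initialization and the validation carve-out.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen among labeled nodes.
    transduction_ : ndarray
        Predicted class label for every sample (labeled and unlabeled).
    probabilities_ : ndarray of shape (n_samples, n_classes)
        Fused class probabilities for every sample.
    view_probabilities_ : list of ndarray
        Per-view probabilities before fusion.
    graphs_ : list of SampleGraph or None
        The per-view graphs (None for the no_gcn variant).
    history_ : nn.TrainHistory
        Loss curves, best and stopping epochs.
    """

    def __init__(
        self,
        metric: str = "cosine_similarity",
        gamma="median",
        beta: float = 0.5,
        alpha: float = 0.5,
        k: int = 10,
        variant: str = "full",
        hidden_dim: int = 64,
        learning_rate: float = 1e-3,
        weight_decay: float = 5e-4,
        max_epochs: int = 2500,
        patience: int = 20,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.metric = metric
        self.gamma = gamma
        self.beta = beta
        self.alpha = alpha
        self.k = k
        self.variant = variant
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _coerce_views(self, X):
        if isinstance(X, (OmicsView, np.ndarray)):
            X = [X]
        mats = []
        for v in X:
            M = v.values if isinstance(v, OmicsView) else np.asarray(v, dtype=float)
            if M.ndim != 2:
                raise ValueError("each view must be a 2-D matrix")
            mats.append(M)
        n = mats[0].shape[0]
        if any(M.shape[0] != n for M in mats):
            raise ValueError("all views must share the same samples")
        return mats

    def similarity_config(self) -> SimilarityConfig:
        return SimilarityConfig(
            metric=self.metric, gamma=self.gamma, beta=self.beta, alpha=self.alpha, k=self.k
        )

    def fit(self, X, y, val_idx=None):
        """Fit transductively.

        Parameters
        ----------
        X : list of views (2-D arrays or OmicsView), or a single view
        y : (n_samples,) int labels, -1 for unlabeled nodes
        val_idx : optional explicit validation indices (labeled); overrides
            the internal stratified carve-out.
        """
        mats = self._coerce_views(X)
        y = np.asarray(y)
        n = mats[0].shape[0]
        if y.shape != (n,):
            raise ValueError("y must have one entry per sample (-1 = unlabeled)")
        labeled = np.flatnonzero(y >= 0)
        if labeled.size == 0:
            raise ValueError("at least one labeled sample is required")
        self.classes_ = np.unique(y[labeled])
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        y_enc = np.full(n, -1, dtype=int)
        y_enc[labeled] = [class_to_idx[c] for c in y[labeled]]

        rng = np.random.default_rng(self.random_state)
        if val_idx is not None:
            val_idx = np.asarray(val_idx, dtype=int)
            train_idx = np.setdiff1d(labeled, val_idx)
        else:
            train_idx, val_idx = _split_labeled(labeled, y_enc, self.val_fraction, rng)

        if self.variant == "no_gcn":
            self.graphs_ = None
            adjacencies = None
        else:
            cfg = self.similarity_config()
            self.graphs_ = [build_graph(M, cfg) for M in mats]
            adjacencies = self.graphs_

        gcns, vcdn, probs, history = nn.train_joint(
            mats,
            adjacencies,
            y_enc,
            train_idx,
            val_idx,
            n_classes=len(self.classes_),
            variant=self.variant,
            hidden_dim=self.hidden_dim,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=int(rng.integers(2**31)),
        )
        self.gcn_params_ = gcns
        self.vcdn_params_ = vcdn
        self.view_probabilities_ = probs["views"]
        self.probabilities_ = probs["fused"]
        self.transduction_ = self.classes_[np.argmax(self.probabilities_, axis=1)]
        self.history_ = history
        self.train_idx_ = train_idx
        self.val_idx_ = val_idx
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        """Fused probabilities for the fitted samples (transductive)."""
        if not hasattr(self, "probabilities_"):
            raise AttributeError("classifier is not fitted")
        if X is not None:
            mats = self._coerce_views(X)
            if mats[0].shape[0] != self.probabilities_.shape[0]:
                raise ValueError(
                    "transductive model: predict applies to the samples seen in fit"
                )
        return self.probabilities_

    def predict(self, X=None) -> np.ndarray:
        self.predict_proba(X)
        return self.transduction_
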