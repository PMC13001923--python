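"""Sample-similarity graph construction.

Six pairwise metrics — cosine similarity/distance, RBF (Gaussian kernel)
similarity/distance, and their convex hybrids — plus the median heuristic for
the RBF bandwidth, top-k sparsification and the symmetric normalized
adjacency D̃^{-1/2} Ã D̃^{-1/2} (Ã = A + I) consumed by graph convolution.

Edge weights are always affinities in [0, 1]: distance metrics are converted
with w = 1 − d before neighbor selection, so "nearest" uniformly means
"largest affinity".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse
from scipy.spatial.distance import pdist
from sklearn.metrics.pairwise import cosine_similarity as _pairwise_cosine
from sklearn.metrics.pairwise import euclidean_distances as _pairwise_euclidean

from .view import OmicsView

__all__ = [
    "METRICS",
    "SimilarityConfig",
    "SampleGraph",
    "cosine_similarity",
    "cosine_distance",
    "angular_distance",
    "rbf_similarity",
    "rbf_distance",
    "hybrid_similarity",
    "hybrid_distance",
    "median_gamma",
    "build_graph",
]

METRICS = (
    "cosine_similarity",
    "cosine_distance",
    "rbf_similarity",
    "rbf_distance",
    "hybrid_similarity",
    "hybrid_distance",
)


# ---------------------------------------------------------------------------
# pairwise metrics on single vectors
# ---------------------------------------------------------------------------


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine is undefined for zero-norm vectors")
    return x, y, nx, ny


def cosine_similarity(x, y) -> float:
    """(x·y)/(‖x‖‖y‖); in [0, 1] for non-negative inputs."""
    x, y, nx, ny = _check_pair(x, y)
    return float(np.dot(x, y) / (nx * ny))


def cosine_distance(x, y) -> float:
    """Complement of cosine similarity: 1 − cos(x, y)."""
    return 1.0 - cosine_similarity(x, y)


def angular_distance(x, y) -> float:
    """arccos(cos(x, y)) / π, a true metric on directions, in [0, 1]."""
    c = np.clip(cosine_similarity(x, y), -1.0, 1.0)
    return float(np.arccos(c) / np.pi)


def _check_gamma(gamma) -> float:
    gamma = float(gamma)
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return gamma


def rbf_similarity(x, y, gamma: float) -> float:
    """Gaussian kernel exp(−γ‖x−y‖²), in (0, 1]."""
    gamma = _check_gamma(gamma)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def rbf_distance(x, y, gamma: float) -> float:
    """1 − exp(−γ‖x−y‖²), in [0, 1)."""
    return 1.0 - rbf_similarity(x, y, gamma)


def hybrid_similarity(x, y, beta: float, gamma: float) -> float:
    """β·cosine_similarity + (1−β)·rbf_similarity; β=1 is pure cosine."""
    if not 0 <= beta <= 1:
        raise ValueError("beta must be in [0, 1]")
    return beta * cosine_similarity(x, y) + (1.0 - beta) * rbf_similarity(x, y, gamma)


def hybrid_distance(x, y, alpha: float, gamma: float) -> float:
    """α·cosine_distance + (1−α)·rbf_distance; α weights angular vs spatial."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * cosine_distance(x, y) + (1.0 - alpha) * rbf_distance(x, y, gamma)


def median_gamma(view) -> float:
    """Median heuristic for the RBF bandwidth: γ = 1 / (2·median‖xi−xj‖²).

    The median runs over all unordered sample pairs, zero-distance pairs
    included; degenerate data whose median pair distance is 0 raise.
    """
    X = view.values if isinstance(view, OmicsView) else np.asarray(view, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("median_gamma needs at least 2 samples")
    med = float(np.median(pdist(X, metric="sqeuclidean")))
    if med == 0:
        raise ValueError("median pairwise distance is 0 (degenerate data)")
    return 1.0 / (2.0 * med)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


@dataclass
class SimilarityConfig:
    """Metric choice and hyperparameters for graph construction.

    gamma may be the string ``"median"`` to invoke the median heuristic on
    the view the graph is built from.  beta/alpha are only consulted by the
    corresponding hybrid metric; k is the number of neighbors kept per node.
    """

    metric: str = "cosine_similarity"
    gamma: float | str = "median"
    beta: float = 0.5
    alpha: float = 0.5
    k: int = 10

    def validate(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.gamma != "median":
            _check_gamma(self.gamma)
        if not 0 <= self.beta <= 1 or not 0 <= self.alpha <= 1:
            raise ValueError("beta and alpha must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def resolve_gamma(self, X: np.ndarray) -> float:
        if self.gamma == "median":
            return median_gamma(X)
        return float(self.gamma)


@dataclass
class SampleGraph:
    """Weighted sample adjacency A plus its normalized form D̃^{-1/2}ÃD̃^{-1/2}."""

    weights: np.ndarray
    normalized: np.ndarray
    sample_ids: list

    def __post_init__(self):
        A = self.weights
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(A)).max(initial=0.0) > 0:
            raise ValueError("weights diagonal must be zero")
        if A.min(initial=0.0) < -1e-12 or A.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("edge weights must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    def to_mtx(self, path) -> None:
        """Export the weighted adjacency as Matrix Market plus an ID sidecar."""
        path = Path(path)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(self.weights))
        sidecar = path.with_suffix(".samples.txt")
        sidecar.write_text("\n".join(str(s) for s in self.sample_ids) + "\n")


def _affinity_matrix(X: np.ndarray, config: SimilarityConfig) -> np.ndarray:
    metric = config.metric
    need_cos = metric in ("cosine_similarity", "cosine_distance",
                          "hybrid_similarity", "hybrid_distance")
    need_rbf = metric in ("rbf_similarity", "rbf_distance",
                          "hybrid_similarity", "hybrid_distance")
    C = R = None
    if need_cos:
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"sample index {bad} has zero norm; cosine undefined")
        C = np.clip(_pairwise_cosine(X), -1.0, 1.0)
    if need_rbf:
        gamma = config.resolve_gamma(X)
        R = np.exp(-gamma * _pairwise_euclidean(X, squared=True))

    if metric == "cosine_similarity":
        W = C
    elif metric == "cosine_distance":
        W = 1.0 - (1.0 - C)  # affinity of the distance metric
    elif metric == "rbf_similarity":
        W = R
    elif metric == "rbf_distance":
        W = 1.0 - (1.0 - R)
    elif metric == "hybrid_similarity":
        W = config.beta * C + (1.0 - config.beta) * R
    else:  # hybrid_distance: w = 1 − (α·dcos + (1−α)·drbf), clamped at 0
        W = 1.0 - (config.alpha * (1.0 - C) + (1.0 - config.alpha) * (1.0 - R))
        W = np.clip(W, 0.0, None)
    return np.clip(W, 0.0, 1.0)


def _topk_mask(W: np.ndarray, k: int) -> np.ndarray:
    """Per-row top-k neighbor mask (self excluded, ties to lower index)."""
    n = W.shape[0]
    mask = np.zeros_like(W, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        row = W[i].copy()
        row[i] = -np.inf
        order = np.lexsort((idx, -row))
        keep = order[:k]
        mask[i, keep] = True
    return mask


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """D̃^{-1/2} Ã D̃^{-1/2} with Ã = A + I (self-loops)."""
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def build_graph(view, config: SimilarityConfig) -> SampleGraph:
    """Build the top-k sample graph for one view under the given metric.

    Steps: full pairwise affinity matrix; per-node top-k neighbor selection
    (largest affinity, ties to the lower sample index); symmetrization by
    elementwise maximum; zero diagonal; symmetric normalization with
    self-loops.
    """
    config.validate()
    if isinstance(view, OmicsView):
        X, sample_ids = view.values, view.sample_ids
    else:
        X = np.asarray(view, dtype=float)
        sample_ids = [f"S{i:04d}" for i in range(X.shape[0])]
    if np.isnan(X).any():
        raise ValueError("graph construction requires a complete matrix; impute first")
    n = X.shape[0]
    if config.k >= n:
        raise ValueError(f"k={config.k} must be < n_samples={n}")

    W = _affinity_matrix(X, config)
    mask = _topk_mask(W, config.k)
    kept = np.where(mask, W, 0.0)
    A = np.maximum(kept, kept.T)  # union symmetrization: no isolated nodes from asymmetry
    np.fill_diagonal(A, 0.0)
    return SampleGraph(weights=A, normalized=normalize_adjacency(A), sample_ids=sample_ids)
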