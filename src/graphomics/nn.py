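"""Graph-convolutional view classifiers and label-space tensor fusion.

Per-view model: a two-layer GCN following the Kipf–Welling propagation rule
H(l+1) = σ(D̃^{-1/2} Ã D̃^{-1/2} H(l) Θ(l)) with a 64-unit ReLU hidden layer
and a direct c-logit output (softmax per node).  The fusion head (VCDN)
forms, per sample, the outer product of the m per-view class-probability
vectors — a c^m tensor flattened row-major with view 1 as the slowest index —
and classifies it with a 128/64-unit ReLU MLP and a softmax output.

Everything is plain numpy: models are small and trained full-batch with a
hand-written backward pass and Adam, which keeps runs bit-reproducible from
a single seed.  Joint training minimizes the sum of the per-view
cross-entropies and the fusion cross-entropy at labeled training nodes, with
early stopping on validation loss.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .graphs import SampleGraph
from .view import OmicsView

__all__ = [
    "GCNParams",
    "VCDNParams",
    "TrainHistory",
    "gcn_layer",
    "gcn_forward",
    "fcn_forward",
    "vcdn_tensor",
    "vcdn_forward",
    "average_fusion",
    "init_gcn_params",
    "init_vcdn_params",
    "train_joint",
]

HIDDEN_DIM = 64
VCDN_HIDDEN = (128, 64)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class GCNParams:
    """Weights of one two-layer GCN: theta0 (in×hidden), theta1 (hidden×c)."""

    theta0: np.ndarray
    theta1: np.ndarray

    def arrays(self):
        return [self.theta0, self.theta1]

    def copy(self):
        return GCNParams(self.theta0.copy(), self.theta1.copy())


@dataclass
class VCDNParams:
    """Weights of the fusion MLP: fc1 (c^m×128), fc2 (128×64), out (64×c)."""

    fc1: np.ndarray
    fc2: np.ndarray
    out: np.ndarray

    def arrays(self):
        return [self.fc1, self.fc2, self.out]

    def copy(self):
        return VCDNParams(self.fc1.copy(), self.fc2.copy(), self.out.copy())


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_gcn_params(rng, in_dim: int, n_classes: int, hidden: int = HIDDEN_DIM) -> GCNParams:
    return GCNParams(_glorot(rng, in_dim, hidden), _glorot(rng, hidden, n_classes))


def init_vcdn_params(rng, n_classes: int, n_views: int) -> VCDNParams:
    h1, h2 = VCDN_HIDDEN
    return VCDNParams(
        _glorot(rng, n_classes**n_views, h1),
        _glorot(rng, h1, h2),
        _glorot(rng, h2, n_classes),
    )


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------


def _as_matrix(view) -> np.ndarray:
    return view.values if isinstance(view, OmicsView) else np.asarray(view, dtype=float)


def gcn_layer(H, normalized, theta, apply_activation: bool = True) -> np.ndarray:
    """One graph convolution: σ(normalized · H · θ); σ omitted for logits."""
    H = np.asarray(H, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape[1] != H.shape[0] or H.shape[1] != theta.shape[0]:
        raise ValueError(
            f"shape mismatch: adj {normalized.shape}, H {H.shape}, theta {theta.shape}"
        )
    out = normalized @ H @ theta
    return relu(out) if apply_activation else out


def gcn_forward(view, graph: SampleGraph, params: GCNParams) -> np.ndarray:
    """Two-layer GCN producing per-node class probabilities (rows on simplex)."""
    X = _as_matrix(view)
    if isinstance(view, OmicsView) and view.sample_ids != list(graph.sample_ids):
        raise ValueError("view and graph sample order differ")
    S = graph.normalized if isinstance(graph, SampleGraph) else np.asarray(graph, dtype=float)
    if S.shape[0] != X.shape[0]:
        raise ValueError("view and graph sample counts differ")
    h = gcn_layer(X, S, params.theta0, apply_activation=True)
    logits = gcn_layer(h, S, params.theta1, apply_activation=False)
    return softmax(logits)


def fcn_forward(view, params: GCNParams) -> np.ndarray:
    """Graph-free ablation: identical widths, identity in place of the adjacency."""
    X = _as_matrix(view)
    h = relu(X @ params.theta0)
    return softmax(h @ params.theta1)


def vcdn_tensor(predictions) -> np.ndarray:
    """Flattened per-sample outer product of per-view probability rows.

    Output shape (n, c^m); flattening is row-major with view 1 as the
    slowest-varying index, so for m=2 the entry at flat index a1*c+a2 is
    ŷ(1)_{a1}·ŷ(2)_{a2}.
    """
    mats = [np.asarray(p, dtype=float) for p in predictions]
    if len(mats) < 2:
        raise ValueError("tensor fusion needs at least 2 views")
    n, c = mats[0].shape
    for p in mats:
        if p.shape != (n, c):
            raise ValueError("all view predictions must share (n_samples, n_classes)")
    flat = mats[0]
    for p in mats[1:]:
        flat = (flat[:, :, None] * p[:, None, :]).reshape(n, -1)
    return flat


def vcdn_forward(flat, params: VCDNParams) -> np.ndarray:
    """Fusion MLP: fc1 → ReLU → fc2 → ReLU → out → softmax."""
    flat = np.asarray(flat, dtype=float)
    h1 = relu(flat @ params.fc1)
    h2 = relu(h1 @ params.fc2)
    return softmax(h2 @ params.out)


def average_fusion(predictions) -> np.ndarray:
    """Elementwise mean of per-view probability matrices (late fusion ablation)."""
    mats = [np.asarray(p, dtype=float) for p in predictions]
    return np.mean(mats, axis=0)


# ---------------------------------------------------------------------------
# joint training
# ---------------------------------------------------------------------------


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class _Adam:
    """Adam with coupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, shapes, lr=1e-3, weight_decay=0.0, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _cross_entropy(probs: np.ndarray, y: np.ndarray, idx: np.ndarray) -> float:
    p = np.clip(probs[idx, y[idx]], 1e-12, None)
    return float(-np.log(p).mean())


def _tensor_view_grad(dT: np.ndarray, probs: list, v: int) -> np.ndarray:
    """Gradient of the fusion loss w.r.t. view v's probability rows.

    Contracts the (n, c, ..., c) tensor gradient with the other views'
    probabilities over every axis except view v's.
    """
    m = len(probs)
    n, c = probs[0].shape
    letters = string.ascii_lowercase[:m]
    dT = dT.reshape((n,) + (c,) * m)
    subs = ["z" + letters] + ["z" + letters[u] for u in range(m) if u != v]
    operands = [dT] + [probs[u] for u in range(m) if u != v]
    return np.einsum(",".join(subs) + "->z" + letters[v], *operands)


def train_joint(
    view_matrices,
    adjacencies,
    y,
    train_idx,
    val_idx,
    n_classes: int,
    variant: str = "full",
    hidden_dim: int = HIDDEN_DIM,
    learning_rate: float = 1e-3,
    weight_decay: float = 5e-4,
    max_epochs: int = 2500,
    patience: int = 20,
    seed: int = 0,
):
    """End-to-end training of the per-view classifiers and the fusion head.

    Parameters
    ----------
    view_matrices : list of (n, f_v) arrays
    adjacencies : list of (n, n) normalized adjacencies, or None for the
        graph-free ``no_gcn`` variant.
    y : (n,) int labels; only train_idx/val_idx entries are consulted.
    variant : {"full", "no_vcdn", "no_gcn"}
        full = GCNs + tensor fusion head; no_vcdn = GCNs with average
        fusion (fusion head untrained/unused); no_gcn = per-view MLPs
        (identity adjacency) + tensor fusion head.

    Returns (gcn_params_list, vcdn_params_or_None, probs, history) where
    probs is the fused (n, c) probability matrix from the best-validation
    parameters.
    """
    if variant not in ("full", "no_vcdn", "no_gcn"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    views = [np.asarray(X, dtype=float) for X in view_matrices]
    m = len(views)
    n = views[0].shape[0]
    y = np.asarray(y)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)

    if variant == "no_gcn":
        S_list = [None] * m  # identity propagation
    else:
        S_list = [
            (A.normalized if isinstance(A, SampleGraph) else np.asarray(A, dtype=float))
            for A in adjacencies
        ]

    use_fusion = variant in ("full", "no_gcn") and m >= 2
    gcns = [init_gcn_params(rng, X.shape[1], n_classes, hidden_dim) for X in views]
    vcdn = init_vcdn_params(rng, n_classes, m) if use_fusion else None

    params = [a for g in gcns for a in g.arrays()] + (vcdn.arrays() if vcdn else [])
    opt = _Adam([p.shape for p in params], lr=learning_rate, weight_decay=weight_decay)

    nt = len(train_idx)
    Y_train = np.zeros((n, n_classes))
    Y_train[train_idx, y[train_idx]] = 1.0
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True

    def forward():
        """Return caches needed for backward plus per-view and fused probs."""
        caches = []
        probs = []
        for X, S, g in zip(views, S_list, gcns):
            SX = X if S is None else S @ X
            H1pre = SX @ g.theta0
            H1 = relu(H1pre)
            SH1 = H1 if S is None else S @ H1
            Z = SH1 @ g.theta1
            P = softmax(Z)
            caches.append((SX, H1pre, H1, SH1, P))
            probs.append(P)
        fused = None
        fcache = None
        if use_fusion:
            T = vcdn_tensor(probs)
            U1 = T @ vcdn.fc1
            R1 = relu(U1)
            U2 = R1 @ vcdn.fc2
            R2 = relu(U2)
            Zf = R2 @ vcdn.out
            fused = softmax(Zf)
            fcache = (T, U1, R1, U2, R2, fused)
        return caches, probs, fused, fcache

    def loss_at(probs, fused, idx):
        # no_vcdn ablation: the average-fusion head is parameter-free, so the
        # training objective is the sum of the per-view cross-entropies only
        total = sum(_cross_entropy(P, y, idx) for P in probs)
        if use_fusion:
            total += _cross_entropy(fused, y, idx)
        return total

    def backward(caches, probs, fused, fcache):
        grads_g = []
        dP_fusion = [np.zeros_like(P) for P in probs]
        gv = []  # vcdn grads
        if use_fusion:
            T, U1, R1, U2, R2, Pf = fcache
            dZf = (Pf - Y_train) / nt
            dZf[~train_mask] = 0.0
            dOut = R2.T @ dZf
            dR2 = dZf @ vcdn.out.T
            dU2 = dR2 * (U2 > 0)
            dFc2 = R1.T @ dU2
            dR1 = dU2 @ vcdn.fc2.T
            dU1 = dR1 * (U1 > 0)
            dFc1 = T.T @ dU1
            dT = dU1 @ vcdn.fc1.T
            gv = [dFc1, dFc2, dOut]
            for v in range(m):
                dP_fusion[v] = _tensor_view_grad(dT, probs, v)
        for v, (X, S, g, cache) in enumerate(zip(views, S_list, gcns, caches)):
            SX, H1pre, H1, SH1, P = cache
            dZ = (P - Y_train) / nt
            dZ[~train_mask] = 0.0
            if use_fusion:
                gp = dP_fusion[v]
                dZ = dZ + P * (gp - (gp * P).sum(axis=1, keepdims=True))
            dTheta1 = SH1.T @ dZ
            dSH1 = dZ @ g.theta1.T
            dH1 = dSH1 if S is None else S @ dSH1  # S is symmetric
            dH1pre = dH1 * (H1pre > 0)
            dTheta0 = SX.T @ dH1pre
            grads_g += [dTheta0, dTheta1]
        return grads_g + gv

    history = TrainHistory()
    best_val = np.inf
    best_state = None
    since_improve = 0
    monitor_idx = val_idx if len(val_idx) > 0 else train_idx

    for epoch in range(1, max_epochs + 1):
        caches, probs, fused, fcache = forward()
        train_loss = loss_at(probs, fused, train_idx)
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        grads = backward(caches, probs, fused, fcache)
        opt.step(params, grads)

        _, probs_new, fused_new, _ = forward()
        val_loss = loss_at(probs_new, fused_new, monitor_idx)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_state = ([g.copy() for g in gcns], vcdn.copy() if vcdn else None)
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
        if since_improve >= patience:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = max_epochs

    gcns_best, vcdn_best = best_state  # noqa: best_state set on first epoch
    # final fused probabilities from the best parameters
    probs = []
    for X, S, g in zip(views, S_list, gcns_best):
        if S is None:
            probs.append(fcn_forward(X, g))
        else:
            h = relu((S @ X) @ g.theta0)
            probs.append(softmax((S @ h) @ g.theta1))
    if use_fusion:
        fused = vcdn_forward(vcdn_tensor(probs), vcdn_best)
    else:
        fused = average_fusion(probs)
    return gcns_best, vcdn_best, {"views": probs, "fused": fused}, history


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(path, gcn_params, vcdn_params=None, manifest: dict | None = None) -> None:
    """Serialize trained parameters to one .npz archive with a JSON manifest."""
    import json

    arrays = {}
    for i, g in enumerate(gcn_params):
        arrays[f"gcn{i}_theta0"] = g.theta0
        arrays[f"gcn{i}_theta1"] = g.theta1
    if vcdn_params is not None:
        arrays["vcdn_fc1"] = vcdn_params.fc1
        arrays["vcdn_fc2"] = vcdn_params.fc2
        arrays["vcdn_out"] = vcdn_params.out
    meta = dict(manifest or {})
    meta["n_views"] = len(gcn_params)
    meta["has_vcdn"] = vcdn_params is not None
    arrays["manifest"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path):
    """Inverse of :func:`save_model`; returns (gcn_params, vcdn_params, manifest)."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["manifest"]).decode())
        gcns = [
            GCNParams(data[f"gcn{i}_theta0"], data[f"gcn{i}_theta1"])
            for i in range(meta["n_views"])
        ]
        vcdn = (
            VCDNParams(data["vcdn_fc1"], data["vcdn_fc2"], data["vcdn_out"])
            if meta["has_vcdn"]
            else None
        )
    return gcns, vcdn, meta
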