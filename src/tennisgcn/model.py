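"""Three-layer spatial-temporal graph-convolutional classifier.

Architecture (three stroke classes):

    input (N, C, V, T)
      -> 3 x [ spatial graph conv with A_norm  ->  temporal conv (kernel 3)
               -> BatchNorm -> ReLU ]          with 32 / 64 / 64 feature maps
      -> global average pool over joints and time
      -> 1x1 convolution (a linear map at pooled size) -> ReLU
      -> concatenate the standardized active-feature vector
      -> fully connected layer to 3 logits -> softmax

The spatial step multiplies the normalized adjacency
Lambda^{-1/2}(A+I)Lambda^{-1/2} into the joint dimension; the temporal step
is an ordinary convolution along the time axis, so consecutive frames of the
same joint are linked without materializing a V*T-node graph.  Training is
stochastic gradient descent with momentum on the cross-entropy loss, with
early stopping when the epoch loss stops improving.  Everything is plain
numpy with analytically derived gradients, which keeps runs bit-reproducible
from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .skeleton_io import CLASSES, MotionSample
from .stgraph import SkeletonGraph

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainResult",
    "EvalResult",
    "STGCN",
    "build_model",
    "forward",
    "train",
    "evaluate",
    "count_parameters",
    "save_model",
    "load_model",
]

_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_channels`` is 2 for raw coordinates and 6 for fuzzified input;
    ``n_feature_inputs`` is the active-feature vector length (0 disables the
    knowledge-base fusion path).
    """

    layer_kernels: tuple[int, int, int] = (32, 64, 64)
    temporal_kernel: int = 3
    n_classes: int = 3
    input_channels: int = 2
    use_active_features: bool = True
    n_feature_inputs: int = 50

    def __post_init__(self) -> None:
        if self.temporal_kernel % 2 != 1:
            raise ValueError("temporal_kernel must be odd for symmetric padding")
        if self.n_classes != len(CLASSES):
            raise ValueError(f"classifier is {len(CLASSES)}-way, got n_classes={self.n_classes}")

    @property
    def fusion_width(self) -> int:
        extra = self.n_feature_inputs if self.use_active_features else 0
        return self.layer_kernels[-1] + extra


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters.

    ``warmup_epochs`` scales the learning rate by 1/4 for the first epochs
    and ``grad_clip`` bounds the global gradient norm; both guard the early
    phase of training against the large activations that spike artifacts in
    raw coordinate input can produce.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 1000
    tol: float = 1e-4
    patience: int = 10
    warmup_epochs: int = 0
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainResult:
    epochs_run: int
    loss_trajectory: list[float]
    model: "STGCN"


@dataclass(frozen=True)
class EvalResult:
    """Confusion matrix (rows = true class, order forehand/backhand/no_shot),
    per-class true-positive rates and overall accuracy."""

    confusion: np.ndarray
    tp_rates: np.ndarray
    accuracy: float


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form trainable parameter count of the architecture."""
    total = 0
    c_in = cfg.input_channels
    for c_out in cfg.layer_kernels:
        total += c_out * c_in * cfg.temporal_kernel + c_out  # conv weights + bias
        total += 2 * c_out  # BatchNorm gamma, beta
        c_in = c_out
    last = cfg.layer_kernels[-1]
    total += last * last + last  # 1x1 convolution on the pooled vector
    total += cfg.n_classes * cfg.fusion_width + cfg.n_classes  # fusion FC
    return total


class STGCN:
    """The classifier with parameters, forward pass and gradients."""

    def __init__(self, cfg: ModelConfig, graph: SkeletonGraph, seed: int = 0):
        if graph.n_nodes < 1:
            raise ValueError("graph has no nodes")
        self.cfg = cfg
        self.graph = graph
        self.A = graph.A_norm.astype(np.float32)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        c_in = cfg.input_channels
        for l, c_out in enumerate(cfg.layer_kernels):
            fan_in = c_in * cfg.temporal_kernel
            bound = 1.0 / np.sqrt(fan_in)
            self.params[f"W{l}"] = rng.uniform(-bound, bound, (c_out, c_in, cfg.temporal_kernel)).astype(np.float32)
            self.params[f"b{l}"] = rng.uniform(-bound, bound, c_out).astype(np.float32)
            self.params[f"gamma{l}"] = np.ones(c_out, dtype=np.float32)
            self.params[f"beta{l}"] = np.zeros(c_out, dtype=np.float32)
            self.running[f"mean{l}"] = np.zeros(c_out, dtype=np.float32)
            self.running[f"var{l}"] = np.ones(c_out, dtype=np.float32)
            c_in = c_out
        last = cfg.layer_kernels[-1]
        bound = 1.0 / np.sqrt(last)
        self.params["Wp"] = rng.uniform(-bound, bound, (last, last)).astype(np.float32)
        self.params["bp"] = rng.uniform(-bound, bound, last).astype(np.float32)
        bound = 1.0 / np.sqrt(cfg.fusion_width)
        self.params["Wf"] = rng.uniform(-bound, bound, (cfg.n_classes, cfg.fusion_width)).astype(np.float32)
        self.params["bf"] = rng.uniform(-bound, bound, cfg.n_classes).astype(np.float32)
        self._bn_collect: list[dict] | None = None
        self._scratch: dict[str, np.ndarray] = {}

    def refresh_bn_stats(self, X: np.ndarray, F: np.ndarray | None = None,
                         batch_size: int = 64) -> None:
        """Recompute BatchNorm running statistics exactly under the current
        weights (a 'precise BN' pass over the given data).

        The incremental running averages tracked during training lag the
        weights they normalize; with heavy-tailed raw input they can be so
        stale that evaluation-mode activations no longer match the fitted
        decision boundary.  One deterministic pass over the training data
        replaces them with the population statistics of the final model.

        This is an optional post-processing utility.  ``train`` itself keeps
        the conventional running averages, as the field's standard network
        implementations do; see the methods note for the consequences for
        the raw-vs-fuzzy comparison.
        """
        n_layers = len(self.cfg.layer_kernels)
        self._bn_collect = [
            {"sum": 0.0, "sumsq": 0.0, "count": 0} for _ in range(n_layers)
        ]
        try:
            for start in range(0, X.shape[0], batch_size):
                Fb = F[start : start + batch_size] if F is not None else None
                self._forward(X[start : start + batch_size], Fb, training=True)
        finally:
            collected, self._bn_collect = self._bn_collect, None
        for l, acc in enumerate(collected):
            mean = acc["sum"] / acc["count"]
            self.running[f"mean{l}"] = mean.astype(np.float32)
            self.running[f"var{l}"] = (acc["sumsq"] / acc["count"] - mean**2).astype(np.float32)

    def _mix(self, X: np.ndarray) -> np.ndarray:
        """Multiply A_norm into the joint axis of a (C, N, V, T) tensor.

        Returns a transposed view of the matmul result; consumers must not
        assume contiguity.
        """
        C, N, V, T = X.shape
        flat = X.transpose(2, 0, 1, 3).reshape(V, -1)  # (V, C*N*T)
        return (self.A @ flat).reshape(V, C, N, T).transpose(1, 2, 0, 3)

    def _buffer(self, key: str, shape: tuple) -> np.ndarray:
        """Reusable scratch array (reduces large-allocation churn per batch)."""
        buf = self._scratch.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._scratch[key] = buf
        return buf

    # ------------------------------------------------------------------ forward

    def _layer_forward(self, X: np.ndarray, l: int, training: bool):
        """One ST-GCN block: graph mix, temporal conv, BatchNorm, ReLU.

        Tensors are channel-first, (C, N, V, T), so the temporal convolution
        collapses to a single (C_out, C_in*kt) x (C_in*kt, N*V*T) matmul.
        """
        cfg = self.cfg
        kt = cfg.temporal_kernel
        pad = kt // 2
        C, N, V, T = X.shape
        Sp = self._buffer(f"Sp{l}", (C, N, V, T + 2 * pad))
        Sp[:, :, :, :pad] = 0.0
        Sp[:, :, :, pad + T :] = 0.0
        Sp[:, :, :, pad : pad + T] = self._mix(X)  # spatial aggregation
        # im2col along time: (C*kt, N*V*T)
        cols = self._buffer(f"cols{l}", (C, kt, N, V, T))
        for k in range(kt):
            cols[:, k] = Sp[:, :, :, k : k + T]
        Xc = cols.reshape(C * kt, -1)
        W = self.params[f"W{l}"]  # (O, C, kt)
        O = W.shape[0]
        Z = (W.reshape(O, C * kt) @ Xc).reshape(O, N, V, T)
        Z += self.params[f"b{l}"][:, None, None, None]
        # BatchNorm over (batch, joints, time) per feature map
        gamma, beta = self.params[f"gamma{l}"], self.params[f"beta{l}"]
        if training:
            M = Z.shape[1] * Z.shape[2] * Z.shape[3]
            mean = Z.sum(axis=(1, 2, 3)) / M
            var = np.einsum("cnvt,cnvt->c", Z, Z, optimize=True) / M - mean**2
            if self._bn_collect is not None:
                self._bn_collect[l]["sum"] += mean
                self._bn_collect[l]["sumsq"] += var + mean**2
                self._bn_collect[l]["count"] += 1
            else:
                self.running[f"mean{l}"] = (1 - _BN_MOMENTUM) * self.running[f"mean{l}"] + _BN_MOMENTUM * mean
                self.running[f"var{l}"] = (1 - _BN_MOMENTUM) * self.running[f"var{l}"] + _BN_MOMENTUM * var
        else:
            mean = self.running[f"mean{l}"]
            var = self.running[f"var{l}"]
        ivar = (1.0 / np.sqrt(var + _EPS)).astype(np.float32)
        xhat = Z
        xhat -= np.asarray(mean, dtype=np.float32)[:, None, None, None]
        xhat *= ivar[:, None, None, None]
        bn = gamma[:, None, None, None] * xhat
        bn += beta[:, None, None, None]
        Y = np.maximum(bn, 0.0, out=bn)
        cache = (Xc, xhat, ivar, Y > 0)
        return Y, cache

    def _forward(self, X: np.ndarray, F: np.ndarray | None, training: bool):
        caches = []
        H = np.ascontiguousarray(X.astype(np.float32).transpose(1, 0, 2, 3))  # (C, N, V, T)
        for l in range(len(self.cfg.layer_kernels)):
            H, cache = self._layer_forward(H, l, training)
            caches.append(cache)
        C, N, V, T = H.shape
        pool = H.mean(axis=(2, 3)).T  # (N, C)
        h = np.maximum(pool @ self.params["Wp"].T + self.params["bp"], 0.0)
        if self.cfg.use_active_features:
            if F is None:
                raise ValueError("model expects an active-feature vector; got None")
            z = np.concatenate([h, F.astype(np.float32)], axis=1)
        else:
            z = h
        logits = z @ self.params["Wf"].T + self.params["bf"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (caches, H.shape, pool, h, z)

    def predict_proba(self, X: np.ndarray, F: np.ndarray | None = None) -> np.ndarray:
        probs, _ = self._forward(X, F, training=False)
        return probs

    def predict(self, X: np.ndarray, F: np.ndarray | None = None) -> np.ndarray:
        return np.argmax(self.predict_proba(X, F), axis=1)

    # ----------------------------------------------------------------- backward

    def _backward(self, X, probs, y_onehot, fwd_cache):
        caches, last_shape, pool, h, z = fwd_cache
        cfg = self.cfg
        N = X.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (probs - y_onehot) / N
        grads["Wf"] = dlogits.T @ z
        grads["bf"] = dlogits.sum(axis=0)
        dz = dlogits @ self.params["Wf"]
        dh = dz[:, : h.shape[1]] * (h > 0)
        grads["Wp"] = dh.T @ pool
        grads["bp"] = dh.sum(axis=0)
        dpool = dh @ self.params["Wp"]
        C, N, V, T = last_shape
        dH = np.broadcast_to(dpool.T[:, :, None, None] / (V * T), last_shape).astype(np.float32)
        for l in reversed(range(len(cfg.layer_kernels))):
            dH = self._layer_backward(dH, l, grads)
        return grads

    def _layer_backward(self, dY, l, grads):
        cfg = self.cfg
        kt = cfg.temporal_kernel
        pad = kt // 2
        Xc, xhat, ivar, relu_mask = self._caches[l]
        O, N, V, T = dY.shape
        M = N * V * T
        dbn = np.multiply(dY, relu_mask, dtype=np.float32)
        gamma = self.params[f"gamma{l}"]
        s1 = dbn.sum(axis=(1, 2, 3))
        s2 = np.einsum("cnvt,cnvt->c", dbn, xhat, optimize=True)
        grads[f"gamma{l}"] = s2
        grads[f"beta{l}"] = s1
        # batchnorm backward with the gamma factor folded into one pass
        dZ = dbn
        dZ -= (s1 / M)[:, None, None, None]
        dZ -= xhat * (s2 / M)[:, None, None, None]
        dZ *= (gamma * ivar)[:, None, None, None]
        grads[f"b{l}"] = dZ.sum(axis=(1, 2, 3))
        C = Xc.shape[0] // kt
        dZr = dZ.reshape(O, M)
        grads[f"W{l}"] = (dZr @ Xc.T).reshape(O, C, kt)
        if l == 0:
            return None  # input gradient not needed below the first layer
        dXc = (self.params[f"W{l}"].reshape(O, C * kt).T @ dZr).reshape(C, kt, N, V, T)
        dSp = self._buffer(f"dSp{l}", (C, N, V, T + 2 * pad))
        dSp[:] = 0.0
        for k in range(kt):
            dSp[:, :, :, k : k + T] += dXc[:, k]
        dS = dSp[:, :, :, pad : pad + T]
        return self._mix(dS)  # A_norm is symmetric

    def loss_and_grads(self, X, F, y):
        probs, cache = self._forward(X, F, training=True)
        self._caches = cache[0]
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(y)), y] = 1.0
        loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))
        grads = self._backward(X, probs, onehot, cache)
        del self._caches
        return loss, grads


def build_model(cfg: ModelConfig, graph: SkeletonGraph, seed: int = 0) -> STGCN:
    """Instantiate a seeded classifier for the given skeleton graph."""
    return STGCN(cfg, graph, seed=seed)


def forward(model: STGCN, sample: MotionSample, feats=None) -> np.ndarray:
    """Class-probability triple for one sample (evaluation mode)."""
    X = sample.data[None].astype(np.float32)
    F = None
    if model.cfg.use_active_features:
        if feats is None:
            raise ValueError("model expects an active-feature vector")
        values = feats.values if hasattr(feats, "values") else np.asarray(feats)
        F = np.asarray(values, dtype=np.float32)[None]
    return model.predict_proba(X, F)[0]


def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def train(model: STGCN, X: np.ndarray, y: np.ndarray, F: np.ndarray | None = None,
          cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """SGD-with-momentum training on cross-entropy, with early stopping.

    Stops at ``max_epochs`` or once the epoch loss has failed to improve on
    its running best by at least ``tol`` for ``patience`` consecutive epochs.
    Fully reproducible from ``cfg.seed``.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=int)
    if F is not None:
        F = np.asarray(F, dtype=np.float32)
    counts = _class_counts(y, model.cfg.n_classes)
    if (counts == 0).any():
        missing = [CLASSES[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"training data has no samples for class(es) {missing}")
    rng = np.random.default_rng(cfg.seed)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    losses: list[float] = []
    best = np.inf
    stall = 0
    N = X.shape[0]
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(N)
        epoch_loss = 0.0
        lr = cfg.learning_rate * (0.25 if epoch < cfg.warmup_epochs else 1.0)
        for start in range(0, N, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            Fb = F[idx] if F is not None else None
            loss, grads = model.loss_and_grads(X[idx], Fb, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: {loss}; "
                    "try a smaller learning rate"
                )
            epoch_loss += loss * len(idx)
            if cfg.grad_clip is not None:
                gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    grads = {k: g * scale for k, g in grads.items()}
            for k, g in grads.items():
                v = velocity[k]
                v *= cfg.momentum
                v -= lr * g.astype(np.float32)
                model.params[k] += v
        epoch_loss /= N
        losses.append(epoch_loss)
        if best - epoch_loss < cfg.tol:
            stall += 1
            if stall >= cfg.patience:
                break
        else:
            stall = 0
        best = min(best, epoch_loss)
    return TrainResult(epochs_run=len(losses), loss_trajectory=losses, model=model)


def evaluate(model: STGCN, X: np.ndarray, y: np.ndarray, F: np.ndarray | None = None) -> EvalResult:
    """Confusion matrix, per-class true-positive rates and overall accuracy."""
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if y.min() < 0 or y.max() >= model.cfg.n_classes:
        raise ValueError(f"labels must be in 0..{model.cfg.n_classes - 1}")
    pred = model.predict(np.asarray(X, dtype=np.float32),
                         None if F is None else np.asarray(F, dtype=np.float32))
    K = model.cfg.n_classes
    confusion = np.zeros((K, K), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    row = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(row > 0, np.diag(confusion) / np.maximum(row, 1), np.nan)
    return EvalResult(confusion=confusion, tp_rates=tp,
                      accuracy=float(np.trace(confusion) / confusion.sum()))


def save_model(model: STGCN, path: str | Path) -> None:
    """Persist parameters, running statistics and config in one .npz archive."""
    meta = json.dumps(asdict(model.cfg))
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"running_{k}": v for k, v in model.running.items()})
    np.savez(path, _config=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path, graph: SkeletonGraph) -> STGCN:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["_config"]).decode())
        meta["layer_kernels"] = tuple(meta["layer_kernels"])
        cfg = ModelConfig(**meta)
        model = STGCN(cfg, graph)
        for k in model.params:
            model.params[k] = archive[f"param_{k}"]
        for k in model.running:
            model.running[k] = archive[f"running_{k}"]
    return model
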