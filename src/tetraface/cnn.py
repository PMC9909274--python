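"""Chain-interaction classifier: a small convolutional network on 20x24 maps.

Architecture: input 1x20x24 -> conv 3x3 (stride 1, no padding) -> ReLU ->
conv 2x2 (stride 1, no padding) -> ReLU -> max-pool 2x2 (stride 2, floor)
-> flatten -> fully connected -> 2 logits, trained with softmax
cross-entropy and Adam.  Spatial dimensions are therefore
20x24 -> 18x22 -> 17x21 -> 8x10.

The network is implemented directly in numpy: the inputs are tiny and a
seeded pure-numpy implementation makes training bit-reproducible, which the
pipeline's determinism contract relies on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .chain_features import FeatureMap

SHAPE_CONTRACT = [(18, 22), (17, 21), (8, 10)]


@dataclass
class CnnConfig:
    """Hyperparameters of the chain-interaction network."""

    kernels_conv1: int = 2
    kernels_conv2: int = 2
    learning_rate: float = 0.000801
    batch_size: int = 128
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernels_conv1 < 1 or self.kernels_conv2 < 1:
            raise ValueError("kernel counts must be >= 1")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0 < self.learning_rate:
            raise ValueError("learning rate must be positive")


@dataclass
class InteractionPrediction:
    """Per-complex chain-pair predictions and the PT bookkeeping vector."""

    chain_pairs: list[tuple[str, str]]
    probabilities: np.ndarray  # P(interaction) per pair
    hard_labels: np.ndarray  # thresholded at 0.5
    pt: tuple[int, int] | None = None  # (a, b)

    @property
    def pt_norm(self) -> int | None:
        return None if self.pt is None else self.pt[0] + self.pt[1]


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation. X (N,C,H,W), W (F,C,KH,KW) -> (N,F,OH,OW)."""
    _, _, H, Wd = X.shape
    F, _, KH, KW = W.shape
    OH, OW = H - KH + 1, Wd - KW + 1
    out = np.tile(b[None, :, None, None], (X.shape[0], 1, OH, OW)).astype(float)
    for p in range(KH):
        for q in range(KW):
            out += np.einsum(
                "ncij,fc->nfij", X[:, :, p : p + OH, q : q + OW], W[:, :, p, q]
            )
    return out


def _conv_backward(
    X: np.ndarray, W: np.ndarray, dOut: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    F, _, KH, KW = W.shape
    OH, OW = dOut.shape[2], dOut.shape[3]
    dW = np.zeros_like(W)
    dX = np.zeros_like(X)
    for p in range(KH):
        for q in range(KW):
            dW[:, :, p, q] = np.einsum(
                "nfij,ncij->fc", dOut, X[:, :, p : p + OH, q : q + OW]
            )
            dX[:, :, p : p + OH, q : q + OW] += np.einsum(
                "nfij,fc->ncij", dOut, W[:, :, p, q]
            )
    db = dOut.sum(axis=(0, 2, 3))
    return dX, dW, db


def _pool_forward(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
    """2x2 max pool, stride 2, floor semantics on odd dimensions."""
    N, C, H, W = X.shape
    OH, OW = H // 2, W // 2
    win = (
        X[:, :, : 2 * OH, : 2 * OW]
        .reshape(N, C, OH, 2, OW, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, OH, OW, 4)
    )
    idx = win.argmax(axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return pooled, idx, (N, C, H, W)


def _pool_backward(dPool: np.ndarray, idx: np.ndarray, xshape: tuple) -> np.ndarray:
    N, C, H, W = xshape
    OH, OW = H // 2, W // 2
    dwin = np.zeros((N, C, OH, OW, 4))
    np.put_along_axis(dwin, idx[..., None], dPool[..., None], axis=-1)
    dX = np.zeros((N, C, H, W))
    dX[:, :, : 2 * OH, : 2 * OW] = (
        dwin.reshape(N, C, OH, OW, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, 2 * OH, 2 * OW)
    )
    return dX


class InteractionCnn:
    """Two-conv-layer network mapping a 20x24 feature map to 2 logits."""

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k1, k2 = config.kernels_conv1, config.kernels_conv2
        self.params = {
            "W1": rng.normal(0, np.sqrt(2.0 / 9), (k1, 1, 3, 3)),
            "b1": np.zeros(k1),
            "W2": rng.normal(0, np.sqrt(2.0 / (4 * k1)), (k2, k1, 2, 2)),
            "b2": np.zeros(k2),
            "Wf": rng.normal(0, np.sqrt(2.0 / (k2 * 80)), (2, k2 * 80)),
            "bf": np.zeros(2),
        }

    @property
    def flat_dim(self) -> int:
        return self.config.kernels_conv2 * 8 * 10

    def forward(
        self, X: np.ndarray, return_cache: bool = False
    ) -> np.ndarray | tuple[np.ndarray, dict]:
        """Logits for a batch of maps X of shape (N, 20, 24)."""
        X = np.asarray(X, float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (20, 24):
            raise ValueError(f"expected (N, 20, 24) maps, got {X.shape}")
        x0 = X[:, None, :, :]
        z1 = _conv_forward(x0, self.params["W1"], self.params["b1"])
        a1 = np.maximum(z1, 0.0)
        z2 = _conv_forward(a1, self.params["W2"], self.params["b2"])
        a2 = np.maximum(z2, 0.0)
        pooled, idx, xshape = _pool_forward(a2)
        flat = pooled.reshape(len(X), -1)
        logits = flat @ self.params["Wf"].T + self.params["bf"]
        if not return_cache:
            return logits
        cache = dict(x0=x0, z1=z1, a1=a1, z2=z2, a2=a2, pooled=pooled,
                     idx=idx, xshape=xshape, flat=flat)
        return logits, cache

    def intermediate_shapes(self, X: np.ndarray) -> list[tuple[int, int]]:
        """Spatial dims after conv1, conv2 and pooling (shape contract)."""
        _, cache = self.forward(X, return_cache=True)
        return [
            cache["z1"].shape[2:],
            cache["z2"].shape[2:],
            cache["pooled"].shape[2:],
        ]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax probabilities, shape (N, 2); column 1 = P(interaction)."""
        return _softmax(self.forward(X))

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        grads = {}
        grads["Wf"] = dlogits.T @ cache["flat"]
        grads["bf"] = dlogits.sum(axis=0)
        dflat = dlogits @ self.params["Wf"]
        dpool = dflat.reshape(cache["pooled"].shape)
        da2 = _pool_backward(dpool, cache["idx"], cache["xshape"])
        dz2 = da2 * (cache["z2"] > 0)
        da1, grads["W2"], grads["b2"] = _conv_backward(
            cache["a1"], self.params["W2"], dz2
        )
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(
            cache["x0"], self.params["W1"], dz1
        )
        return grads

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "InteractionCnn":
        path = Path(path)
        config = CnnConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = _softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def _as_arrays(
    maps, labels=None
) -> tuple[np.ndarray, np.ndarray | None]:
    if len(maps) == 0:
        raise ValueError("empty dataset")
    mats = np.stack(
        [m.matrix if isinstance(m, FeatureMap) else np.asarray(m, float) for m in maps]
    )
    if labels is None:
        labels = [m.label for m in maps if isinstance(m, FeatureMap)]
        if len(labels) != len(mats) or any(l is None for l in labels):
            raise ValueError("labels missing: pass them explicitly")
    y = np.asarray(labels, dtype=int)
    return mats, y


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int | None = None


def build_cnn(config: CnnConfig | None = None) -> InteractionCnn:
    return InteractionCnn(config or CnnConfig())


def train_cnn(
    maps,
    labels=None,
    config: CnnConfig | None = None,
    validation: tuple | None = None,
) -> tuple[InteractionCnn, TrainHistory]:
    """Train the network with Adam on softmax cross-entropy.

    Deterministic given ``config.seed``.  When a validation set
    ``(maps, labels)`` is supplied, the parameters with the lowest
    validation loss across epochs are retained.
    """
    config = config or CnnConfig()
    X, y = _as_arrays(maps, labels)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    Xv = yv = None
    if validation is not None:
        Xv, yv = _as_arrays(*validation)

    model = InteractionCnn(config)
    rng = np.random.default_rng(config.seed + 1)
    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = TrainHistory()
    best = None

    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits, cache = model.forward(X[idx], return_cache=True)
            loss, dlogits = _xent(logits, y[idx])
            losses.append(loss)
            grads = model._backward(cache, dlogits)
            step += 1
            for k in model.params:
                mom[k] = beta1 * mom[k] + (1 - beta1) * grads[k]
                vel[k] = beta2 * vel[k] + (1 - beta2) * grads[k] ** 2
                mhat = mom[k] / (1 - beta1**step)
                vhat = vel[k] / (1 - beta2**step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.train_loss.append(float(np.mean(losses)))
        if Xv is not None:
            vloss, _ = _xent(model.forward(Xv), yv)
            history.val_loss.append(vloss)
            if best is None or vloss < best[0]:
                best = (vloss, {k: v.copy() for k, v in model.params.items()}, epoch)
    if best is not None:
        model.params = best[1]
        history.best_epoch = best[2]
    return model, history


def predict_complex(
    model: InteractionCnn,
    maps: list[FeatureMap],
    true_labels: list[int] | None = None,
    threshold: float = 0.5,
) -> InteractionPrediction:
    """Predict the six chain-pair interactions of one complex.

    When true labels are given, also computes the PT vector (a, b): the
    counts of correctly predicted interactions and non-interactions.
    """
    if len(maps) != 6:
        raise ValueError(f"a tetramer yields exactly 6 chain pairs, got {len(maps)}")
    X, _ = _as_arrays(maps, true_labels if true_labels is not None else [0] * 6)
    probs = model.predict_proba(X)[:, 1]
    hard = (probs >= threshold).astype(int)
    pt = None
    if true_labels is not None:
        yt = np.asarray(true_labels, int)
        a = int(np.sum((yt == 1) & (hard == 1)))
        b = int(np.sum((yt == 0) & (hard == 0)))
        pt = (a, b)
    pairs = [m.chain_pair if isinstance(m, FeatureMap) else ("", "") for m in maps]
    return InteractionPrediction(pairs, probs, hard, pt)


def search_hyperparams(
    train: tuple,
    validation: tuple,
    budget: int = 10,
    seed: int = 0,
    epochs: int = 20,
    lr_range: tuple[float, float] = (1e-5, 1e-3),
    kernel_choices: tuple[int, ...] = (1, 2, 3, 4),
) -> tuple[CnnConfig, float]:
    """Seeded random hyperparameter search maximizing validation AUC.

    Samples ``budget`` configurations (log-uniform learning rate, kernel
    counts from ``kernel_choices``), trains each, and returns the config
    with the best validation AUC; ties break toward the lower learning
    rate, then the fewer total kernels.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    from .metrics import auc

    rng = np.random.default_rng(seed)
    Xv, yv = _as_arrays(*validation)
    best: tuple | None = None
    for _ in range(budget):
        lr = float(np.exp(rng.uniform(np.log(lr_range[0]), np.log(lr_range[1]))))
        k1 = int(rng.choice(kernel_choices))
        k2 = int(rng.choice(kernel_choices))
        config = CnnConfig(
            kernels_conv1=k1, kernels_conv2=k2, learning_rate=lr,
            epochs=epochs, seed=seed,
        )
        model, _ = train_cnn(*train, config=config)
        score = auc(model.predict_proba(Xv)[:, 1], yv)
        key = (-score, lr, k1 + k2)
        if best is None or key < best[0]:
            best = (key, config, score)
    return best[1], best[2]
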