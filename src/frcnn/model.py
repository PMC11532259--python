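"""Fr-CNN assembly, complexity accounting, and GFSGD training.

The network is the two-stage attention CNN: conv(200, 3x3) -> spatial
attention -> mixed pool(2x2) -> conv(100, 3x3) -> attention -> mixed
pool -> flatten -> dense(100, ReLU) -> dense(50, ReLU) -> dense(K,
softmax).  On a 128x128x3 input this chains through the printed shapes
(126,126,200) -> (63,63,400) -> (61,61,100) -> (30,30,200) -> 180000 ->
100 -> 50 -> K and totals 18,371,305 trainable parameters for K = 3.

Parameter counts follow (ks*Ci + 1)*Co for convolutions (ks = kernel
area) and (Ni + 1)*No for dense layers; FLOPs follow 2*Ho*Wo*Co*(ks*Ci)
and 2*Ni*No; model size is parameters x bytes-per-parameter.

Training uses the fractional optimizer from :mod:`frcnn.fractional`
applied per mini-batch; :class:`FrCNNClassifier` wraps the loop in a
scikit-learn estimator interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .fractional import GFSGD, FractionalConfig
from .layers import (
    Conv2D,
    Dense,
    Flatten,
    Layer,
    MixedPool,
    ReLU,
    SpatialAttention,
    softmax_probs,
    softmax_xent,
    softmax_xent_backward,
)

__all__ = [
    "LayerSummary",
    "NetworkSpec",
    "TrainingHistory",
    "TrainingDiverged",
    "build_frcnn",
    "count_parameters",
    "count_flops",
    "model_size_mb",
    "Network",
    "train",
    "alpha_sweep",
    "FrCNNClassifier",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class LayerSummary:
    """One architecture row: layer kind, resolved output shape, counts."""

    kind: str
    output_shape: tuple
    n_params: int
    flops: int


@dataclass
class NetworkSpec:
    """Declarative architecture: layer objects plus resolved shape chain."""

    layers: list[Layer]
    input_shape: tuple[int, int, int]
    num_classes: int
    summaries: list[LayerSummary] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(s.n_params for s in self.summaries)

    @property
    def total_flops(self) -> int:
        return sum(s.flops for s in self.summaries)

    def describe(self) -> pd.DataFrame:
        rows = [
            {"layer": s.kind, "output_shape": s.output_shape, "params": s.n_params,
             "flops": s.flops}
            for s in self.summaries
        ]
        return pd.DataFrame(rows)


def _layer_flops(layer: Layer, in_shape: tuple, out_shape: tuple) -> int:
    """2*Ho*Wo*Co*(ks*Ci) for conv-like layers, 2*Ni*No for dense, else 0."""
    if layer.kind == "conv2d":
        ho, wo, co = out_shape
        kh, kw = layer.kernel
        return 2 * ho * wo * co * (kh * kw * in_shape[2])
    if layer.kind == "attention":
        h, w, c = in_shape
        return 2 * h * w * 1 * (1 * c)  # the 1x1 gate convolution
    if layer.kind == "dense":
        return 2 * in_shape[0] * out_shape[0]
    return 0


def _resolve(spec: NetworkSpec) -> None:
    """Chain shapes through the layers and fill per-layer summaries."""
    shape = tuple(spec.input_shape)
    summaries = []
    for layer in spec.layers:
        out = layer.out_shape(shape)
        summaries.append(
            LayerSummary(layer.kind, out, layer.n_params(shape),
                         _layer_flops(layer, shape, out))
        )
        shape = out
    spec.summaries = summaries


def build_frcnn(
    input_shape: tuple[int, int, int] = (128, 128, 3),
    num_classes: int = 3,
    conv_filters: tuple[int, int] = (200, 100),
    dense_units: tuple[int, int] = (100, 50),
    kernel: tuple[int, int] = (3, 3),
    pool: tuple[int, int] = (2, 2),
) -> NetworkSpec:
    """Assemble the two-stage attention/mixed-pooling CNN.

    Raises ``ValueError`` if the input is too small to pass two
    conv+pool stages.
    """
    h, w, _ = input_shape
    if h < 8 or w < 8:
        raise ValueError(f"input spatial dims must be >= 8, got {input_shape}")
    layers: list[Layer] = [
        Conv2D(conv_filters[0], kernel),
        ReLU(),
        SpatialAttention(),
        MixedPool(pool),
        Conv2D(conv_filters[1], kernel),
        ReLU(),
        SpatialAttention(),
        MixedPool(pool),
        Flatten(),
        Dense(dense_units[0]),
        ReLU(),
        Dense(dense_units[1]),
        ReLU(),
        Dense(num_classes),
    ]
    spec = NetworkSpec(layers=layers, input_shape=tuple(input_shape),
                       num_classes=int(num_classes))
    _resolve(spec)  # validates the shape chain
    return spec


def count_parameters(spec: NetworkSpec) -> tuple[list[int], int]:
    """Per-layer and total trainable parameter counts."""
    per_layer = [s.n_params for s in spec.summaries]
    return per_layer, sum(per_layer)


def count_flops(spec: NetworkSpec) -> tuple[list[int], int]:
    """Per-layer and total FLOP counts (multiply-add counted as 2)."""
    per_layer = [s.flops for s in spec.summaries]
    return per_layer, sum(per_layer)


def model_size_mb(total_params: int, bytes_per_param: int = 4) -> float:
    """Model size in MB (parameters x bytes each / 1024^2), 2 decimals."""
    if total_params < 0 or bytes_per_param <= 0:
        raise ValueError("counts must be non-negative / positive")
    return round(total_params * bytes_per_param / 1024**2, 2)


class Network:
    """Runtime network: initialized parameters plus forward/backward."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator,
                 dtype=np.float64):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        shape = tuple(spec.input_shape)
        for layer in spec.layers:
            layer.init_params(shape, rng, self.dtype)
            shape = layer.out_shape(shape)
        spec.layers[0].skip_input_grad = True

    @property
    def layers(self) -> list[Layer]:
        return self.spec.layers

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            k = len(layer.params)
            layer.params = params[i : i + k]
            i += k

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax_probs(self.forward(x[i : i + batch_size])))
        return np.concatenate(outs, axis=0)

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, np.ndarray, list[np.ndarray]]:
        logits = self.forward(x)
        loss, probs = softmax_xent(logits, y)
        grad = softmax_xent_backward(probs, y).astype(self.dtype, copy=False)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        param_grads = []
        for layer in self.layers:
            param_grads.extend(layer.param_grads())
        return loss, probs, param_grads


class _PlainSGD:
    """Reference stochastic gradient descent: x <- x - lr * g."""

    def __init__(self, learning_rate: float):
        self.learning_rate = learning_rate

    def update(self, params, grads):
        return [p - self.learning_rate * np.asarray(g) for p, g in
                zip(params, grads, strict=True)]


class TrainingDiverged(FloatingPointError):
    """Raised when the loss becomes non-finite mid-training.

    Carries the epoch/batch of the failure and the history recorded up
    to the last completed epoch, so callers (e.g. the order sweep) can
    report the run as failed without losing its trajectory.
    """

    def __init__(self, epoch: int, batch: int, history: "TrainingHistory"):
        super().__init__(
            f"non-finite loss at epoch {epoch}, batch {batch}")
        self.epoch = epoch
        self.batch = batch
        self.history = history


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy bookkeeping for train and validation."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.epochs + 1),
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


def _evaluate(net: Network, x: np.ndarray, y: np.ndarray,
              batch_size: int = 256) -> tuple[float, float]:
    probs = net.predict_proba(x, batch_size=batch_size)
    n = len(x)
    p_true = probs[np.arange(n), y].astype(np.float64)
    loss = float(-np.mean(np.log(p_true + 1e-300)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: FractionalConfig | None = None,
    epochs: int = 35,
    batch_size: int = 32,
    seed: int = 0,
    optimizer: str = "gfsgd",
) -> TrainingHistory:
    """Seeded mini-batch training loop.

    ``optimizer="gfsgd"`` applies the fractional update per batch;
    ``optimizer="sgd"`` is an independent plain-SGD reference that
    shares the identical shuffling and batching (used to demonstrate
    the alpha = 1 equivalence).  Aborts with a diagnostic if the loss
    becomes non-finite.
    """
    if config is None:
        config = FractionalConfig(alpha=1.5, learning_rate=0.001)
    if optimizer == "gfsgd":
        opt = GFSGD(config)
    elif optimizer == "sgd":
        opt = _PlainSGD(config.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    rng = np.random.default_rng(seed)
    history = TrainingHistory(config={**config.to_dict(), "epochs": epochs,
                                      "batch_size": batch_size, "seed": seed,
                                      "optimizer": optimizer})
    n = len(x_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            loss, probs, grads = net.loss_and_grads(xb, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch + 1, start // batch_size + 1,
                                       history)
            losses.append(loss * len(idx))
            correct += int(np.sum(probs.argmax(axis=1) == yb))
            try:
                net.set_parameters(opt.update(net.parameters(), grads))
            except FloatingPointError as err:  # non-finite parameter update
                raise TrainingDiverged(epoch + 1, start // batch_size + 1,
                                       history) from err
        history.train_loss.append(float(np.sum(losses) / n))
        history.train_accuracy.append(correct / n)
        if x_val is not None and len(x_val):
            vl, va = _evaluate(net, x_val, y_val)
        else:
            vl, va = float("nan"), float("nan")
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
    return history


def alpha_sweep(
    build_net,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    alpha_grid,
    learning_rate: float = 0.001,
    epochs: int = 35,
    batch_size: int = 32,
    seed: int = 0,
) -> pd.DataFrame:
    """One training run per fractional order, identical init and data order.

    ``build_net`` is a zero-argument factory returning a fresh
    :class:`Network`; it must be deterministic so every alpha starts
    from identical weights.  Returns a table of final and best
    validation accuracy/loss per alpha.  A run whose loss diverges is
    recorded with final accuracy 0.0 and infinite loss (flagged in the
    ``diverged`` column), with best-so-far values from its partial
    history.
    """
    rows = []
    for alpha in alpha_grid:
        net = build_net()
        cfg = FractionalConfig(alpha=float(alpha), learning_rate=learning_rate)
        try:
            hist = train(net, x_train, y_train, x_val, y_val, config=cfg,
                         epochs=epochs, batch_size=batch_size, seed=seed)
            final_acc, final_loss = hist.val_accuracy[-1], hist.val_loss[-1]
            diverged = False
        except TrainingDiverged as err:
            hist = err.history
            final_acc, final_loss = 0.0, float("inf")
            diverged = True
        best_acc = float(np.nanmax(hist.val_accuracy)) if hist.epochs else 0.0
        min_loss = (float(np.nanmin(hist.val_loss)) if hist.epochs
                    else float("inf"))
        rows.append(
            {
                "alpha": float(alpha),
                "final_val_accuracy": final_acc,
                "final_val_loss": final_loss,
                "best_val_accuracy": best_acc,
                "min_val_loss": min_loss,
                "diverged": diverged,
            }
        )
    return pd.DataFrame(rows)


class FrCNNClassifier(BaseEstimator, ClassifierMixin):
    """Attention/mixed-pooling CNN trained with fractional-order SGD.

    A scikit-learn style estimator over image batches shaped
    ``(n_samples, H, W, C)`` (flat input is not supported — the
    architecture is spatial).  ``alpha`` is the fractional order of the
    optimizer; ``alpha = 1`` is plain SGD, the recommended setting is
    ``alpha = 1.5`` with ``learning_rate = 0.001``.

    Parameters
    ----------
    alpha : float, default 1.5
        Fractional order in (0, 2).
    learning_rate : float, default 0.001
    epsilon : float, default 1e-8
        Stabilizer in the fractional scale factor.
    first_step_mode : {"plain_sgd", "epsilon_power"}
    conv_filters, dense_units : tuple of int
        Widths of the two conv stages and the two hidden dense layers.
        Defaults are the full-size architecture (200, 100) / (100, 50);
        reduce for desk-scale experiments.
    epochs : int, default 35
    batch_size : int, default 32
    validation_fraction : float, default 0.15
        Stratified share of the training data monitored per epoch.
    optimizer : {"gfsgd", "sgd"}
    dtype : numpy dtype, default float32
    random_state : int, default 0

    Attributes
    ----------
    network_ : Network
        The trained runtime network.
    history_ : TrainingHistory
    classes_ : ndarray
    n_features_in_ : int
    """

    def __init__(
        self,
        alpha: float = 1.5,
        learning_rate: float = 0.001,
        epsilon: float = 1e-8,
        first_step_mode: str = "plain_sgd",
        conv_filters: tuple[int, int] = (200, 100),
        dense_units: tuple[int, int] = (100, 50),
        kernel: tuple[int, int] = (3, 3),
        pool: tuple[int, int] = (2, 2),
        epochs: int = 35,
        batch_size: int = 32,
        validation_fraction: float = 0.15,
        optimizer: str = "gfsgd",
        dtype="float32",
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.epsilon = epsilon
        self.first_step_mode = first_step_mode
        self.conv_filters = conv_filters
        self.dense_units = dense_units
        self.kernel = kernel
        self.pool = pool
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.optimizer = optimizer
        self.dtype = dtype
        self.random_state = random_state

    def _check_x(self, x):
        x = np.asarray(x)
        if x.ndim != 4:
            raise ValueError(f"X must be (n, H, W, C) images, got {x.ndim}-D")
        if not np.all(np.isfinite(x)):
            raise ValueError("X must be finite")
        return x

    def fit(self, X, y):
        X = self._check_x(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        self.input_shape_ = X.shape[1:]

        spec = build_frcnn(self.input_shape_, len(self.classes_),
                           self.conv_filters, self.dense_units,
                           self.kernel, self.pool)
        rng = np.random.default_rng(self.random_state)
        net = Network(spec, rng, dtype=self.dtype)

        if self.validation_fraction > 0:
            from .synth import stratified_indices

            tr_idx, val_idx = stratified_indices(
                y_enc, self.validation_fraction,
                np.random.default_rng(self.random_state + 1))
            x_tr, y_tr = X[tr_idx], y_enc[tr_idx]
            x_val, y_val = X[val_idx], y_enc[val_idx]
        else:
            x_tr, y_tr, x_val, y_val = X, y_enc, None, None

        cfg = FractionalConfig(self.alpha, self.learning_rate, self.epsilon,
                               self.first_step_mode)
        self.history_ = train(net, x_tr, y_tr, x_val, y_val, config=cfg,
                              epochs=self.epochs, batch_size=self.batch_size,
                              seed=self.random_state, optimizer=self.optimizer)
        self.network_ = net
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = self._check_x(X)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"image shape {X.shape[1:]} != fitted shape {self.input_shape_}")
        return self.network_.predict_proba(X)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]


# --- checkpoints ------------------------------------------------------------

def save_weights(net: Network, path) -> None:
    """HDF5 checkpoint: one group per layer, datasets weights/bias."""
    convs = [l.filters for l in net.layers if l.kind == "conv2d"]
    denses = [l.units for l in net.layers if l.kind == "dense"]
    with h5py.File(path, "w") as f:
        f.attrs["input_shape"] = net.spec.input_shape
        f.attrs["num_classes"] = net.spec.num_classes
        f.attrs["conv_filters"] = convs
        f.attrs["dense_units"] = denses[:-1]
        for i, layer in enumerate(net.layers):
            grp = f.create_group(f"layer_{i:02d}")
            grp.attrs["kind"] = layer.kind
            if layer.weights is not None:
                grp.create_dataset("weights", data=layer.weights)
            if layer.bias is not None:
                grp.create_dataset("bias", data=layer.bias)


def load_weights(net: Network, path) -> Network:
    """Load an HDF5 checkpoint into a compatibly-built network."""
    with h5py.File(path, "r") as f:
        for i, layer in enumerate(net.layers):
            grp = f[f"layer_{i:02d}"]
            if grp.attrs["kind"] != layer.kind:
                raise ValueError(
                    f"layer {i} kind mismatch: checkpoint has "
                    f"{grp.attrs['kind']!r}, network has {layer.kind!r}")
            if layer.weights is not None:
                layer.weights = grp["weights"][...].astype(net.dtype)
            if layer.bias is not None:
                layer.bias = grp["bias"][...].astype(net.dtype)
    return net


def load_network(path, dtype=np.float32) -> Network:
    """Rebuild a network from checkpoint attributes and load its weights."""
    with h5py.File(path, "r") as f:
        spec = build_frcnn(
            tuple(int(v) for v in f.attrs["input_shape"]),
            int(f.attrs["num_classes"]),
            tuple(int(v) for v in f.attrs["conv_filters"]),
            tuple(int(v) for v in f.attrs["dense_units"]),
        )
    net = Network(spec, np.random.default_rng(0), dtype=dtype)
    return load_weights(net, path)
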