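"""From-scratch dense, deep and 1-D convolutional regression networks.

Three architectures map a 256-point NIR spectrum to a single regression
output (moisture or aging time):

* ANN  — 256 -> H -> 1 (one hidden layer);
* DNN  — 256 -> H -> H -> H -> 1 (three equal hidden layers);
* CNN  — 256 -> conv1d(F filters, kernel 5, valid) -> flatten -> D -> 1.

Hidden activations are ReLU with configurable slope ``a`` (``a x`` for
``x > 0``, else 0); the output node is linear.  Weights are He-initialized
(Gaussian, SD ``sqrt(2 / fan_in)``), biases start at zero.  Training is
mini-batch gradient descent on the mean-squared error, plain or with the
Adam optimizer (bias-corrected first/second moment estimates), exact
gradients by reverse-mode accumulation.  Everything is plain numpy and
deterministic for fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


def relu(x, a: float = 1.0):
    """Rectified linear activation: ``a * x`` for positive x, else 0."""
    if a <= 0:
        raise ValueError("activation slope must be positive")
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, a * x, 0.0)


def relu_grad(x, a: float = 1.0):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, a, 0.0)


def he_init_sigma(n_layer_nodes: int) -> float:
    """Standard deviation ``sqrt(2 / N)`` of the He weight initialization."""
    if n_layer_nodes < 1:
        raise ValueError("node count must be at least 1")
    return float(np.sqrt(2.0 / n_layer_nodes))


def dense_forward(inputs: np.ndarray, weights: np.ndarray, biases: np.ndarray | None = None) -> np.ndarray:
    """Fully connected affine map: every output node is the weighted sum of
    all inputs plus its bias.  ``inputs`` is (batch, n_in) or (n_in,)."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    W = np.asarray(weights, dtype=float)
    if x.shape[1] != W.shape[0]:
        raise ValueError(f"input dimension {x.shape[1]} does not match weights {W.shape}")
    out = x @ W
    if biases is not None:
        out = out + np.asarray(biases, dtype=float)
    return out[0] if np.asarray(inputs).ndim == 1 else out

def conv1d_forward(inputs: np.ndarray, kernels: np.ndarray, biases: np.ndarray | None = None) -> np.ndarray:
    """Valid-mode sliding cross-correlation of each filter with the input.

    ``inputs`` is (batch, n) or (n,); ``kernels`` is (n_filters, k).  Output
    is (batch, n_filters, n - k + 1): position w of filter f is
    ``sum_k inputs[w + k] * kernels[f, k] + bias[f]``.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    K = np.atleast_2d(np.asarray(kernels, dtype=float))
    k = K.shape[1]
    if k > x.shape[1]:
        raise ValueError(f"kernel size {k} exceeds input length {x.shape[1]}")
    windows = sliding_window_view(x, k, axis=1)  # (batch, n-k+1, k)
    out = np.einsum("bwk,fk->bfw", windows, K)
    if biases is not None:
        out = out + np.asarray(biases, dtype=float)[None, :, None]
    return out[0] if np.asarray(inputs).ndim == 1 else out


@dataclass
class Layer:
    """One runtime layer: weights/biases (empty for flatten) and activation."""

    kind: str  # dense | conv1d | flatten
    W: np.ndarray | None = None  # dense: (n_in, n_out); conv1d: (F, k)
    b: np.ndarray | None = None
    activate: bool = True  # ReLU on outputs; False for the output layer
    slope: float = 1.0

    @property
    def has_params(self) -> bool:
        return self.W is not None


@dataclass
class NetworkState:
    """Ordered layers plus the seed that produced the initial weights."""

    layers: list
    input_dim: int
    init_seed: int
    arch: str = "custom"

    def parameters(self) -> list:
        return [(ly.W, ly.b) for ly in self.layers if ly.has_params]

    def set_parameters(self, params: list) -> None:
        it = iter(params)
        for ly in self.layers:
            if ly.has_params:
                ly.W, ly.b = next(it)

    def n_parameters(self) -> int:
        return int(sum(W.size + b.size for W, b in self.parameters()))

    def copy(self) -> "NetworkState":
        layers = [
            Layer(ly.kind, None if ly.W is None else ly.W.copy(),
                  None if ly.b is None else ly.b.copy(), ly.activate, ly.slope)
            for ly in self.layers
        ]
        return NetworkState(layers, self.input_dim, self.init_seed, self.arch)


def _he_dense(rng, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, he_init_sigma(n_in), size=(n_in, n_out))


def build_ann(hidden_nodes: int, input_dim: int = 256, seed: int = 0, slope: float = 1.0) -> NetworkState:
    """Three-layer network: input -> one ReLU hidden layer -> linear output."""
    if hidden_nodes < 1:
        raise ValueError("hidden node count must be positive")
    rng = np.random.default_rng(seed)
    layers = [
        Layer("dense", _he_dense(rng, input_dim, hidden_nodes), np.zeros(hidden_nodes), True, slope),
        Layer("dense", _he_dense(rng, hidden_nodes, 1), np.zeros(1), False, slope),
    ]
    return NetworkState(layers, input_dim, seed, "ann")


def build_dnn(nodes_per_layer: int, input_dim: int = 256, seed: int = 0, slope: float = 1.0) -> NetworkState:
    """Deep variant: three equal ReLU hidden layers before the linear output."""
    if nodes_per_layer < 1:
        raise ValueError("hidden node count must be positive")
    rng = np.random.default_rng(seed)
    h = nodes_per_layer
    layers = [
        Layer("dense", _he_dense(rng, input_dim, h), np.zeros(h), True, slope),
        Layer("dense", _he_dense(rng, h, h), np.zeros(h), True, slope),
        Layer("dense", _he_dense(rng, h, h), np.zeros(h), True, slope),
        Layer("dense", _he_dense(rng, h, 1), np.zeros(1), False, slope),
    ]
    return NetworkState(layers, input_dim, seed, "dnn")


def build_cnn(
    n_filters: int,
    dense_nodes: int = 200,
    kernel_size: int = 5,
    input_dim: int = 256,
    seed: int = 0,
    slope: float = 1.0,
) -> NetworkState:
    """Convolutional variant: conv1d (valid, stride 1) -> flatten -> dense -> output."""
    if n_filters < 1 or dense_nodes < 1:
        raise ValueError("filter and node counts must be positive")
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel size must be odd and positive")
    rng = np.random.default_rng(seed)
    conv_w = rng.normal(0.0, he_init_sigma(kernel_size), size=(n_filters, kernel_size))
    flat_dim = n_filters * (input_dim - kernel_size + 1)
    layers = [
        Layer("conv1d", conv_w, np.zeros(n_filters), True, slope),
        Layer("flatten", None, None, False, slope),
        Layer("dense", _he_dense(rng, flat_dim, dense_nodes), np.zeros(dense_nodes), True, slope),
        Layer("dense", _he_dense(rng, dense_nodes, 1), np.zeros(1), False, slope),
    ]
    return NetworkState(layers, input_dim, seed, "cnn")


def forward(net: NetworkState, X: np.ndarray, keep_cache: bool = False):
    """Run the network; returns predictions (batch,) and, optionally, the
    per-layer (input, pre-activation) cache for backpropagation."""
    a = np.atleast_2d(np.asarray(X, dtype=float))
    if a.shape[1] != net.input_dim:
        raise ValueError(f"input dimension {a.shape[1]} != network input {net.input_dim}")
    cache = []
    for ly in net.layers:
        if ly.kind == "dense":
            if a.ndim != 2:
                raise ValueError("dense layer needs flattened input")
            z = a @ ly.W + ly.b
        elif ly.kind == "conv1d":
            z = conv1d_forward(a, ly.W, ly.b)
        elif ly.kind == "flatten":
            z = a.reshape(a.shape[0], -1)
        else:
            raise ValueError(f"unknown layer kind {ly.kind!r}")
        if keep_cache:
            cache.append((a, z))
        a = relu(z, ly.slope) if ly.activate else z
    out = a[:, 0] if a.ndim == 2 and a.shape[1] == 1 else a
    return (out, cache) if keep_cache else out


def predict(net: NetworkState, X: np.ndarray) -> np.ndarray:
    return forward(net, X)


def backprop_gradients(net: NetworkState, batch_X: np.ndarray, batch_y: np.ndarray) -> list:
    """Exact gradients of the batch mean-squared error.

    Returns ``[(dW, db), ...]`` aligned with ``net.parameters()``.
    """
    X = np.atleast_2d(np.asarray(batch_X, dtype=float))
    y = np.asarray(batch_y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("batch X and y sizes differ")
    pred, cache = forward(net, X, keep_cache=True)
    n = y.shape[0]
    grads = []
    d_out = (2.0 / n) * (pred - y)[:, None]  # dL/d(output activation)
    d_a = d_out
    for ly, (a_in, z) in zip(reversed(net.layers), reversed(cache)):
        d_z = d_a * relu_grad(z, ly.slope) if ly.activate else d_a
        if ly.kind == "dense":
            dW = a_in.T @ d_z
            db = d_z.sum(axis=0)
            d_a = d_z @ ly.W.T
            grads.append((dW, db))
        elif ly.kind == "conv1d":
            k = ly.W.shape[1]
            windows = sliding_window_view(a_in, k, axis=1)  # (batch, L, k)
            dW = np.einsum("bfw,bwk->fk", d_z, windows)
            db = d_z.sum(axis=(0, 2))
            # input gradient = full convolution of d_z with each kernel
            pad = np.pad(d_z, ((0, 0), (0, 0), (k - 1, k - 1)))
            pw = sliding_window_view(pad, k, axis=2)  # (batch, F, n, k)
            d_a = np.einsum("bfik,fk->bi", pw, ly.W[:, ::-1])
            grads.append((dW, db))
        elif ly.kind == "flatten":
            d_a = d_z.reshape(a_in.shape)
    grads.reverse()
    return grads


def sgd_step(weights: np.ndarray, gradients: np.ndarray, eta: float) -> np.ndarray:
    """Plain gradient-descent update ``w - eta * g``."""
    w = np.asarray(weights, dtype=float)
    g = np.asarray(gradients, dtype=float)
    if w.shape != g.shape:
        raise ValueError("weight and gradient shapes differ")
    return w - eta * g


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch training configuration (Adam defaults, >= 100 epochs)."""

    epochs: int = 200
    batch_size: int = 32
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate >= 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie strictly in (0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""

    m: list
    v: list
    t: int = 0

    @classmethod
    def init(cls, params: list) -> "AdamState":
        return cls(
            m=[(np.zeros_like(W), np.zeros_like(b)) for W, b in params],
            v=[(np.zeros_like(W), np.zeros_like(b)) for W, b in params],
        )


def adam_step(params: list, grads: list, state: AdamState, config: TrainConfig) -> tuple[list, AdamState]:
    """One bias-corrected Adam update over a list of (W, b) parameter pairs."""
    state.t += 1
    b1, b2, eps, eta = config.beta1, config.beta2, config.eps, config.learning_rate
    c1 = 1.0 - b1**state.t
    c2 = 1.0 - b2**state.t
    new_params = []
    for i, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
        mW, mb = state.m[i]
        vW, vb = state.v[i]
        mW = b1 * mW + (1 - b1) * gW
        mb = b1 * mb + (1 - b1) * gb
        vW = b2 * vW + (1 - b2) * gW**2
        vb = b2 * vb + (1 - b2) * gb**2
        state.m[i] = (mW, mb)
        state.v[i] = (vW, vb)
        W = W - eta * (mW / c1) / (np.sqrt(vW / c2) + eps)
        b = b - eta * (mb / c1) / (np.sqrt(vb / c2) + eps)
        new_params.append((W, b))
    return new_params, state


def train(
    net: NetworkState,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[NetworkState, np.ndarray]:
    """Mini-batch training on the mean-squared error.

    Inputs and targets are expected on the [0, 1] min-max scale.  The batch
    order is reshuffled every epoch from ``config.seed``; the returned loss
    history holds the full-training-set MSE after each epoch.  Raises
    :class:`TrainingDiverged` if the loss becomes non-finite.
    """
    config = TrainConfig() if config is None else config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    net = net.copy()
    rng = np.random.default_rng(config.seed)
    adam = AdamState.init(net.parameters()) if config.optimizer == "adam" else None
    history = np.empty(config.epochs)
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grads = backprop_gradients(net, X[idx], y[idx])
            params = net.parameters()
            if config.optimizer == "adam":
                params, adam = adam_step(params, grads, adam, config)
            else:
                params = [
                    (sgd_step(W, gW, config.learning_rate), sgd_step(b, gb, config.learning_rate))
                    for (W, b), (gW, gb) in zip(params, grads)
                ]
            net.set_parameters(params)
        loss = float(np.mean((forward(net, X) - y) ** 2))
        if not np.isfinite(loss):
            raise TrainingDiverged(epoch)
        history[epoch] = loss
    return net, history


def architecture_sweep(
    builder,
    parameter_grid,
    X: np.ndarray,
    y: np.ndarray,
    split,
    train_config: TrainConfig | None = None,
    n_repeats: int = 1,
):
    """Build/train/evaluate a network for every grid point.

    ``builder`` is one of :func:`build_ann` / :func:`build_dnn` /
    :func:`build_cnn` (or any callable of signature ``builder(p, seed=...)``);
    ``parameter_grid`` is the swept sizes — default grids elsewhere are
    100..1000 nodes (step 100) for dense networks and 2..18 filters (step 2,
    nine configurations) for the CNN.  Returns a pandas table of
    :class:`~nirdry.chemometrics.FitMetrics` fields per configuration and
    repeat.
    """
    import pandas as pd

    from .chemometrics import evaluate_fit, split_train_val

    train_config = TrainConfig() if train_config is None else train_config
    grid = list(parameter_grid)
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    cal, val = split_train_val(len(y), split)
    rows = []
    for p in grid:
        for rep in range(n_repeats):
            seed = int((train_config.seed + 1) * 10_000 + rep) % (2**31)
            net = builder(p, input_dim=X.shape[1], seed=seed)
            cfg = replace(train_config, seed=seed)
            fitted, history = train(net, X[cal], y[cal], cfg)
            m = evaluate_fit(
                y[cal], predict(fitted, X[cal]), y[val], predict(fitted, X[val]),
                n_params=fitted.n_parameters(),
            )
            rows.append(
                {
                    "parameter": p,
                    "repeat": rep,
                    "rmsec": m.rmsec,
                    "rmsev": m.rmsev,
                    "r2_cal": m.r2_cal,
                    "r2_val": m.r2_val,
                    "final_loss": history[-1],
                }
            )
    return pd.DataFrame(rows)


ANN_NODE_GRID = tuple(range(100, 1001, 100))
DNN_NODE_GRID = tuple(range(100, 1001, 100))
CNN_FILTER_GRID = tuple(range(2, 19, 2))  # nine configurations
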