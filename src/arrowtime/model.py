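"""The window-direction classifier: a deep fully connected network.

A window pattern (flattened N regions x w timepoints) is classified as
*forward* or *backward*.  The architecture is an input layer of size N*w
followed by ten fully connected layers of dimensions
2048, 1024, 512, 256, 128, 64, 32, 16, 8, 4 — each with batch
normalization and a ReLU — and a final fully connected softmax layer of
dimension 2.  Class coding: output 1 is backward, output 2 is forward
(targets [1, 0] and [0, 1]).

Training is plain mini-batch Adam with cross-entropy loss, L2 weight decay,
a fixed number of epochs and a single dataset shuffle before the first
epoch.  Everything is implemented in numpy in float32, single-threaded and
bit-deterministic under the training seed.  At evaluation, batch-norm
layers use running statistics accumulated during training.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

HIDDEN_DIMS = (2048, 1024, 512, 256, 128, 64, 32, 16, 8, 4)
N_CLASSES = 2
_BN_EPS = 1e-5


@dataclass
class TrainConfig:
    """Optimizer settings (Adam with defaults commonly used for this task)."""

    learning_rate: float = 1e-3
    l2: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    max_epochs: int = 10
    minibatch: int = 128
    shuffle: str = "once"
    seed: int = 0
    bn_momentum: float = 0.1

    def __post_init__(self):
        for name in ("learning_rate", "beta1", "beta2", "epsilon",
                     "max_epochs", "minibatch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.shuffle not in ("once", "every-epoch", "never"):
            raise ValueError(f"unknown shuffle mode {self.shuffle!r}")


@dataclass
class DirectionNet:
    """Weights, batch-norm state and provenance of the direction classifier."""

    layer_dims: list
    weights: list = field(repr=False, default_factory=list)
    biases: list = field(repr=False, default_factory=list)
    gamma: list = field(repr=False, default_factory=list)
    beta: list = field(repr=False, default_factory=list)
    running_mean: list = field(repr=False, default_factory=list)
    running_var: list = field(repr=False, default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return self.layer_dims[0]

    @property
    def n_hidden_layers(self) -> int:
        return len(self.layer_dims) - 2

    # -- forward pass -----------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Softmax outputs, shape (n, 2); column 1 is the forward class."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"pattern length {X.shape[1]} does not match the model's "
                f"expected N*w = {self.n_inputs}"
            )
        outs = []
        for lo in range(0, X.shape[0], batch_size):
            h = X[lo:lo + batch_size]
            for l in range(self.n_hidden_layers):
                z = h @ self.weights[l] + self.biases[l]
                zhat = (z - self.running_mean[l]) / np.sqrt(
                    self.running_var[l] + _BN_EPS)
                h = np.maximum(self.gamma[l] * zhat + self.beta[l], 0.0)
            logits = h @ self.weights[-1] + self.biases[-1]
            outs.append(_softmax(logits))
        return np.concatenate(outs).astype(np.float64)

    def apply(self, pattern_vector: np.ndarray) -> np.ndarray:
        """Classify one flattened window; returns the 2-simplex output."""
        return self.predict_proba(np.asarray(pattern_vector).ravel()[None, :])[0]

    # -- persistence ------------------------------------------------------

    def save(self, path: str) -> None:
        """Write weights to ``path`` (npz) and metadata to ``path`` + .json."""
        arrays = {}
        for name in ("weights", "biases", "gamma", "beta",
                     "running_mean", "running_var"):
            for i, a in enumerate(getattr(self, name)):
                arrays[f"{name}_{i}"] = a
        np.savez(path, layer_dims=np.array(self.layer_dims), **arrays)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def load(cls, path: str) -> "DirectionNet":
        if not str(path).endswith(".npz") and os.path.exists(str(path) + ".npz"):
            path = str(path) + ".npz"
        with np.load(path) as data:
            layer_dims = [int(d) for d in data["layer_dims"]]
            net = cls(layer_dims)
            n_hidden = len(layer_dims) - 2
            for name, n in (("weights", n_hidden + 1), ("biases", n_hidden + 1),
                            ("gamma", n_hidden), ("beta", n_hidden),
                            ("running_mean", n_hidden), ("running_var", n_hidden)):
                setattr(net, name, [data[f"{name}_{i}"] for i in range(n)])
        meta_path = str(path).removesuffix(".npz") + ".json"
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                net.metadata = json.load(fh)
        return net


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_net(n_inputs: int, seed: int = 0,
              metadata: dict | None = None) -> DirectionNet:
    """Initialize the network with Glorot-uniform weights, zero biases,
    unit batch-norm scale and zero shift; deterministic under ``seed``."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    dims = [int(n_inputs), *HIDDEN_DIMS, N_CLASSES]
    rng = np.random.default_rng(seed)
    net = DirectionNet(dims, metadata=dict(metadata or {}))
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        net.weights.append(
            rng.uniform(-bound, bound, (fan_in, fan_out)).astype(np.float32))
        net.biases.append(np.zeros(fan_out, dtype=np.float32))
    for d in dims[1:-1]:
        net.gamma.append(np.ones(d, dtype=np.float32))
        net.beta.append(np.zeros(d, dtype=np.float32))
        net.running_mean.append(np.zeros(d, dtype=np.float32))
        net.running_var.append(np.ones(d, dtype=np.float32))
    net.metadata.setdefault("init_seed", int(seed))
    net.metadata["layer_dims"] = dims
    net.metadata["flatten_order"] = "region-major"
    net.metadata["class_coding"] = {"backward": 0, "forward": 1}
    return net


def train_net(net: DirectionNet, X: np.ndarray, y: np.ndarray,
              config: TrainConfig | None = None,
              validation: tuple | None = None) -> DirectionNet:
    """Train in place with mini-batch Adam; returns the trained net.

    ``y`` holds class indices (0 backward, 1 forward).  ``validation``, if
    given as (X_val, y_val), is monitored (loss/accuracy recorded in
    ``metadata['history']``) but never acted on: the epoch count is fixed.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D pattern array")
    if X.shape[1] != net.n_inputs:
        raise ValueError(
            f"pattern length {X.shape[1]} does not match the model's "
            f"expected N*w = {net.n_inputs}"
        )
    if X.shape[0] < config.minibatch:
        raise ValueError("minibatch larger than the dataset")
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n) if config.shuffle != "never" else np.arange(n)

    params = (net.weights + net.biases + net.gamma + net.beta)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    n_hidden = net.n_hidden_layers
    step = 0
    history = []
    init_loss = None
    for epoch in range(config.max_epochs):
        if config.shuffle == "every-epoch" and epoch > 0:
            order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, config.minibatch):
            idx = order[lo:lo + config.minibatch]
            h = X[idx]
            yb = y[idx]
            # forward pass, caching what backprop needs
            cache = []
            for l in range(n_hidden):
                z = h @ net.weights[l] + net.biases[l]
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                inv = 1.0 / np.sqrt(var + _BN_EPS)
                zhat = (z - mu) * inv
                a = net.gamma[l] * zhat + net.beta[l]
                out = np.maximum(a, 0.0)
                cache.append((h, zhat, inv, out))
                mom = np.float32(config.bn_momentum)
                net.running_mean[l] = ((1 - mom) * net.running_mean[l]
                                       + mom * mu)
                net.running_var[l] = ((1 - mom) * net.running_var[l]
                                      + mom * var)
                h = out
            logits = h @ net.weights[-1] + net.biases[-1]
            probs = _softmax(logits)
            b = len(idx)
            loss = -np.mean(np.log(probs[np.arange(b), yb] + 1e-12))
            epoch_loss += float(loss)
            n_batches += 1
            if init_loss is None:
                init_loss = float(loss)
            # backward pass
            gW = [None] * (n_hidden + 1)
            gb = [None] * (n_hidden + 1)
            gg = [None] * n_hidden
            gbeta = [None] * n_hidden
            delta = probs.copy()
            delta[np.arange(b), yb] -= 1.0
            delta /= b
            delta = delta.astype(np.float32)
            gW[-1] = cache[-1][3].T @ delta if n_hidden else X[idx].T @ delta
            gb[-1] = delta.sum(axis=0)
            grad_h = delta @ net.weights[-1].T
            for l in range(n_hidden - 1, -1, -1):
                h_in, zhat, inv, out = cache[l]
                grad_a = grad_h * (out > 0)
                gg[l] = (grad_a * zhat).sum(axis=0)
                gbeta[l] = grad_a.sum(axis=0)
                grad_zhat = grad_a * net.gamma[l]
                # batch-norm backward
                grad_z = (inv / b) * (
                    b * grad_zhat
                    - grad_zhat.sum(axis=0)
                    - zhat * (grad_zhat * zhat).sum(axis=0)
                )
                gW[l] = h_in.T @ grad_z
                gb[l] = grad_z.sum(axis=0)
                grad_h = grad_z @ net.weights[l].T
            # L2 weight decay on weights only (not biases / BN parameters)
            grads = gW + gb + gg + gbeta
            for i, W in enumerate(net.weights):
                grads[i] = grads[i] + np.float32(config.l2) * W
            # Adam update
            step += 1
            b1, b2 = config.beta1, config.beta2
            corr1 = 1 - b1 ** step
            corr2 = 1 - b2 ** step
            lr = config.learning_rate
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                p -= np.float32(lr) * (m[i] / corr1) / (
                    np.sqrt(v[i] / corr2) + np.float32(config.epsilon))
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if validation is not None:
            Xv, yv = validation
            pv = net.predict_proba(Xv)
            entry["val_loss"] = float(-np.mean(
                np.log(pv[np.arange(len(yv)), np.asarray(yv, int)] + 1e-12)))
            entry["val_accuracy"] = float(
                np.mean(pv.argmax(axis=1) == np.asarray(yv, int)))
        history.append(entry)
    _finalize_bn_stats(net, X, config.minibatch)
    net.metadata["history"] = history
    net.metadata["train_config"] = dataclasses.asdict(config)
    net.metadata["initial_loss"] = init_loss
    return net


def _finalize_bn_stats(net: DirectionNet, X: np.ndarray,
                       batch_size: int) -> None:
    """Replace running batch-norm statistics with population statistics.

    After the last optimizer step the exponential running averages lag the
    final weights; a full pass over the training data under the trained
    weights gives the population mean/variance each layer actually sees at
    evaluation time.
    """
    # layer by layer: the statistics of layer l must be computed under the
    # (population-normalized) activations of the layers before it
    h = X
    for l in range(net.n_hidden_layers):
        z = h @ net.weights[l] + net.biases[l]
        mean = z.mean(axis=0, dtype=np.float64)
        var = z.astype(np.float64).var(axis=0)
        net.running_mean[l] = mean.astype(np.float32)
        net.running_var[l] = var.astype(np.float32)
        zhat = (z - net.running_mean[l]) / np.sqrt(
            net.running_var[l] + _BN_EPS)
        h = np.maximum(net.gamma[l] * zhat + net.beta[l], 0.0)


def accuracy(net: DirectionNet, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of patterns whose argmax class matches ``y``."""
    probs = net.predict_proba(X)
    return float(np.mean(probs.argmax(axis=1) == np.asarray(y, int)))
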