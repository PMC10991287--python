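"""Multilayer dense network with Gaussian hidden activations.

Hidden units compute a = exp(-z²) of their affine pre-activation
z = b + Σ w·x — a radial-basis-style squashing that peaks at 1 on the unit's
decision surface and decays symmetrically — and the single output unit is
linear.  Training is per-sample (online) backpropagation: the output error
e = d - r is propagated through the activation derivatives
(d/dz) exp(-z²) = -2z·exp(-z²) and each weight moves by α·k·input.

Despite its lineage the architecture is fully dense: the defining equations
contain no convolution, so none is implemented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records_io import DomainError


class ShapeError(ValueError):
    """Input/weight shape mismatch."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def gaussian(x):
    """Gaussian activation exp(-x²); range (0, 1], symmetric about 0."""
    return np.exp(-np.square(x))


def gaussian_derivative(x):
    """d/dx exp(-x²) = -2x·exp(-x²); vanishes at the activation peak."""
    return -2.0 * np.asarray(x) * np.exp(-np.square(x))


def weighted_sum(F: Sequence[float], W: Sequence[float]) -> float:
    """Σ F_i·W_i (the unit's pre-activation before bias)."""
    F = np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    if F.shape != W.shape:
        raise ShapeError(f"length mismatch: {F.shape} vs {W.shape}")
    return float(F @ W)


@dataclass
class NetworkConfig:
    """Architecture and online-training hyperparameters.

    ``alpha`` is the learning-rate (momentum) coefficient of the weight
    update; ``init_scale`` the half-range of the uniform weight init;
    ``threshold`` the downstream decision cutoff on the linear output.
    """

    layer_sizes: tuple[int, ...] = (13, 8, 1)
    alpha: float = 0.05
    epochs: int = 100
    init_scale: float = 0.5
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 3:
            raise DomainError("need at least one hidden layer")
        if self.layer_sizes[-1] != 1:
            raise DomainError("output layer must have exactly one unit")
        if self.alpha <= 0:
            raise DomainError("alpha must be positive")


@dataclass
class Network:
    """Per-layer weight matrices (out x in) and bias vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        for i in range(len(self.weights) - 1):
            if self.weights[i + 1].shape[1] != self.weights[i].shape[0]:
                raise ShapeError("layer shapes do not chain")
        for W, b in zip(self.weights, self.biases):
            if W.shape[0] != b.shape[0]:
                raise ShapeError("bias length does not match layer width")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(W.shape[0] for W in self.weights)

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def copy(self) -> "Network":
        return Network([W.copy() for W in self.weights],
                       [b.copy() for b in self.biases])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "layer_sizes": list(self.layer_sizes),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "Network":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls([np.array(W, dtype=float) for W in data["weights"]],
                   [np.array(b, dtype=float) for b in data["biases"]])


def init_network(cfg: NetworkConfig) -> Network:
    """Uniform weight/bias init on [-init_scale, +init_scale], seeded."""
    rng = np.random.default_rng(cfg.seed)
    weights, biases = [], []
    for n_in, n_out in zip(cfg.layer_sizes[:-1], cfg.layer_sizes[1:]):
        weights.append(rng.uniform(-cfg.init_scale, cfg.init_scale, (n_out, n_in)))
        biases.append(rng.uniform(-cfg.init_scale, cfg.init_scale, n_out))
    return Network(weights, biases)


@dataclass
class ForwardTrace:
    """Per-layer pre-activations and activations recorded by a forward pass."""

    pre_activations: list[np.ndarray] = field(default_factory=list)
    activations: list[np.ndarray] = field(default_factory=list)


def forward(net: Network, F: np.ndarray) -> tuple[float, ForwardTrace]:
    """Single-row forward pass: Gaussian hidden layers, linear output."""
    x = np.asarray(F, dtype=float)
    if x.shape != (net.weights[0].shape[1],):
        raise ShapeError(
            f"input length {x.shape} does not match {net.weights[0].shape[1]}")
    trace = ForwardTrace(activations=[x])
    n_layers = len(net.weights)
    for layer, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = b + W @ x
        trace.pre_activations.append(z)
        x = z if layer == n_layers - 1 else gaussian(z)
        trace.activations.append(x)
    return float(x[0]), trace


def forward_batch(net: Network, X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over the rows of X (same math as forward)."""
    A = np.asarray(X, dtype=float)
    n_layers = len(net.weights)
    for layer, (W, b) in enumerate(zip(net.weights, net.biases)):
        Z = A @ W.T + b
        A = Z if layer == n_layers - 1 else gaussian(Z)
    return A[:, 0]


def output_error(d: float, r: float) -> float:
    """Error signal e = target - output."""
    return d - r


def error_signal(e: float, pre_activation: float, derivative=None) -> float:
    """Propagated signal k = e·f(z) with f the activation derivative at the
    unit's pre-activation (f ≡ 1 for the linear output unit)."""
    f = 1.0 if derivative is None else derivative(pre_activation)
    return e * f


def weight_delta(alpha: float, k: float, F: float) -> float:
    """Additive weight adjustment α·k·input."""
    return alpha * k * F


def _backprop_step(net: Network, x: np.ndarray, d: float, alpha: float) -> float:
    """One online update on sample (x, d); returns the pre-update sq. error."""
    r, trace = forward(net, x)
    e = output_error(d, r)
    n_layers = len(net.weights)
    # output layer: linear, so delta = e
    delta = np.array([e])
    for layer in range(n_layers - 1, -1, -1):
        a_prev = trace.activations[layer]
        grad_W = np.outer(delta, a_prev)
        net.weights[layer] += alpha * grad_W
        net.biases[layer] += alpha * delta
        if layer > 0:
            # propagate through the previous Gaussian layer
            back = net.weights[layer].T @ delta
            delta = back * gaussian_derivative(trace.pre_activations[layer - 1])
    return e * e


def train_backprop(net: Network, X: np.ndarray, y: np.ndarray,
                   cfg: NetworkConfig) -> tuple[Network, list[float]]:
    """Online backpropagation: per-sample updates in seeded-shuffle order each
    epoch; returns the trained network and the epoch-wise mean squared error.

    Raises :class:`DivergenceError` if the loss goes non-finite.
    """
    net = net.copy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(y))
        for i in order:
            _backprop_step(net, X[i], y[i], cfg.alpha)
        preds = forward_batch(net, X)
        mse = float(np.mean((preds - y) ** 2))
        if not np.isfinite(mse):
            raise DivergenceError(f"training diverged at epoch {epoch}")
        history.append(mse)
    return net, history


def predict(net: Network, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff the linear output is >= threshold."""
    scores = forward_batch(net, np.atleast_2d(np.asarray(X, dtype=float)))
    return (scores >= threshold).astype(int)
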