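"""Feed-forward classifier network and its two trainers.

A small fully connected net (default 3-8-3: three principal-component scores
in, one logistic unit per class out) with hyperbolic-tangent ("tansig") hidden
layers and a logistic ("logsig") output layer. It can be trained two ways:

* ``train_gdm`` — classic back-propagation by batch gradient descent with a
  momentum term on the mean-squared error against one-hot targets;
* ``train_iaabc`` — derivative-free: the weight matrices and bias (threshold)
  vectors are flattened into a single parameter vector and handed to the bee
  colony of :mod:`uvbee.iaabc`, whose objective is the training-set MSE.

Class labels are integer codes ``1..k``; a prediction is the 1-based index of
the largest output unit (ties go to the lowest index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import iaabc

__all__ = [
    "NetworkArchitecture",
    "NetworkParams",
    "GdmConfig",
    "LabeledFeatures",
    "FeatureScaler",
    "forward",
    "flatten",
    "unflatten",
    "init_params",
    "mse",
    "train_gdm",
    "train_iaabc",
    "TrainResult",
    "predict_classes",
]

_TRANSFERS = ("tansig", "logsig", "purelin")


def _apply_transfer(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tansig":
        return np.tanh(z)
    if name == "logsig":
        with np.errstate(over="ignore"):  # saturates cleanly to 0
            return 1.0 / (1.0 + np.exp(-z))
    if name == "purelin":
        return z
    raise ValueError(f"unknown transfer function {name!r}")


def _transfer_deriv(name: str, a: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value
    if name == "tansig":
        return 1.0 - a * a
    if name == "logsig":
        return a * (1.0 - a)
    if name == "purelin":
        return np.ones_like(a)
    raise ValueError(f"unknown transfer function {name!r}")


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer sizes and transfer functions of the feed-forward net."""

    layer_sizes: tuple[int, ...] = (3, 8, 3)
    hidden_transfer: str = "tansig"
    output_transfer: str = "logsig"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("need at least an input and an output layer")
        if any(s < 1 for s in sizes):
            raise ValueError("all layer sizes must be >= 1")
        for t in (self.hidden_transfer, self.output_transfer):
            if t not in _TRANSFERS:
                raise ValueError(f"unknown transfer function {t!r}")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    @property
    def param_count(self) -> int:
        """Total number of weights plus thresholds."""
        return sum(
            n_out * n_in + n_out
            for n_in, n_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:])
        )

    def transfer_of_layer(self, layer: int) -> str:
        n_layers = len(self.layer_sizes) - 1
        return self.output_transfer if layer == n_layers - 1 else self.hidden_transfer


@dataclass
class NetworkParams:
    """Per-layer weight matrices (n_out x n_in) and threshold vectors (n_out,)."""

    weights: list[np.ndarray]
    thresholds: list[np.ndarray]

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights],
                             [b.copy() for b in self.thresholds])


def init_params(arch: NetworkArchitecture, rng: np.random.Generator,
                scale: float = 0.5) -> NetworkParams:
    """Uniform initialization in [-scale, scale] for every weight and threshold."""
    weights, thresholds = [], []
    for n_in, n_out in zip(arch.layer_sizes[:-1], arch.layer_sizes[1:]):
        weights.append(rng.uniform(-scale, scale, size=(n_out, n_in)))
        thresholds.append(rng.uniform(-scale, scale, size=n_out))
    return NetworkParams(weights, thresholds)


def flatten(params: NetworkParams) -> np.ndarray:
    """Concatenate all layers as [W1.ravel(), b1, W2.ravel(), b2, ...]."""
    parts = []
    for w, b in zip(params.weights, params.thresholds):
        parts.append(w.ravel())
        parts.append(b)
    return np.concatenate(parts)


def unflatten(vector: np.ndarray, arch: NetworkArchitecture) -> NetworkParams:
    """Inverse of :func:`flatten`; exact round-trip."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (arch.param_count,):
        raise ValueError(
            f"expected vector of length {arch.param_count}, got {vector.shape}")
    weights, thresholds, pos = [], [], 0
    for n_in, n_out in zip(arch.layer_sizes[:-1], arch.layer_sizes[1:]):
        w = vector[pos:pos + n_out * n_in].reshape(n_out, n_in)
        pos += n_out * n_in
        b = vector[pos:pos + n_out]
        pos += n_out
        weights.append(w.copy())
        thresholds.append(b.copy())
    return NetworkParams(weights, thresholds)


def _forward_all(params: NetworkParams, features: np.ndarray,
                 arch: NetworkArchitecture) -> list[np.ndarray]:
    """Activations of every layer, input included."""
    a = np.asarray(features, dtype=float)
    if a.ndim != 2 or a.shape[1] != params.weights[0].shape[1]:
        raise ValueError(
            f"feature width {a.shape} does not match input layer size "
            f"{params.weights[0].shape[1]}")
    acts = [a]
    for layer, (w, b) in enumerate(zip(params.weights, params.thresholds)):
        z = acts[-1] @ w.T + b
        acts.append(_apply_transfer(arch.transfer_of_layer(layer), z))
    return acts


def forward(params: NetworkParams, features: np.ndarray,
            arch: NetworkArchitecture | None = None) -> np.ndarray:
    """Network outputs (n_samples x n_outputs), each in (0, 1) for logsig output."""
    if arch is None:
        sizes = [params.weights[0].shape[1]] + [w.shape[0] for w in params.weights]
        arch = NetworkArchitecture(tuple(sizes))
    return _forward_all(params, features, arch)[-1]


@dataclass
class LabeledFeatures:
    """Score-vector features with 1-based integer class labels and one-hot targets."""

    features: np.ndarray
    labels: np.ndarray
    targets: np.ndarray

    @classmethod
    def from_labels(cls, features: np.ndarray, labels: np.ndarray,
                    n_classes: int) -> "LabeledFeatures":
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if features.shape[0] != labels.shape[0]:
            raise ValueError("features and labels disagree in length")
        if labels.size == 0:
            raise ValueError("empty dataset")
        if labels.min() < 1 or labels.max() > n_classes:
            raise ValueError(f"labels must lie in 1..{n_classes}")
        targets = np.zeros((labels.size, n_classes))
        targets[np.arange(labels.size), labels - 1] = 1.0
        return cls(features, labels, targets)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


@dataclass
class FeatureScaler:
    """Per-dimension standardization fit on the training split only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, features: np.ndarray) -> "FeatureScaler":
        x = np.asarray(features, dtype=float)
        std = x.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)  # constant dimensions pass through
        return cls(x.mean(axis=0), std)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mean) / self.std


def mse(params: NetworkParams, data: LabeledFeatures,
        arch: NetworkArchitecture) -> float:
    out = forward(params, data.features, arch)
    with np.errstate(over="ignore"):  # divergence is reported by the caller
        return float(np.mean((out - data.targets) ** 2))


@dataclass
class GdmConfig:
    """Gradient-descent-with-momentum hyperparameters."""

    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 2000
    goal: float = 1e-6

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class TrainResult:
    """Trained parameters plus the per-epoch (or per-cycle) loss trace."""

    params: NetworkParams
    mse_trace: np.ndarray
    epochs_run: int
    opt_result: iaabc.OptResult | None = None

    @property
    def final_mse(self) -> float:
        return float(self.mse_trace[-1]) if self.mse_trace.size else math.nan


def _gradients(params: NetworkParams, data: LabeledFeatures,
               arch: NetworkArchitecture) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    acts = _forward_all(params, data.features, arch)
    out = acts[-1]
    err = out - data.targets
    with np.errstate(over="ignore", invalid="ignore"):
        loss = float(np.mean(err ** 2))
    n_layers = len(params.weights)
    scale = 2.0 / err.size
    delta = scale * err * _transfer_deriv(arch.transfer_of_layer(n_layers - 1), out)
    grads_w: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
    for layer in range(n_layers - 1, -1, -1):
        grads_w[layer] = delta.T @ acts[layer]
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ params.weights[layer]) * _transfer_deriv(
                arch.transfer_of_layer(layer - 1), acts[layer])
    return grads_w, grads_b, loss


def train_gdm(arch: NetworkArchitecture, data: LabeledFeatures,
              config: GdmConfig | None = None,
              rng: np.random.Generator | None = None,
              params: NetworkParams | None = None) -> TrainResult:
    """Batch back-propagation with momentum until ``goal`` or ``max_epochs``.

    Raises ``FloatingPointError`` if the loss turns non-finite (divergence):
    lower the learning rate.
    """
    if data.n_samples == 0:
        raise ValueError("empty dataset")
    config = config or GdmConfig()
    if params is None:
        rng = rng if rng is not None else np.random.default_rng()
        params = init_params(arch, rng)
    else:
        params = params.copy()

    trace = [mse(params, data, arch)]
    if trace[0] <= config.goal:
        return TrainResult(params, np.asarray(trace), 0)

    vel_w = [np.zeros_like(w) for w in params.weights]
    vel_b = [np.zeros_like(b) for b in params.thresholds]
    epochs = 0
    for epoch in range(config.max_epochs):
        grads_w, grads_b, loss = _gradients(params, data, arch)
        if not math.isfinite(loss):
            raise FloatingPointError(
                "training diverged (non-finite MSE); try a smaller learning_rate")
        for l in range(len(params.weights)):
            vel_w[l] = config.momentum * vel_w[l] - config.learning_rate * grads_w[l]
            vel_b[l] = config.momentum * vel_b[l] - config.learning_rate * grads_b[l]
            params.weights[l] += vel_w[l]
            params.thresholds[l] += vel_b[l]
        epochs = epoch + 1
        trace.append(mse(params, data, arch))
        if trace[-1] <= config.goal:
            break
    if not math.isfinite(trace[-1]):
        raise FloatingPointError(
            "training diverged (non-finite MSE); try a smaller learning_rate")
    return TrainResult(params, np.asarray(trace), epochs)


def train_iaabc(arch: NetworkArchitecture, data: LabeledFeatures,
                colony_config: iaabc.ColonyConfig | None = None,
                variant: str = "iaabc",
                weight_bound: float = 5.0) -> TrainResult:
    """Optimize the flattened parameter vector by the bee colony.

    The search space is the box ``[-weight_bound, weight_bound]`` per
    parameter; the objective is the training-set MSE.
    """
    if data.n_samples == 0:
        raise ValueError("empty dataset")
    colony_config = colony_config or iaabc.ColonyConfig()

    def objective(theta: np.ndarray) -> float:
        return mse(unflatten(theta, arch), data, arch)

    space = iaabc.SearchSpace.cube(arch.param_count, -weight_bound, weight_bound)
    result = iaabc.optimize(objective, space, colony_config, variant=variant)
    params = unflatten(result.best_position, arch)
    return TrainResult(params, result.trace, result.cycles_run, opt_result=result)


def predict_classes(outputs: np.ndarray) -> np.ndarray:
    """1-based class codes from network outputs; ties take the lowest index."""
    out = np.asarray(outputs, dtype=float)
    if out.size == 0 or out.ndim != 2:
        raise ValueError("outputs must be a non-empty n x k matrix")
    return np.argmax(out, axis=1) + 1
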