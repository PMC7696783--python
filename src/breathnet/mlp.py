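"""Single-hidden-layer tanh perceptron trained by error backpropagation.

The network is deliberately written from first principles in NumPy: a
fully connected 238-476-1 architecture (hidden layer twice the input width)
with hyperbolic-tangent activation on every layer, full-batch gradient
descent on the mean squared error against +/-1 class targets, and
patience-based early stopping on a validation set to prevent overfitting.
The best-validation weight snapshot is returned, never the final epoch's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .exceptions import ParameterError, ShapeError, TrainingDivergenceError

STOP_EARLY = "early-stop"
STOP_MAX_EPOCHS = "max-epochs"


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``hidden_dim`` defaults to twice the input width; targets are coded
    +1 for the pathological class and -1 for healthy, matching the tanh
    output range.
    """

    input_dim: int = 238
    hidden_dim: Optional[int] = None
    output_dim: int = 1
    activation: str = "tanh"
    learning_rate: float = 0.01
    max_epochs: int = 1_000_000
    patience: int = 20
    validation_check_interval: int = 100
    init_scale: float = 0.1
    seed: int = 0
    label_positive: float = 1.0
    label_negative: float = -1.0

    def __post_init__(self) -> None:
        if self.hidden_dim is None:
            self.hidden_dim = 2 * self.input_dim

    def validate(self) -> None:
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ParameterError("input_dim and hidden_dim must be >= 1")
        if self.output_dim != 1:
            raise ParameterError("output_dim is fixed at 1")
        if self.activation != "tanh":
            raise ParameterError("only tanh activation is supported")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if self.validation_check_interval < 1:
            raise ParameterError("validation_check_interval must be >= 1")
        if self.init_scale < 0:
            raise ParameterError("init_scale must be >= 0")


@dataclass
class Perceptron:
    """Weights of the one-hidden-layer network."""

    W1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float

    def copy(self) -> "Perceptron":
        return Perceptron(self.W1.copy(), self.b1.copy(),
                          self.W2.copy(), float(self.b2))


@dataclass
class TrainingHistory:
    epochs_run: int = 0
    train_error: list = field(default_factory=list)  # MSE per check
    val_error: list = field(default_factory=list)
    stop_reason: str = ""


def init_network(config: NetworkConfig) -> Perceptron:
    """Uniform [-init_scale, +init_scale] initialization, seeded."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return Perceptron(
        W1=rng.uniform(-s, s, size=(config.hidden_dim, config.input_dim)),
        b1=rng.uniform(-s, s, size=config.hidden_dim),
        W2=rng.uniform(-s, s, size=config.hidden_dim),
        b2=float(rng.uniform(-s, s)),
    )


def forward(net: Perceptron, x: np.ndarray) -> np.ndarray | float:
    """Score(s) in (-1, 1): tanh(W2 . tanh(W1 x + b1) + b2)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.ndim != 2 or X.shape[1] != net.W1.shape[1]:
        raise ShapeError(
            f"input has shape {x.shape}, network expects "
            f"(*, {net.W1.shape[1]})")
    h = np.tanh(X @ net.W1.T + net.b1)
    y = np.tanh(h @ net.W2 + net.b2)
    return float(y[0]) if single else y


def predict_scores(net: Perceptron, features: Sequence[np.ndarray]) -> np.ndarray:
    """Vectorized forward pass, order preserved."""
    X = np.stack([np.asarray(f, dtype=float) for f in features])
    return np.asarray(forward(net, X))


def gradients(net: Perceptron, X: np.ndarray, targets: np.ndarray):
    """Analytic gradients of batch MSE w.r.t. all weights, plus the MSE.

    Loss = mean over the batch of (tanh(W2 . tanh(W1 x + b1) + b2) - t)^2.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.W1.shape[1]:
        raise ShapeError(
            f"batch has shape {X.shape}, network expects "
            f"(*, {net.W1.shape[1]})")
    n = X.shape[0]
    z1 = X @ net.W1.T + net.b1
    h = np.tanh(z1)
    y = np.tanh(h @ net.W2 + net.b2)
    err = y - t
    mse = float(np.mean(err ** 2))
    dz2 = (2.0 / n) * err * (1.0 - y ** 2)          # (n,)
    gW2 = h.T @ dz2                                  # (hidden,)
    gb2 = float(dz2.sum())
    dz1 = np.outer(dz2, net.W2) * (1.0 - h ** 2)     # (n, hidden)
    gW1 = dz1.T @ X                                  # (hidden, input)
    gb1 = dz1.sum(axis=0)
    return (gW1, gb1, gW2, gb2), mse


def batch_mse(net: Perceptron, X: np.ndarray, targets: np.ndarray) -> float:
    y = np.asarray(forward(net, np.asarray(X, dtype=float)))
    return float(np.mean((y - np.asarray(targets, dtype=float)) ** 2))


def backprop_step(net: Perceptron, X: np.ndarray, targets: np.ndarray,
                  learning_rate: float) -> float:
    """One full-batch gradient-descent update in place; returns pre-update MSE."""
    t = np.asarray(targets, dtype=float)
    if not np.all(np.isin(t, (-1.0, 1.0))):
        raise ParameterError("targets must be coded -1/+1")
    (gW1, gb1, gW2, gb2), mse = gradients(net, X, t)
    if not (np.isfinite(mse) and np.all(np.isfinite(gW1))
            and np.all(np.isfinite(gW2))):
        raise TrainingDivergenceError("non-finite gradient encountered")
    net.W1 -= learning_rate * gW1
    net.b1 -= learning_rate * gb1
    net.W2 -= learning_rate * gW2
    net.b2 -= learning_rate * gb2
    return mse


def train(net: Perceptron, train_set: tuple, val_set: tuple,
          config: NetworkConfig) -> tuple[Perceptron, TrainingHistory]:
    """Backpropagation with patience-based early stopping.

    ``train_set`` and ``val_set`` are (X, targets) pairs with disjoint
    subjects.  Every ``validation_check_interval`` epochs both errors are
    recorded; training stops once validation MSE has failed to improve for
    ``patience`` consecutive checks, or at ``max_epochs``.  The returned
    network is the snapshot with the minimum recorded validation MSE.
    """
    config.validate()
    X_tr, t_tr = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    X_va, t_va = np.asarray(val_set[0], float), np.asarray(val_set[1], float)
    if X_tr.shape[0] == 0 or X_va.shape[0] == 0:
        raise ParameterError("train and validation sets must be non-empty")

    history = TrainingHistory()
    best = net.copy()
    best_val = np.inf
    bad_checks = 0
    epoch = 0
    try:
        for epoch in range(1, config.max_epochs + 1):
            backprop_step(net, X_tr, t_tr, config.learning_rate)
            if epoch % config.validation_check_interval == 0:
                tr_mse = batch_mse(net, X_tr, t_tr)
                va_mse = batch_mse(net, X_va, t_va)
                history.train_error.append(tr_mse)
                history.val_error.append(va_mse)
                if va_mse < best_val:
                    best_val = va_mse
                    best = net.copy()
                    bad_checks = 0
                else:
                    bad_checks += 1
                    if bad_checks >= config.patience:
                        history.stop_reason = STOP_EARLY
                        break
        else:
            history.stop_reason = STOP_MAX_EPOCHS
        if not history.stop_reason:
            history.stop_reason = STOP_MAX_EPOCHS
    except TrainingDivergenceError as exc:
        raise TrainingDivergenceError(f"{exc} at epoch {epoch}") from None
    history.epochs_run = epoch
    # If no check ever ran (max_epochs < interval) keep the trained weights.
    if np.isinf(best_val):
        best = net.copy()
    return best, history


class TanhMLPClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn-style front end for the tanh perceptron.

    ``fit`` splits off an internal stratified validation subset (default
    20%) to drive early stopping, so cross-validation folds never leak
    held-out subjects into the stopping rule.  ``decision_function`` returns
    the raw tanh score in (-1, 1); ``predict`` thresholds it at 0.

    Parameters mirror :class:`NetworkConfig`; the positive class is
    ``classes_[1]`` (NumPy sort order of the supplied labels).
    """

    def __init__(self, hidden_dim: Optional[int] = None,
                 learning_rate: float = 0.01, max_epochs: int = 1_000_000,
                 patience: int = 20, validation_check_interval: int = 100,
                 init_scale: float = 0.1, validation_fraction: float = 0.2,
                 seed: int = 0):
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_check_interval = validation_check_interval
        self.init_scale = init_scale
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _network_config(self, input_dim: int) -> NetworkConfig:
        return NetworkConfig(
            input_dim=input_dim, hidden_dim=self.hidden_dim,
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            patience=self.patience,
            validation_check_interval=self.validation_check_interval,
            init_scale=self.init_scale, seed=self.seed)

    def fit(self, X, y) -> "TanhMLPClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ShapeError("X must be 2-D")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ParameterError(
                f"exactly two classes required, got {self.classes_.size}")
        t = np.where(y == self.classes_[1], 1.0, -1.0)
        self.n_features_in_ = X.shape[1]
        config = self._network_config(X.shape[1])
        config.validate()

        # Internal validation split for the early-stopping monitor; tiny
        # datasets fall back to monitoring the training error itself.
        min_class = int(np.bincount((t > 0).astype(int)).min())
        n_val = int(round(self.validation_fraction * X.shape[0]))
        if 0 < self.validation_fraction < 1 and n_val >= 2 and min_class >= 2:
            X_tr, X_va, t_tr, t_va = train_test_split(
                X, t, test_size=self.validation_fraction, stratify=t,
                random_state=self.seed % (2 ** 32))
        else:
            X_tr, t_tr = X, t
            X_va, t_va = X, t
        net = init_network(config)
        self.network_, self.history_ = train(
            net, (X_tr, t_tr), (X_va, t_va), config)
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(forward(self.network_, np.asarray(X, dtype=float)))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[(scores > 0).astype(int)]
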