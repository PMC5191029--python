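"""Three-layer back-propagation network (logsig hidden, purelin output).

The classifier is a single-hidden-layer feed-forward network trained on
one-hot activity targets by minimizing the summed squared error
E = 1/2 sum_k (d_k - y_k)^2, averaged over the batch.  Hidden units use
the logistic sigmoid, output units are linear, and predictions are the
argmax over output units (ties toward the lower class index).

The hidden-layer width follows the empirical sizing rule
m = floor(sqrt(x * y)) for x inputs and y outputs.  Two training modes are
provided: ``gd`` — full-batch steepest descent on the printed update
equations (the default, and the mode the tests rely on) — and ``lm`` —
Levenberg-Marquardt on the same residuals via an analytic Jacobian, the
faster quasi-Newton variant commonly used for small networks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkShape",
    "Weights",
    "TrainConfig",
    "TrainedModel",
    "hidden_size",
    "init_weights",
    "logsig",
    "forward",
    "train",
    "predict",
    "fit_classifier",
    "predict_labels",
]


def hidden_size(x: int, y: int) -> int:
    """Empirical hidden-layer width: floor(sqrt(x * y))."""
    if x < 1 or y < 1:
        raise ValueError("layer sizes must be positive")
    return int(math.floor(math.sqrt(x * y)))


@dataclass
class NetworkShape:
    x: int  # inputs
    m: int  # hidden units
    y: int  # outputs (= number of classes)

    @classmethod
    def sized(cls, x: int, y: int) -> "NetworkShape":
        return cls(x=x, m=hidden_size(x, y), y=y)


@dataclass
class Weights:
    """Input->hidden weights/thresholds and hidden->output weights/thresholds.

    Unit inputs follow the thresholded convention sum(w * o) - theta.
    """

    w1: np.ndarray  # (m, x)
    t1: np.ndarray  # (m,)
    w2: np.ndarray  # (y, m)
    t2: np.ndarray  # (y,)

    def copy(self) -> "Weights":
        return Weights(self.w1.copy(), self.t1.copy(), self.w2.copy(), self.t2.copy())


@dataclass
class TrainConfig:
    eta: float = 0.1  # learning rate (gd mode)
    # cap sized so the MSE goal, not the cap, normally ends gd training
    max_epochs: int = 20000
    mse_goal: float = 1e-3
    seed: int = 0
    mode: str = "gd"  # or "lm"

    def validate(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"learning rate must be > 0, got {self.eta}")
        if self.mode not in ("gd", "lm"):
            raise ValueError(f"mode must be 'gd' or 'lm', got {self.mode!r}")


@dataclass
class TrainedModel:
    shape: NetworkShape
    weights: Weights
    mse_trace: list[float] = field(default_factory=list)
    classes: list[int] | None = None  # class-index mapping for predict_labels
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None

    def save(self, path) -> None:
        """Serialize to a self-describing JSON file."""
        doc = {
            "shape": {"x": self.shape.x, "m": self.shape.m, "y": self.shape.y},
            "w1": self.weights.w1.tolist(),
            "t1": self.weights.t1.tolist(),
            "w2": self.weights.w2.tolist(),
            "t2": self.weights.t2.tolist(),
            "classes": self.classes,
            "norm_mean": None if self.norm_mean is None else list(self.norm_mean),
            "norm_sd": None if self.norm_sd is None else list(self.norm_sd),
            "final_mse": self.mse_trace[-1] if self.mse_trace else None,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        shape = NetworkShape(**doc["shape"])
        weights = Weights(
            w1=np.array(doc["w1"]),
            t1=np.array(doc["t1"]),
            w2=np.array(doc["w2"]),
            t2=np.array(doc["t2"]),
        )
        model = cls(shape=shape, weights=weights, classes=doc.get("classes"))
        if doc.get("norm_mean") is not None:
            model.norm_mean = np.array(doc["norm_mean"])
            model.norm_sd = np.array(doc["norm_sd"])
        if doc.get("final_mse") is not None:
            model.mse_trace = [doc["final_mse"]]
        return model


def init_weights(shape: NetworkShape, seed: int) -> Weights:
    """Small random initial weights: uniform in [-0.5, 0.5] / sqrt(x)."""
    rng = np.random.default_rng(seed)
    scale = 1.0 / math.sqrt(shape.x)

    def u(*size):
        return rng.uniform(-0.5, 0.5, size=size) * scale

    return Weights(w1=u(shape.m, shape.x), t1=u(shape.m), w2=u(shape.y, shape.m), t2=u(shape.y))


def logsig(x: np.ndarray) -> np.ndarray:
    # split form avoids overflow for large |x|
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward(
    weights: Weights, inputs: np.ndarray, return_hidden: bool = False
):
    """Network output for a single vector or a batch (rows = samples)."""
    x = np.asarray(inputs, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != weights.w1.shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} != network input size {weights.w1.shape[1]}"
        )
    hidden = logsig(X @ weights.w1.T - weights.t1)
    out = hidden @ weights.w2.T - weights.t2
    if single:
        out, hidden = out[0], hidden[0]
    return (out, hidden) if return_hidden else out


def _mse(weights: Weights, X: np.ndarray, D: np.ndarray) -> float:
    Y = forward(weights, X)
    with np.errstate(over="ignore"):  # divergence surfaces as inf, caught by train()
        return float(np.mean(np.sum((D - Y) ** 2, axis=1) / 2.0))


def gradients(
    weights: Weights, X: np.ndarray, D: np.ndarray
) -> tuple[Weights, float]:
    """Batch-mean gradient of the half-squared error, by back-propagation."""
    n = X.shape[0]
    Y, O = forward(weights, X, return_hidden=True)
    # a diverging run overflows to inf/nan here; train() catches it via the loss
    with np.errstate(over="ignore", invalid="ignore"):
        err = Y - D  # (n, y)
        g_w2 = err.T @ O / n
        g_t2 = -err.mean(axis=0)
        delta_h = (err @ weights.w2) * O * (1.0 - O)  # (n, m)
        g_w1 = delta_h.T @ X / n
        g_t1 = -delta_h.mean(axis=0)
        mse = float(np.mean(np.sum(err**2, axis=1) / 2.0))
    return Weights(w1=g_w1, t1=g_t1, w2=g_w2, t2=g_t2), mse


def _pack(w: Weights) -> np.ndarray:
    return np.concatenate([w.w1.ravel(), w.t1, w.w2.ravel(), w.t2])


def _unpack(theta: np.ndarray, shape: NetworkShape) -> Weights:
    m, x, y = shape.m, shape.x, shape.y
    i = 0
    w1 = theta[i : i + m * x].reshape(m, x); i += m * x
    t1 = theta[i : i + m]; i += m
    w2 = theta[i : i + y * m].reshape(y, m); i += y * m
    t2 = theta[i : i + y]
    return Weights(w1=w1, t1=t1, w2=w2, t2=t2)


def _lm_jacobian(weights: Weights, X: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the flattened residuals (y - d) w.r.t. params."""
    n, x_dim = X.shape
    m, y_dim = weights.w1.shape[0], weights.w2.shape[0]
    _, O = forward(weights, X, return_hidden=True)
    dO = O * (1.0 - O)  # (n, m)
    p = m * x_dim + m + y_dim * m + y_dim
    J = np.zeros((n * y_dim, p))
    rows = np.arange(n * y_dim).reshape(n, y_dim)
    # d y_k / d w1[j, i] = w2[k, j] * dO[n, j] * X[n, i]
    blk = (dO[:, :, None] * X[:, None, :]).reshape(n, m * x_dim)  # (n, m*x)
    for k in range(y_dim):
        J[rows[:, k], : m * x_dim] = blk * np.repeat(weights.w2[k], x_dim)
        J[rows[:, k], m * x_dim : m * x_dim + m] = -dO * weights.w2[k]
        J[rows[:, k], m * x_dim + m + k * m : m * x_dim + m + (k + 1) * m] = O
        J[rows[:, k], m * x_dim + m + y_dim * m + k] = -1.0
    return J


def train(
    features: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    shape: NetworkShape | None = None,
) -> TrainedModel:
    """Fit the network to one-hot targets.

    gd mode runs full-batch steepest descent with learning rate ``eta``
    until the MSE goal or ``max_epochs``; lm mode runs Levenberg-Marquardt
    on the residual vector with the analytic Jacobian.  Deterministic for
    a fixed seed and config.
    """
    config.validate()
    X = np.asarray(features, dtype=float)
    D = np.asarray(targets, dtype=float)
    if X.ndim != 2 or D.ndim != 2 or X.shape[0] != D.shape[0]:
        raise ValueError("features and targets must be 2-D with matching rows")
    if shape is None:
        shape = NetworkShape.sized(X.shape[1], D.shape[1])
    weights = init_weights(shape, config.seed)
    trace: list[float] = []
    if config.mode == "gd":
        for epoch in range(config.max_epochs):
            grad, mse = gradients(weights, X, D)
            if not np.isfinite(mse):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            trace.append(mse)
            if mse < config.mse_goal:
                break
            weights.w1 -= config.eta * grad.w1
            weights.t1 -= config.eta * grad.t1
            weights.w2 -= config.eta * grad.w2
            weights.t2 -= config.eta * grad.t2
        trace.append(_mse(weights, X, D))
    else:  # lm
        from scipy.optimize import least_squares

        def residuals(theta):
            w = _unpack(theta, shape)
            return (forward(w, X) - D).ravel()

        def jac(theta):
            return _lm_jacobian(_unpack(theta, shape), X)

        trace.append(_mse(weights, X, D))
        sol = least_squares(
            residuals,
            _pack(weights),
            jac=jac,
            method="lm",
            max_nfev=config.max_epochs,
        )
        weights = _unpack(sol.x, shape)
        trace.append(_mse(weights, X, D))
    return TrainedModel(shape=shape, weights=weights, mse_trace=trace)


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Class indices (0-based argmax; ties toward the lower index)."""
    out = np.atleast_2d(forward(model.weights, features))
    return np.argmax(out, axis=1)


def one_hot(labels: np.ndarray, classes: list[int]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    D = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        D[r, index[int(lab)]] = 1.0
    return D


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    classes: list[int] | None = None,
    hidden: int | None = None,
) -> TrainedModel:
    """Train on integer class labels; records the class-index mapping."""
    if classes is None:
        classes = sorted(int(c) for c in np.unique(labels))
    D = one_hot(np.asarray(labels), classes)
    X = np.asarray(features, dtype=float)
    m = hidden if hidden is not None else hidden_size(X.shape[1], len(classes))
    shape = NetworkShape(x=X.shape[1], m=m, y=len(classes))
    model = train(X, D, config, shape=shape)
    model.classes = classes
    return model


def predict_labels(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Original class labels via the model's class-index mapping."""
    idx = predict(model, features)
    classes = model.classes or list(range(model.shape.y))
    return np.array([classes[i] for i in idx], dtype=int)
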