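"""Radial-basis-function network regression.

The predictor is a single hidden layer of ``k`` Gaussian units,

    f(x) = sum_j w_j * exp(-gamma * ||x - c_j||^2),

with no bias term. Centers ``c_j`` come from K-means on the training inputs
(see :mod:`thorbfnn.cluster_init`) and the shared width ``gamma`` is a
hyperparameter tuned externally (see :mod:`thorbfnn.hyper_opt`); only the
output weights ``w`` are trained, by full-batch gradient descent on the RMSE
loss with RMSprop-style squared-gradient scaling. With fixed centers the
model is linear in ``w``, so :func:`closed_form_weights` provides an exact
least-squares solution used as an optimality oracle in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "RBFModel",
    "TrainConfig",
    "TrainHistory",
    "interpolation_matrix",
    "forward",
    "rmse_loss",
    "train",
    "closed_form_weights",
    "save_model",
    "load_model",
]

_SCHEMA_TAG = "thorbfnn-rbf-model/1"


@dataclass
class RBFModel:
    """A trained (or trainable) RBF regressor.

    centers : (k, d) array of unit centers in predictor space.
    gamma   : positive shared kernel width.
    weights : (k,) output weights.
    feature_names : column names bound, in order, to the center dimensions.
    scale_tags : per-feature scale annotation carried through from
        preprocessing (``raw`` or ``log``), informational.
    encoding : optional serialized categorical encoding map, so a stored
        model can re-encode prediction-time inputs consistently.
    """

    centers: np.ndarray
    gamma: float
    weights: np.ndarray
    feature_names: list[str]
    scale_tags: dict = field(default_factory=dict)
    encoding: dict | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.centers.shape[0] != self.weights.size:
            raise ValueError(
                f"{self.centers.shape[0]} centers but {self.weights.size} weights"
            )

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def predict(self, X) -> np.ndarray:
        return forward(self, X)


@dataclass
class TrainConfig:
    """Settings for the full-batch RMSprop weight optimizer.

    Defaults favour tight convergence to the least-squares optimum of the
    (linear-in-weights) RMSE objective: RMSprop with a fixed learning rate
    settles into an oscillation whose amplitude scales with the learning
    rate, so a small step with a generous epoch budget is what actually
    reaches the optimum. One full-batch epoch at the problem sizes this
    package targets (N ~ 10^3-10^4, k <= 25) costs a single N x k matrix
    product, so the large epoch count stays cheap.

    :meth:`for_search` returns a lighter preset for the inner loop of the
    feature-combination search, where hundreds of models are fitted and
    only their relative validation ranking matters.
    """

    learning_rate: float = 3e-4
    max_epochs: int = 12000
    optimizer_decay: float = 0.9
    epsilon: float = 1e-8
    seed: int = 0

    @classmethod
    def for_search(cls, seed: int = 0) -> "TrainConfig":
        """Throughput preset used per-candidate inside hyperparameter search."""
        return cls(learning_rate=5e-3, max_epochs=800, optimizer_decay=0.9, seed=seed)

    def __post_init__(self):
        if not (0.0 < self.optimizer_decay < 1.0):
            raise ValueError("optimizer_decay must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainHistory:
    """Per-epoch loss trace of one training run."""

    losses: list[float]
    initial_loss: float
    best_epoch: int

    @property
    def final_loss(self) -> float:
        return self.losses[-1] if self.losses else self.initial_loss


class DivergenceError(RuntimeError):
    pass


def interpolation_matrix(X, centers, gamma: float) -> np.ndarray:
    """Gaussian activation matrix G with G[i, j] = exp(-gamma ||x_i - c_j||^2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has d={X.shape[1]}, centers d={centers.shape[1]}"
        )
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    sq = cdist(X, centers, metric="sqeuclidean")
    return np.exp(-gamma * sq)


def forward(model: RBFModel, X) -> np.ndarray:
    """Predictions G @ w for inputs ``X`` (columns in model.feature_names order)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(
            f"feature mismatch: model expects d={model.d} "
            f"({model.feature_names}), got {X.shape[1]} columns"
        )
    G = interpolation_matrix(X, model.centers, model.gamma)
    return G @ model.weights


def rmse_loss(y, yhat) -> float:
    """Root-mean-squared error, the training objective."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size == 0:
        raise ValueError("empty target vector")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def closed_form_weights(G, y) -> np.ndarray:
    """Minimum-norm least-squares weights for G @ w ~ y (testing oracle).

    With fixed centers the network output is linear in the weights, so the
    RMSE-optimal weights solve an ordinary least-squares problem exactly.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    w, *_ = np.linalg.lstsq(G, y, rcond=None)
    return w


def train(model: RBFModel, X, y, config: TrainConfig) -> tuple[RBFModel, TrainHistory]:
    """Fit output weights by full-batch RMSprop on the RMSE loss.

    Centers and gamma are frozen; weights start from seeded N(0, 0.1^2)
    draws. The returned model carries the weights of the best epoch seen
    (lowest training loss), not necessarily the last one — with a fixed
    learning rate the iterates hover around the optimum, and the best-seen
    state is strictly closer to it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"{X.shape[0]} rows but {y.size} targets")

    rng = np.random.default_rng(config.seed)
    w = rng.normal(0.0, 0.1, size=model.k)

    G = interpolation_matrix(X, model.centers, model.gamma)
    n = y.size

    def loss_of(wv):
        return float(np.sqrt(np.mean((G @ wv - y) ** 2)))

    initial_loss = loss_of(w)
    best_loss = initial_loss
    best_w = w.copy()
    best_epoch = -1

    losses: list[float] = []
    s = np.zeros_like(w)  # running average of squared gradients
    rho, eps, lr = config.optimizer_decay, config.epsilon, config.learning_rate

    for epoch in range(config.max_epochs):
        resid = G @ w - y
        rmse = np.sqrt(np.mean(resid**2))
        if not np.isfinite(rmse):
            raise DivergenceError(
                f"non-finite loss at epoch {epoch} (learning_rate={lr})"
            )
        # d RMSE / d w = G^T resid / (n * rmse); at an exact fit the loss is
        # already minimal, so a zero gradient is substituted.
        if rmse > 0:
            grad = G.T @ resid / (n * rmse)
        else:
            grad = np.zeros_like(w)
        s = rho * s + (1.0 - rho) * grad**2
        w = w - lr * grad / (np.sqrt(s) + eps)

        cur = loss_of(w)
        losses.append(cur)
        if cur < best_loss:
            best_loss = cur
            best_w = w.copy()
            best_epoch = epoch

    fitted = RBFModel(
        centers=model.centers.copy(),
        gamma=model.gamma,
        weights=best_w,
        feature_names=list(model.feature_names),
        scale_tags=dict(model.scale_tags),
        encoding=model.encoding,
    )
    history = TrainHistory(losses=losses, initial_loss=initial_loss, best_epoch=best_epoch)
    return fitted, history


def save_model(model: RBFModel, path) -> None:
    """Serialize a model to a flat JSON file with a schema tag."""
    payload = {
        "schema": _SCHEMA_TAG,
        "feature_names": list(model.feature_names),
        "centers": model.centers.tolist(),
        "gamma": float(model.gamma),
        "weights": model.weights.tolist(),
        "scale_tags": dict(model.scale_tags),
        "encoding": model.encoding,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> RBFModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != _SCHEMA_TAG:
        raise ValueError(f"unrecognized model schema: {payload.get('schema')!r}")
    return RBFModel(
        centers=np.asarray(payload["centers"], dtype=float),
        gamma=payload["gamma"],
        weights=np.asarray(payload["weights"], dtype=float),
        feature_names=payload["feature_names"],
        scale_tags=payload.get("scale_tags", {}),
        encoding=payload.get("encoding"),
    )
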