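"""Shallow neural classifiers: a linear perceptron and 1/2-hidden-layer MLPs.

The linear predictor is trained with the LMS rule ``W <- W + mu * e * x``
(no hard threshold; identity activation).  The MLPs use sigmoid units on
every hidden and output layer, exactly two output units (one per class),
hidden widths from the halving rule (first hidden = input/2, second =
input/4), and are trained either by scaled conjugate gradients (default)
or by plain per-sample backpropagation.  Early stopping monitors an
internal validation split and halts after a fixed number of consecutive
epochs without improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# single-layer perceptron (linear predictor)

@dataclass
class SLPModel:
    """Linear predictor; one weight column (plus bias) per output class."""

    weights: np.ndarray  # (n_features + 1, n_outputs)
    learning_rate: float = 0.1


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def slp_fit(X: np.ndarray, D: np.ndarray, learning_rate: float = 0.1,
            epochs: int = 20, seed: int = 0) -> SLPModel:
    """Train the linear predictor by per-sample LMS updates.

    ``D`` holds 0/1 targets, one column per class.  Samples are visited in
    a freshly shuffled (seeded) order each epoch; the update is
    ``W <- W + mu * x * e^T`` with ``e = d - W^T x`` (linear output, no
    squashing).  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=np.float64)
    D = np.atleast_2d(np.asarray(D, dtype=np.float64))
    if D.shape[0] == 1 and X.shape[0] != 1:
        D = D.T
    if not (np.isfinite(X).all() and np.isfinite(D).all()):
        raise ValueError("non-finite values in training data")
    Xa = _augment(X)
    rng = np.random.default_rng(seed)
    W = np.zeros((Xa.shape[1], D.shape[1]))
    for _ in range(epochs):
        for n in rng.permutation(len(Xa)):
            x = Xa[n]
            e = D[n] - x @ W
            W += learning_rate * np.outer(x, e)
    return SLPModel(weights=W, learning_rate=learning_rate)


def slp_predict(model: SLPModel, X: np.ndarray) -> np.ndarray:
    """Linear scores, one column per class (not squashed to [0, 1])."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] + 1 != model.weights.shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match model width {model.weights.shape[0] - 1}"
        )
    return _augment(X) @ model.weights


# ---------------------------------------------------------------------------
# multilayer perceptron

def mlp_architecture(input_dim: int, n_hidden_layers: int,
                     allow_odd: bool = False) -> list[int]:
    """Layer sizes under the halving rule.

    One hidden layer: ``[input, input/2, 2]``; two: ``[input, input/2,
    input/4, 2]``.  Inputs whose halves are not integral (e.g. the
    10-feature baseline) are rejected unless ``allow_odd`` is set, in
    which case halves round up.
    """
    if n_hidden_layers not in (1, 2):
        raise ValueError(f"n_hidden_layers must be 1 or 2, got {n_hidden_layers}")
    if input_dim < 2:
        raise ValueError(f"input_dim must be >= 2, got {input_dim}")
    if not allow_odd and input_dim % 4 != 0:
        raise ValueError(
            f"input_dim {input_dim} does not halve cleanly; pass allow_odd=True to round up"
        )
    h1 = math.ceil(input_dim / 2)
    if n_hidden_layers == 1:
        return [input_dim, h1, 2]
    h2 = math.ceil(h1 / 2)
    return [input_dim, h1, h2, 2]


@dataclass
class TrainConfig:
    optimizer: str = "scg"          # {"scg", "backprop"}
    loss: str = "xent"              # {"xent", "mse"}
    learning_rate: float = 0.01     # backprop only
    max_epochs: int = 200
    max_validation_fails: int = 5
    validation_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.optimizer not in ("scg", "backprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("xent", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.max_validation_fails < 1:
            raise ValueError("max_validation_fails must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class MLPModel:
    layer_sizes: list[int]
    weights: list[np.ndarray]       # each (fan_in + 1, fan_out), bias folded in
    loss: str = "xent"
    trained_epochs: int = 0
    stop_reason: str = "untrained"
    train_curve: list[float] = field(default_factory=list)
    val_curve: list[float] = field(default_factory=list)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_weights(layer_sizes: list[int], seed: int) -> list[np.ndarray]:
    """Symmetric uniform initialisation scaled by fan-in, seeded."""
    rng = np.random.default_rng(seed)
    weights = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in + 1)
        weights.append(rng.uniform(-bound, bound, size=(fan_in + 1, fan_out)))
    return weights


def forward(weights: list[np.ndarray], X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer (input first, output last); sigmoid throughout."""
    acts = [np.asarray(X, dtype=np.float64)]
    for W in weights:
        acts.append(_sigmoid(_augment(acts[-1]) @ W))
    return acts


def loss_value(weights: list[np.ndarray], X: np.ndarray, T: np.ndarray,
               loss: str = "xent") -> float:
    Y = forward(weights, X)[-1]
    if loss == "mse":
        return float(0.5 * np.mean(np.sum((Y - T) ** 2, axis=1)))
    eps = 1e-12
    Yc = np.clip(Y, eps, 1 - eps)
    return float(-np.mean(np.sum(T * np.log(Yc) + (1 - T) * np.log(1 - Yc), axis=1)))


def loss_gradients(weights: list[np.ndarray], X: np.ndarray, T: np.ndarray,
                   loss: str = "xent") -> list[np.ndarray]:
    """Analytic gradient of the mean loss w.r.t. every weight matrix.

    Backpropagates the output delta through the sigmoid layers; the delta
    of a hidden unit is its derivative ``y (1 - y)`` times the weighted sum
    of the downstream deltas.
    """
    acts = forward(weights, X)
    Y = acts[-1]
    m = X.shape[0]
    if loss == "mse":
        delta = (Y - T) * Y * (1 - Y) / m
    else:
        delta = (Y - T) / m
    grads: list[np.ndarray] = [None] * len(weights)  # type: ignore[list-item]
    for l in range(len(weights) - 1, -1, -1):
        grads[l] = _augment(acts[l]).T @ delta
        if l > 0:
            a = acts[l]
            delta = (delta @ weights[l][:-1].T) * a * (1 - a)
    return grads


def _flatten(arrays: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _unflatten(vec: np.ndarray, template: list[np.ndarray]) -> list[np.ndarray]:
    out, pos = [], 0
    for a in template:
        out.append(vec[pos:pos + a.size].reshape(a.shape))
        pos += a.size
    return out


def _scg_minimize(w0: list[np.ndarray], fun, jac, max_epochs: int,
                  callback) -> tuple[list[np.ndarray], int, str]:
    """Scaled conjugate gradient descent (Moller 1993) with early stopping.

    ``callback(weights) -> bool`` is invoked once per iteration; returning
    True stops training (validation failure budget exhausted).
    """
    template = w0
    w = _flatten(w0)
    n = w.size
    sigma0, lam, lam_bar = 1e-5, 1e-6, 0.0
    r = -_flatten(jac(_unflatten(w, template)))
    p = r.copy()
    success = True
    delta = 1.0
    E = fun(_unflatten(w, template))
    for k in range(1, max_epochs + 1):
        p2 = float(p @ p)
        if p2 == 0.0 or not np.isfinite(p2):
            return _unflatten(w, template), k - 1, "converged"
        if success:
            sigma = sigma0 / math.sqrt(p2)
            g_shift = _flatten(jac(_unflatten(w + sigma * p, template)))
            s = (g_shift + r) / sigma  # r = -grad, so grad = -r
            delta = float(p @ s)
        delta += (lam - lam_bar) * p2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        E_new = fun(_unflatten(w + alpha * p, template))
        Delta = 2.0 * delta * (E - E_new) / (mu * mu) if mu != 0 else -1.0
        if Delta >= 0:  # successful step
            w = w + alpha * p
            r_new = -_flatten(jac(_unflatten(w, template)))
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            E = E_new
            if Delta >= 0.75:
                lam *= 0.25
            # validation check only after an accepted step (w changed)
            if callback(_unflatten(w, template)):
                return _unflatten(w, template), k, "validation_fails"
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam += delta * (1.0 - Delta) / p2
        lam = min(lam, 1e20)
    return _unflatten(w, template), max_epochs, "max_epochs"


def _backprop_epoch(weights: list[np.ndarray], X: np.ndarray, T: np.ndarray,
                    eta: float, loss: str, rng: np.random.Generator) -> None:
    """One pass of per-sample delta-rule updates, in shuffled order."""
    for idx in rng.permutation(len(X)):
        acts = forward(weights, X[idx:idx + 1])
        y = acts[-1]
        e = T[idx:idx + 1] - y
        delta = y * (1 - y) * e if loss == "mse" else e
        for l in range(len(weights) - 1, -1, -1):
            grad = _augment(acts[l]).T @ delta
            if l > 0:
                a = acts[l]
                delta = (delta @ weights[l][:-1].T) * a * (1 - a)
            weights[l] += eta * grad


def mlp_fit(X: np.ndarray, Y: np.ndarray, config: TrainConfig,
            layer_sizes: list[int] | None = None,
            n_hidden_layers: int = 1) -> MLPModel:
    """Train an MLP with early stopping on an internal validation split.

    ``Y`` holds two 0/1 target columns (one per class).  The validation
    split (``validation_fraction``, default the 80:20 split) is carved out
    of the supplied training data; training stops once validation loss has
    failed to improve for ``max_validation_fails`` consecutive epochs, and
    the best-validation weights are restored.
    """
    config.validate()
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("Y must have exactly two 0/1 target columns")
    if layer_sizes is None:
        layer_sizes = mlp_architecture(X.shape[1], n_hidden_layers, allow_odd=True)
    if layer_sizes[0] != X.shape[1]:
        raise ValueError(
            f"architecture input width {layer_sizes[0]} != data width {X.shape[1]}"
        )

    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.validation_fraction * len(X))))
    order = rng.permutation(len(X))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation split leaves no training samples")
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    weights = init_weights(layer_sizes, config.seed)
    model = MLPModel(layer_sizes=list(layer_sizes), weights=weights, loss=config.loss)
    if config.max_epochs == 0:
        model.stop_reason = "max_epochs"
        return model

    state = {"best": float("inf"), "best_w": [w.copy() for w in weights],
             "prev": float("inf"), "fails": 0, "epochs": 0}

    def check(w: list[np.ndarray]) -> bool:
        state["epochs"] += 1
        tr_loss = loss_value(w, Xtr, Ytr, config.loss)
        val_loss = loss_value(w, Xval, Yval, config.loss)
        if not np.isfinite(val_loss) or not np.isfinite(tr_loss):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {state['epochs']}"
            )
        model.train_curve.append(tr_loss)
        model.val_curve.append(val_loss)
        if val_loss < state["best"]:
            state["best"] = val_loss
            state["best_w"] = [wi.copy() for wi in w]
        # a validation failure = the validation error did not decrease this
        # epoch; the counter resets on any decrease (the best-so-far
        # weights are what the fit finally returns)
        if val_loss < state["prev"] - 1e-12:
            state["fails"] = 0
        else:
            state["fails"] += 1
        state["prev"] = val_loss
        return state["fails"] >= config.max_validation_fails

    if config.optimizer == "scg":
        weights, epochs, reason = _scg_minimize(
            weights,
            fun=lambda w: loss_value(w, Xtr, Ytr, config.loss),
            jac=lambda w: loss_gradients(w, Xtr, Ytr, config.loss),
            max_epochs=config.max_epochs,
            callback=check,
        )
    else:
        reason = "max_epochs"
        epochs = config.max_epochs
        for epoch in range(config.max_epochs):
            _backprop_epoch(weights, Xtr, Ytr, config.learning_rate, config.loss, rng)
            if check(weights):
                epochs, reason = epoch + 1, "validation_fails"
                break

    model.weights = state["best_w"] if state["best"] < float("inf") else weights
    model.trained_epochs = epochs
    model.stop_reason = reason
    return model


def predict(model: MLPModel | SLPModel, X: np.ndarray) -> np.ndarray:
    """Per-sample scores, one column per class.

    MLP scores are sigmoid outputs in [0, 1]; linear-perceptron scores are
    raw linear outputs (used for ranking/ROC and argmax decisions).
    """
    if isinstance(model, SLPModel):
        return slp_predict(model, X)
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match model input {model.layer_sizes[0]}"
        )
    return forward(model.weights, X)[-1]


def aggregate_by_cell(scores: np.ndarray, cell_ids: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean score per cell; returns (unique cell ids, aggregated scores)."""
    ids = np.asarray(cell_ids)
    uniq, inverse = np.unique(ids, return_inverse=True)
    agg = np.zeros((len(uniq), scores.shape[1]))
    counts = np.bincount(inverse, minlength=len(uniq))
    for c in range(scores.shape[1]):
        agg[:, c] = np.bincount(inverse, weights=scores[:, c], minlength=len(uniq))
    return uniq, agg / counts[:, None]
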