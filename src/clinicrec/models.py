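"""Multi-label learners: logistic regression and a feed-forward network.

Both models emit one independent logistic (sigmoid) output per target, so a
single forward pass scores every candidate order / order-set template at once.
The network is trained with a *positive-weighted* binary cross-entropy: order
labels are extremely sparse (most candidate orders are not placed in any given
24-hour horizon), so the loss multiplies each positive term by a constant
weight ``w`` to keep the gradient from being dominated by the easy negatives,
plus an L2 penalty on layer weight matrices::

    loss = -(1/m) Σ_i [ w·y_i·log ŷ_i + (1 - y_i)·log(1 - ŷ_i) ]
           + (λ/2) Σ_l ||W_l||²

The implementation is a self-contained NumPy multilayer perceptron (ReLU
hidden layers, optional batch normalization and inverted dropout, Nesterov
Adam or vanilla SGD), deterministic given a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse

EPS_CLIP = 1e-7


@dataclass(frozen=True)
class LossSpec:
    """Positive-class weight ``w`` and L2 coefficient ``l2_lambda`` (λ)."""

    positive_weight: float = 1.0
    l2_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.positive_weight <= 0:
            raise ValueError("positive_weight must be > 0")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


@dataclass(frozen=True)
class NetworkParams:
    """Architecture of the feed-forward net.

    ``hidden_units`` is one integer per hidden layer; an empty tuple reduces
    the architecture to multi-label logistic regression (a single linear
    layer with sigmoid outputs).
    """

    hidden_units: tuple[int, ...] = (512, 512)
    dropout_rate: float = 0.0
    batch_norm: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if any(h < 1 for h in self.hidden_units):
            raise ValueError("hidden layer widths must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "nadam"  # "sgd" | "nadam"
    learning_rate: float = 0.001
    epochs: int = 1
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "nadam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def weighted_bce_loss(
    y: np.ndarray,
    yhat: np.ndarray,
    loss: LossSpec = LossSpec(),
    layer_weights: tuple[np.ndarray, ...] = (),
) -> float:
    """Positive-weighted binary cross-entropy (natural log) plus L2 penalty.

    ``m`` is the number of examples (rows); with multi-label matrices each
    row's per-target terms are summed first, matching a per-example loss.
    With ``w = 1`` and ``λ = 0`` this is the standard mean BCE.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs yhat {yhat.shape}")
    yhat = np.clip(yhat, EPS_CLIP, 1.0 - EPS_CLIP)
    m = y.shape[0] if y.ndim > 0 and y.shape[0] > 0 else 1
    data = -(loss.positive_weight * y * np.log(yhat) + (1.0 - y) * np.log(1.0 - yhat)).sum() / m
    reg = 0.5 * loss.l2_lambda * sum(float((W**2).sum()) for W in layer_weights)
    return float(data + reg)


def _as_dense(X) -> np.ndarray:
    if scipy.sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


class FeedForwardScorer:
    """Multi-label MLP with sigmoid outputs.

    Holds layer weights ``W_l``/biases ``b_l``, optional batch-norm
    parameters and running moments, and the training-time column schema so
    scoring can reject mismatched feature matrices.
    """

    BN_MOMENTUM = 0.99
    BN_EPS = 1e-5

    def __init__(
        self,
        n_features: int,
        n_targets: int,
        net: NetworkParams,
        loss: LossSpec,
        seed: int,
        columns: list[str] | None = None,
    ):
        self.net = net
        self.loss_spec = loss
        self.columns = columns
        self.n_features = n_features
        self.n_targets = n_targets
        rng = np.random.default_rng(seed)
        dims = [n_features, *net.hidden_units, n_targets]
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            # He initialization for the ReLU stack
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        n_hidden = len(net.hidden_units)
        self.gamma = [np.ones(h) for h in net.hidden_units] if net.batch_norm else []
        self.beta = [np.zeros(h) for h in net.hidden_units] if net.batch_norm else []
        self.bn_mean = [np.zeros(h) for h in net.hidden_units]
        self.bn_var = [np.ones(h) for h in net.hidden_units]
        self._n_hidden = n_hidden

    # ---- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator | None):
        cache = {"a": [X], "pre": [], "bn": [], "drop": []}
        a = X
        for l in range(self._n_hidden):
            z = a @ self.W[l] + self.b[l]
            if self.net.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.bn_mean[l] = self.BN_MOMENTUM * self.bn_mean[l] + (1 - self.BN_MOMENTUM) * mu
                    self.bn_var[l] = self.BN_MOMENTUM * self.bn_var[l] + (1 - self.BN_MOMENTUM) * var
                else:
                    mu, var = self.bn_mean[l], self.bn_var[l]
                zhat = (z - mu) / np.sqrt(var + self.BN_EPS)
                cache["bn"].append((z, zhat, mu, var))
                z = self.gamma[l] * zhat + self.beta[l]
            h = np.maximum(z, 0.0)
            if training and self.net.dropout_rate > 0:
                keep = 1.0 - self.net.dropout_rate
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                cache["drop"].append(mask)
            cache["pre"].append(z)
            cache["a"].append(h)
            a = h
        logits = a @ self.W[-1] + self.b[-1]
        yhat = 1.0 / (1.0 + np.exp(-logits))
        return yhat, cache

    def _backward(self, y: np.ndarray, yhat: np.ndarray, cache):
        m = y.shape[0]
        w = self.loss_spec.positive_weight
        lam = self.loss_spec.l2_lambda
        # d(loss)/d(logit) for the weighted BCE through the sigmoid
        delta = (yhat * (1.0 + (w - 1.0) * y) - w * y) / m
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        ggamma = [None] * self._n_hidden
        gbeta = [None] * self._n_hidden
        gW[-1] = cache["a"][-1].T @ delta + lam * self.W[-1]
        gb[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for l in range(self._n_hidden - 1, -1, -1):
            if self.net.dropout_rate > 0 and cache["drop"]:
                da = da * cache["drop"][l]
            dz = da * (cache["pre"][l] > 0)
            if self.net.batch_norm:
                z, zhat, mu, var = cache["bn"][l]
                ggamma[l] = (dz * zhat).sum(axis=0)
                gbeta[l] = dz.sum(axis=0)
                inv = 1.0 / np.sqrt(var + self.BN_EPS)
                dzhat = dz * self.gamma[l]
                mb = z.shape[0]
                dz = inv / mb * (
                    mb * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
                )
            gW[l] = cache["a"][l].T @ dz + lam * self.W[l]
            gb[l] = dz.sum(axis=0)
            if l > 0:
                da = dz @ self.W[l].T
        return gW, gb, ggamma, gbeta

    # ---- training -----------------------------------------------------------

    def fit(self, X, Y, cfg: TrainConfig, log_path: str | Path | None = None) -> "FeedForwardScorer":
        Y = _as_dense(Y)
        n = X.shape[0]
        rng = np.random.default_rng(cfg.seed)
        params = self.W + self.b + self.gamma + self.beta
        state_m = [np.zeros_like(p) for p in params]
        state_v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        log = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb = _as_dense(X[idx])
                Yb = Y[idx]
                yhat, cache = self._forward(Xb, training=True, rng=rng)
                gW, gb, ggamma, gbeta = self._backward(Yb, yhat, cache)
                grads = gW + gb + [g for g in ggamma if g is not None] + [
                    g for g in gbeta if g is not None
                ]
                t += 1
                if cfg.optimizer == "sgd":
                    for p, g in zip(params, grads):
                        p -= cfg.learning_rate * g
                else:  # Nesterov Adam
                    for k, (p, g) in enumerate(zip(params, grads)):
                        state_m[k] = beta1 * state_m[k] + (1 - beta1) * g
                        state_v[k] = beta2 * state_v[k] + (1 - beta2) * g**2
                        mhat = state_m[k] / (1 - beta1 ** (t + 1))
                        vhat = state_v[k] / (1 - beta2**t)
                        m_bar = beta1 * mhat + (1 - beta1) * g / (1 - beta1**t)
                        p -= cfg.learning_rate * m_bar / (np.sqrt(vhat) + eps)
                batch_loss = weighted_bce_loss(Yb, yhat, self.loss_spec, tuple(self.W))
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite loss at update {t} (lr={cfg.learning_rate}, "
                        f"w={self.loss_spec.positive_weight}, λ={self.loss_spec.l2_lambda})"
                    )
                log.append({"update": t, "loss": batch_loss})
        if log_path is not None:
            with open(log_path, "w") as fh:
                for rec in log:
                    fh.write(json.dumps(rec) + "\n")
        self.train_log = log
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_dense(X)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature schema mismatch: model expects {self.n_features} columns, got {X.shape[1]}"
            )
        yhat, _ = self._forward(X, training=False, rng=None)
        return np.clip(yhat, EPS_CLIP, 1.0 - EPS_CLIP)

    # ---- persistence (text JSON checkpoints, schema embedded) ---------------

    def save(self, path: str | Path) -> None:
        obj = {
            "net": {
                "hidden_units": list(self.net.hidden_units),
                "dropout_rate": self.net.dropout_rate,
                "batch_norm": self.net.batch_norm,
            },
            "loss": {
                "positive_weight": self.loss_spec.positive_weight,
                "l2_lambda": self.loss_spec.l2_lambda,
            },
            "n_features": self.n_features,
            "n_targets": self.n_targets,
            "columns": self.columns,
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
            "gamma": [g.tolist() for g in self.gamma],
            "beta": [b.tolist() for b in self.beta],
            "bn_mean": [m.tolist() for m in self.bn_mean],
            "bn_var": [v.tolist() for v in self.bn_var],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path: str | Path) -> "FeedForwardScorer":
        obj = json.loads(Path(path).read_text())
        net = NetworkParams(
            hidden_units=tuple(obj["net"]["hidden_units"]),
            dropout_rate=obj["net"]["dropout_rate"],
            batch_norm=obj["net"]["batch_norm"],
        )
        loss = LossSpec(obj["loss"]["positive_weight"], obj["loss"]["l2_lambda"])
        model = cls(obj["n_features"], obj["n_targets"], net, loss, seed=0, columns=obj["columns"])
        model.W = [np.asarray(w) for w in obj["W"]]
        model.b = [np.asarray(b) for b in obj["b"]]
        model.gamma = [np.asarray(g) for g in obj["gamma"]]
        model.beta = [np.asarray(b) for b in obj["beta"]]
        model.bn_mean = [np.asarray(m) for m in obj["bn_mean"]]
        model.bn_var = [np.asarray(v) for v in obj["bn_var"]]
        return model


def train_logistic(
    X,
    Y,
    cfg: TrainConfig = TrainConfig(optimizer="sgd", learning_rate=0.01, epochs=1),
    columns: list[str] | None = None,
) -> FeedForwardScorer:
    """Multi-label logistic regression: one sigmoid output per target over a
    single linear layer, unweighted BCE, vanilla SGD (default lr 0.01, one
    full pass)."""
    model = FeedForwardScorer(
        X.shape[1], Y.shape[1], NetworkParams(hidden_units=()), LossSpec(), cfg.seed, columns
    )
    return model.fit(X, Y, cfg)


def train_clinicnet(
    X,
    Y,
    net: NetworkParams = NetworkParams(),
    loss: LossSpec = LossSpec(),
    cfg: TrainConfig = TrainConfig(),
    columns: list[str] | None = None,
    log_path: str | Path | None = None,
) -> FeedForwardScorer:
    """Train the feed-forward recommender on the weighted BCE objective."""
    model = FeedForwardScorer(X.shape[1], Y.shape[1], net, loss, cfg.seed, columns)
    return model.fit(X, Y, cfg, log_path=log_path)


def predict_scores(model: FeedForwardScorer, X) -> np.ndarray:
    """Per-row, per-target scores in (0, 1); dropout off, batch norm frozen."""
    return model.predict(X)


DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "hidden_layers": [1, 2, 3, 4],
    "hidden_units": [64, 128, 256, 512, 1024],
    "dropout": [0.0, 0.1, 0.25, 0.5],
    "batch_norm": [False, True],
    "positive_weight": [1.0, 3.0, 10.0, 30.0, 100.0],
    "l2_lambda": [0.0, 1e-5, 1e-4, 1e-3],
}


@dataclass
class SearchResult:
    net: NetworkParams
    loss: LossSpec
    val_score: float
    trials: list[dict] = field(default_factory=list)


def hyperparameter_search(
    X_train,
    Y_train,
    X_val,
    Y_val,
    space: dict[str, list] | None = None,
    n_rows: int = 50_000,
    n_trials: int = 10,
    seed: int = 0,
    cfg: TrainConfig = TrainConfig(),
) -> SearchResult:
    """Random search over architecture and loss hyperparameters.

    Each trial trains on a random ``n_rows``-row subsample of the training
    data and is scored by micro-averaged average precision on the validation
    split; the arg-max trial wins.  The full trial log is returned.
    """
    from clinicrec.evaluation import average_precision

    space = dict(DEFAULT_SEARCH_SPACE if space is None else space)
    rng = np.random.default_rng(seed)
    n = X_train.shape[0]
    if n_rows > n:
        warnings.warn(f"requested {n_rows} search rows but only {n} available; using all")
        n_rows = n
    sub = rng.choice(n, size=n_rows, replace=False)
    Xs, Ys = X_train[sub], _as_dense(Y_train)[sub]
    yval = _as_dense(Y_val).ravel()

    trials = []
    best = None
    for trial in range(n_trials):
        pick = {k: v[rng.integers(len(v))] for k, v in space.items()}
        net = NetworkParams(
            hidden_units=tuple([int(pick["hidden_units"])] * int(pick["hidden_layers"])),
            dropout_rate=float(pick["dropout"]),
            batch_norm=bool(pick["batch_norm"]),
        )
        loss = LossSpec(float(pick["positive_weight"]), float(pick["l2_lambda"]))
        trial_cfg = TrainConfig(
            optimizer=cfg.optimizer,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            seed=int(rng.integers(2**31)),
        )
        model = train_clinicnet(Xs, Ys, net, loss, trial_cfg)
        scores = model.predict(X_val).ravel()
        val_ap = average_precision(scores, yval)
        trials.append({"trial": trial, "params": pick, "val_average_precision": val_ap})
        if best is None or val_ap > best[0]:
            best = (val_ap, net, loss)
    return SearchResult(net=best[1], loss=best[2], val_score=best[0], trials=trials)
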