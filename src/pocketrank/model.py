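"""Densely connected feed-forward classifier for pocket pair vectors.

The network follows the DenseNet idea transplanted to fully connected
layers: hidden block ``k`` receives the concatenation of the raw input and
the outputs of all preceding blocks,

    h_0 = x
    h_k = dropout(ReLU(W_k · [h_0, …, h_{k-1}] + b_k)),   k = 1 … n_blocks
    p   = sigmoid(w · [h_0, …, h_n] + b)

so block ``k``'s weight matrix has input width ``input_dim + (k-1)·units``.
Training minimizes binary cross-entropy with mini-batch Adam; dropout is
active only during training, making inference a pure function.

The default geometry is 16 blocks of 100 units on a 600-d input with
dropout 0.25, trained for 1,500 epochs (the configuration at which the
reference validation curves converge); all of it is configurable.

Implemented directly in numpy (forward, backprop, Adam) as a scikit-learn
estimator, which keeps the arithmetic transparent enough to check against
a per-sample oracle in the tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

CHECKPOINT_FORMAT = "pocketrank-dfcnn-v1"


@dataclass
class DFCNNConfig:
    """Hyperparameters of the densely connected classifier."""

    input_dim: int = 600
    n_blocks: int = 16
    units: int = 100
    dropout: float = 0.25
    learning_rate: float = 1e-3
    epochs: int = 1500
    batch_size: int = 128
    random_state: int | None = 0

    def validate(self) -> None:
        problems = []
        if self.input_dim <= 0:
            problems.append("input_dim must be positive")
        if self.n_blocks < 1:
            problems.append("n_blocks must be >= 1")
        if self.units < 1:
            problems.append("units must be >= 1")
        if not (0 <= self.dropout < 1):
            problems.append("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            problems.append("learning_rate must be positive")
        if self.epochs < 0:
            problems.append("epochs must be >= 0")
        if self.batch_size < 1:
            problems.append("batch_size must be >= 1")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    # keep probabilities strictly inside (0, 1) despite float saturation
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def _bce(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class DenseFeedForwardClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier with densely connected hidden blocks.

    Parameters mirror :class:`DFCNNConfig`; fitted attributes follow the
    scikit-learn convention (``coefs_``, ``intercepts_``, ``history_`` …).
    ``predict_proba`` runs in inference mode (dropout off) and is
    deterministic.
    """

    def __init__(
        self,
        n_blocks: int = 16,
        units: int = 100,
        dropout: float = 0.25,
        learning_rate: float = 1e-3,
        epochs: int = 1500,
        batch_size: int = 128,
        random_state: int | None = 0,
    ):
        self.n_blocks = n_blocks
        self.units = units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # ------------------------------------------------------------------ config

    def _config(self, input_dim: int) -> DFCNNConfig:
        cfg = DFCNNConfig(
            input_dim=input_dim,
            n_blocks=self.n_blocks,
            units=self.units,
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            random_state=self.random_state,
        )
        cfg.validate()
        return cfg

    def _init_weights(self, cfg: DFCNNConfig, rng: np.random.Generator) -> None:
        """He-style uniform initialization, U(±sqrt(6 / fan_in))."""
        self.coefs_, self.intercepts_ = [], []
        width = cfg.input_dim
        for _ in range(cfg.n_blocks):
            limit = np.sqrt(6.0 / width)
            self.coefs_.append(rng.uniform(-limit, limit, size=(width, cfg.units)))
            self.intercepts_.append(np.zeros(cfg.units))
            width += cfg.units
        limit = np.sqrt(6.0 / width)
        self.output_coef_ = rng.uniform(-limit, limit, size=width)
        self.output_intercept_ = 0.0
        self.n_features_in_ = cfg.input_dim

    # ----------------------------------------------------------------- forward

    def _forward_cached(self, X: np.ndarray, dropout_rng: np.random.Generator | None):
        """Forward pass; returns (probabilities, concat activations, pre-
        activations, dropout masks).  ``dropout_rng`` None means inference."""
        concat = X
        zs, masks = [], []
        keep = 1.0 - self.dropout
        for W, b in zip(self.coefs_, self.intercepts_):
            z = concat @ W + b
            h = _relu(z)
            if dropout_rng is not None and self.dropout > 0:
                mask = dropout_rng.random(h.shape) >= self.dropout
                h = h * mask / keep
            else:
                mask = None
            zs.append(z)
            masks.append(mask)
            concat = np.concatenate([concat, h], axis=1)
        p = _sigmoid(concat @ self.output_coef_ + self.output_intercept_)
        return p, concat, zs, masks

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = self._check_X(X)
        p, _, _, _ = self._forward_cached(X, dropout_rng=None)
        return p

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} does not match model width "
                f"{self.n_features_in_}"
            )
        return X

    # ---------------------------------------------------------------- training

    def fit(self, X, y, X_val=None, y_val=None) -> "DenseFeedForwardClassifier":
        """Train with mini-batch Adam on binary cross-entropy.

        ``X_val``/``y_val`` (optional) are scored at the end of every epoch
        and recorded in ``history_`` alongside the running train loss and
        accuracy.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-d with one label per row")
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))):
            raise ValueError("labels must be binary 0/1")
        if classes.size < 2:
            raise ValueError("training set contains a single class")

        cfg = self._config(input_dim=X.shape[1])
        self.classes_ = np.array([0, 1])
        init_rng = np.random.default_rng(cfg.random_state)
        self._init_weights(cfg, init_rng)
        train_rng = np.random.default_rng(
            None if cfg.random_state is None else cfg.random_state + 1
        )

        params = self.coefs_ + self.intercepts_ + [self.output_coef_]
        adam_m = [np.zeros_like(p) for p in params] + [0.0]
        adam_v = [np.zeros_like(p) for p in params] + [0.0]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        self.history_ = {k: [] for k in ("epoch", "train_loss", "train_acc", "val_loss", "val_acc")}
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = train_rng.permutation(n)
            epoch_loss, epoch_correct = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                drop_rng = train_rng if self.dropout > 0 else None
                p, concat, zs, masks = self._forward_cached(xb, dropout_rng=drop_rng)
                loss = _bce(yb, p)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch + 1}"
                    )
                epoch_loss += loss * len(idx)
                epoch_correct += int(np.sum((p >= 0.5) == (yb == 1.0)))

                grads = self._backward(xb, yb, p, concat, zs, masks, cfg)
                step += 1
                flat = grads["W"] + grads["b"] + [grads["w_out"], grads["b_out"]]
                for i, g in enumerate(flat):
                    adam_m[i] = beta1 * np.asarray(adam_m[i]) + (1 - beta1) * g
                    adam_v[i] = beta2 * np.asarray(adam_v[i]) + (1 - beta2) * g**2
                    m_hat = adam_m[i] / (1 - beta1**step)
                    v_hat = adam_v[i] / (1 - beta2**step)
                    update = cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    if i < cfg.n_blocks:
                        self.coefs_[i] -= update
                    elif i < 2 * cfg.n_blocks:
                        self.intercepts_[i - cfg.n_blocks] -= update
                    elif i == 2 * cfg.n_blocks:
                        self.output_coef_ -= update
                    else:
                        self.output_intercept_ -= float(update)

            self.history_["epoch"].append(epoch + 1)
            self.history_["train_loss"].append(epoch_loss / n)
            self.history_["train_acc"].append(epoch_correct / n)
            if X_val is not None and y_val is not None:
                pv = self.decision_function(X_val)
                yv = np.asarray(y_val, dtype=float).ravel()
                self.history_["val_loss"].append(_bce(yv, pv))
                self.history_["val_acc"].append(float(np.mean((pv >= 0.5) == (yv == 1.0))))
            else:
                self.history_["val_loss"].append(np.nan)
                self.history_["val_acc"].append(np.nan)
        return self

    def _backward(self, xb, yb, p, concat, zs, masks, cfg):
        n = xb.shape[0]
        keep = 1.0 - self.dropout
        dlogit = (p - yb) / n  # dL/dz_out for sigmoid + BCE
        grad_w_out = concat.T @ dlogit
        grad_b_out = float(np.sum(dlogit))

        # gradient w.r.t. the full concatenation [x, h_1 … h_n]
        d_concat = np.outer(dlogit, self.output_coef_)
        grads_W = [None] * cfg.n_blocks
        grads_b = [None] * cfg.n_blocks
        for k in range(cfg.n_blocks - 1, -1, -1):
            w_in = cfg.input_dim + k * cfg.units
            dh = d_concat[:, w_in:]
            if masks[k] is not None:
                dh = dh * masks[k] / keep
            dz = dh * (zs[k] > 0)
            grads_W[k] = concat[:, :w_in].T @ dz
            grads_b[k] = dz.sum(axis=0)
            d_concat = d_concat[:, :w_in] + dz @ self.coefs_[k].T
        return {"W": grads_W, "b": grads_b, "w_out": grad_w_out, "b_out": grad_b_out}

    # ------------------------------------------------------------- persistence

    def save(self, path: str | os.PathLike, normalization: dict | None = None) -> None:
        """Write a single-file checkpoint (weights + config + normalization)."""
        check_is_fitted(self, "coefs_")
        cfg = self._config(self.n_features_in_)
        payload = {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(cfg),
            "normalization": normalization or getattr(self, "normalization_", None),
        }
        arrays = {
            f"W{k}": W for k, W in enumerate(self.coefs_)
        }
        arrays.update({f"b{k}": b for k, b in enumerate(self.intercepts_)})
        arrays["w_out"] = self.output_coef_
        arrays["b_out"] = np.array([self.output_intercept_])
        with open(os.fspath(path), "wb") as fh:
            np.savez(fh, meta=json.dumps(payload), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DenseFeedForwardClassifier":
        with np.load(os.fspath(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(
                    f"checkpoint format mismatch: {meta.get('format')!r} "
                    f"(expected {CHECKPOINT_FORMAT!r})"
                )
            cfg = DFCNNConfig(**meta["config"])
            model = cls(
                n_blocks=cfg.n_blocks,
                units=cfg.units,
                dropout=cfg.dropout,
                learning_rate=cfg.learning_rate,
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                random_state=cfg.random_state,
            )
            model.coefs_ = [data[f"W{k}"] for k in range(cfg.n_blocks)]
            model.intercepts_ = [data[f"b{k}"] for k in range(cfg.n_blocks)]
            model.output_coef_ = data["w_out"]
            model.output_intercept_ = float(data["b_out"][0])
            model.n_features_in_ = cfg.input_dim
            model.classes_ = np.array([0, 1])
            model.history_ = None
            if meta.get("normalization"):
                model.normalization_ = meta["normalization"]
        return model

    def history_frame(self):
        """Training history as a DataFrame (epoch, losses, accuracies)."""
        import pandas as pd

        check_is_fitted(self, "history_")
        return pd.DataFrame(self.history_)


def init_model(config: DFCNNConfig) -> DenseFeedForwardClassifier:
    """Initialize an untrained model with reproducible weights."""
    config.validate()
    model = DenseFeedForwardClassifier(
        n_blocks=config.n_blocks,
        units=config.units,
        dropout=config.dropout,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        random_state=config.random_state,
    )
    rng = np.random.default_rng(config.random_state)
    model._init_weights(config, rng)
    model.classes_ = np.array([0, 1])
    model.history_ = None
    return model


def save_model(model: DenseFeedForwardClassifier, path, normalization: dict | None = None) -> None:
    model.save(path, normalization=normalization)


def load_model(path) -> DenseFeedForwardClassifier:
    return DenseFeedForwardClassifier.load(path)
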