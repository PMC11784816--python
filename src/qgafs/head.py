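"""Softmax classifier head: dense-128 + ReLU -> dropout -> softmax.

A compact, fully deterministic numpy implementation of the single-hidden-
layer classification head used on top of extracted features.  Training
follows the usual deep-learning protocol for such heads: Adam with
learning rate 1e-3, mini-batches of 32, at most 50 epochs, early stopping
on validation loss (patience 5, best weights restored) and
reduce-on-plateau learning-rate decay.  Dropout is inverted dropout on the
hidden layer, active only during training.

Implements the scikit-learn estimator API, so the head composes with
pipelines and model selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["SoftmaxHeadClassifier"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _log_loss(proba: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(proba[np.arange(y.size), y], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


class SoftmaxHeadClassifier(ClassifierMixin, BaseEstimator):
    """Hidden-layer(+ReLU) -> dropout -> softmax classifier.

    Parameters
    ----------
    hidden_units : int, default 128
        Width of the single hidden layer.
    dropout : float, default 0.5
        Inverted-dropout rate on the hidden activations during training.
    learning_rate : float, default 0.001
        Initial Adam step size.
    batch_size : int, default 32
    max_epochs : int, default 50
    early_stopping_patience : int, default 5
        Stop when validation loss has not improved for this many epochs;
        the best-validation weights are restored.
    lr_reduce_patience : int, default 5
        Epochs without validation-loss improvement before the learning
        rate is multiplied by ``lr_reduce_factor``.
    lr_reduce_factor : float, default 0.5
    min_learning_rate : float, default 1e-5
    validation_fraction : float, default 0.1
        Stratified share of the training data held out for the callbacks.
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    history_ : DataFrame
        Per-epoch table (epoch, train_loss, val_loss, learning_rate).
    n_epochs_ : int
        Number of epochs actually run.
    """

    def __init__(
        self,
        hidden_units: int = 128,
        dropout: float = 0.5,
        learning_rate: float = 0.001,
        batch_size: int = 32,
        max_epochs: int = 50,
        early_stopping_patience: int = 5,
        lr_reduce_patience: int = 5,
        lr_reduce_factor: float = 0.5,
        min_learning_rate: float = 1e-5,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.lr_reduce_patience = lr_reduce_patience
        self.lr_reduce_factor = lr_reduce_factor
        self.min_learning_rate = min_learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, X, params, drop_mask=None):
        W1, b1, W2, b2 = params
        h = np.maximum(0.0, X @ W1 + b1)
        if drop_mask is not None:
            h = h * drop_mask
        return h, _softmax(h @ W2 + b2)

    def _split_validation(self, X, y, rng):
        frac = self.validation_fraction
        n_classes = np.unique(y).size
        n_val = int(round(frac * y.size))
        if n_val < n_classes or y.size - n_val < n_classes:
            # Too small for a stratified holdout; validate on the training
            # data itself so the callbacks still have a loss to watch.
            return X, y, X, y
        seed = int(rng.integers(2**31 - 1))
        try:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, test_size=frac, stratify=y, random_state=seed
            )
        except ValueError:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, test_size=frac, random_state=seed
            )
        return X_tr, y_tr, X_val, y_val

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        n, d = X.shape
        C = self.classes_.size
        rng = np.random.default_rng(self.random_state)

        X_tr, y_tr, X_val, y_val = self._split_validation(X, y_enc, rng)

        h = self.hidden_units
        W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h, C))
        b2 = np.zeros(C)
        params = [W1, b1, W2, b2]
        adam_m = [np.zeros_like(p) for p in params]
        adam_v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        lr = self.learning_rate
        best_val = np.inf
        best_params = [p.copy() for p in params]
        stall = lr_stall = 0
        step = 0
        history = []
        n_tr = y_tr.size

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, self.batch_size):
                idx = order[start : start + self.batch_size]
                Xb, yb = X_tr[idx], y_tr[idx]
                if self.dropout > 0.0:
                    mask = (rng.random((idx.size, h)) >= self.dropout) / (
                        1.0 - self.dropout
                    )
                else:
                    mask = None
                hid, proba = self._forward(Xb, params, mask)
                # Softmax cross-entropy gradients.
                dz2 = proba.copy()
                dz2[np.arange(yb.size), yb] -= 1.0
                dz2 /= yb.size
                gW2 = hid.T @ dz2
                gb2 = dz2.sum(axis=0)
                dh = dz2 @ params[2].T
                if mask is not None:
                    dh = dh * mask
                dh[hid <= 0.0] = 0.0
                gW1 = Xb.T @ dh
                gb1 = dh.sum(axis=0)
                grads = [gW1, gb1, gW2, gb2]
                step += 1
                for p, g, m_, v_ in zip(params, grads, adam_m, adam_v):
                    m_ *= beta1
                    m_ += (1 - beta1) * g
                    v_ *= beta2
                    v_ += (1 - beta2) * g * g
                    m_hat = m_ / (1 - beta1**step)
                    v_hat = v_ / (1 - beta2**step)
                    p -= lr * m_hat / (np.sqrt(v_hat) + eps)

            _, tr_proba = self._forward(X_tr, params)
            _, val_proba = self._forward(X_val, params)
            train_loss = _log_loss(tr_proba, y_tr)
            val_loss = _log_loss(val_proba, y_val)
            history.append((epoch, train_loss, val_loss, lr))

            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                stall = lr_stall = 0
            else:
                stall += 1
                lr_stall += 1
                if lr_stall >= self.lr_reduce_patience:
                    lr = max(lr * self.lr_reduce_factor, self.min_learning_rate)
                    lr_stall = 0
                if stall >= self.early_stopping_patience:
                    break

        self._params = best_params
        self.n_epochs_ = len(history)
        self.history_ = pd.DataFrame(
            history, columns=["epoch", "train_loss", "val_loss", "learning_rate"]
        )
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_params")
        X = check_array(X)
        _, proba = self._forward(X, self._params)
        return proba

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
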