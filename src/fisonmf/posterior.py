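"""Probabilistic class-membership model with analytic input gradients.

A single-hidden-layer feed-forward network (tanh hidden units, softmax
output) estimates ``p(c | x)``.  The network is deliberately small and
smooth: the Fisher information metric downstream is built from gradients of
the log-posteriors with respect to the *input*, so a well-conditioned,
differentiable posterior surface matters more than raw capacity.  Training
is deterministic full-batch gradient descent on the cross-entropy with L2
weight decay; the seed controls only the weight initialization.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["MLPPosterior"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPPosterior(ClassifierMixin, BaseEstimator):
    """Softmax MLP classifier exposing d(log p)/dx.

    Parameters
    ----------
    hidden_units : int, default=8
        Width of the single tanh hidden layer.
    alpha : float, default=1e-3
        L2 weight-decay strength.
    max_iter : int, default=500
        Full-batch gradient-descent epochs.
    learning_rate : float, default=0.5
        Initial step size; adapted multiplicatively (grown on accepted
        steps, halved and retried on loss increases).
    patience : int, default=50
        Early stopping: epochs without validation-loss improvement before
        training halts (only when validation data are supplied to ``fit``).
    random_state : int or None
        Seed for weight initialization.

    Attributes
    ----------
    classes_ : ndarray of shape (C,)
        Sorted class labels; row order of every probability/gradient output.
    loss_curve_ : list of float
        Training loss at each accepted step (non-increasing by construction).
    validation_accuracy_ : float or None
        Hold-out accuracy recorded when validation data were supplied.
    """

    def __init__(
        self,
        hidden_units: int = 8,
        alpha: float = 1e-3,
        max_iter: int = 500,
        learning_rate: float = 0.5,
        patience: int = 50,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.alpha = alpha
        self.max_iter = max_iter
        self.learning_rate = learning_rate
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _forward(self, X, params):
        W1, b1, W2, b2 = params
        A = np.tanh(X @ W1 + b1)
        P = _softmax(A @ W2 + b2)
        return A, P

    def _loss_grad(self, X, Y, params):
        W1, b1, W2, b2 = params
        n = X.shape[0]
        A, P = self._forward(X, params)
        eps = 1e-12
        loss = -np.sum(Y * np.log(P + eps)) / n
        loss += 0.5 * self.alpha * (np.sum(W1**2) + np.sum(W2**2))
        dZ2 = (P - Y) / n
        gW2 = A.T @ dZ2 + self.alpha * W2
        gb2 = dZ2.sum(axis=0)
        dA = dZ2 @ W2.T * (1.0 - A**2)
        gW1 = X.T @ dA + self.alpha * W1
        gb1 = dA.sum(axis=0)
        return loss, (gW1, gb1, gW2, gb2)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on labeled spectra (rows are cases).

        ``X_val``/``y_val``, when given, drive early stopping on the
        validation loss and are scored into ``validation_accuracy_``.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = np.array(sorted(set(y.tolist())), dtype=object)
        if self.classes_.size < 2:
            raise ValueError("training set must contain at least 2 classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        Y = np.zeros((X.shape[0], self.classes_.size))
        Y[np.arange(X.shape[0]), [class_index[c] for c in y]] = 1.0

        d, h, C = X.shape[1], self.hidden_units, self.classes_.size
        rng = np.random.default_rng(self.random_state)
        params = [
            rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, h)),
            np.zeros(h),
            rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, C)),
            np.zeros(C),
        ]

        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val)
            Y_val = np.zeros((X_val.shape[0], C))
            for i, c in enumerate(y_val):
                if c not in class_index:
                    raise ValueError(f"validation label {c!r} unseen in training")
                Y_val[i, class_index[c]] = 1.0

        step = float(self.learning_rate)
        loss, grads = self._loss_grad(X, Y, params)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss at initialization")
        self.loss_curve_ = [loss]
        best_val, best_params, stall = np.inf, None, 0
        for _ in range(self.max_iter):
            # back-tracking step: accept only non-increasing training loss
            accepted = False
            for _try in range(30):
                cand = [p - step * g for p, g in zip(params, grads)]
                new_loss, new_grads = self._loss_grad(X, Y, cand)
                if np.isfinite(new_loss) and new_loss <= loss:
                    params, loss, grads = cand, new_loss, new_grads
                    step *= 1.2
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            self.loss_curve_.append(loss)
            if X_val is not None:
                _, Pv = self._forward(X_val, params)
                vloss = -np.mean(np.sum(Y_val * np.log(Pv + 1e-12), axis=1))
                if vloss < best_val - 1e-12:
                    best_val, stall = vloss, 0
                    best_params = [p.copy() for p in params]
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if X_val is not None and best_params is not None:
            params = best_params

        self.coef_hidden_, self.intercept_hidden_ = params[0], params[1]
        self.coef_output_, self.intercept_output_ = params[2], params[3]
        self.n_features_in_ = d
        self.validation_accuracy_ = None
        if X_val is not None:
            self.validation_accuracy_ = float(
                np.mean(self.predict(X_val) == y_val)
            )
        return self

    # ------------------------------------------------------------------
    def _check_X(self, X):
        check_is_fitted(self, "coef_hidden_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probabilities, one row per case, columns = classes_."""
        X = self._check_X(X)
        params = (
            self.coef_hidden_, self.intercept_hidden_,
            self.coef_output_, self.intercept_output_,
        )
        return self._forward(X, params)[1]

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def log_proba_input_gradient(self, X) -> np.ndarray:
        """Analytic gradients of log-posteriors w.r.t. the input.

        Returns an array of shape ``(m, C, d)``: row ``c`` of each case's
        block is grad_x log p(c | x).  For a single 1-D input a ``(C, d)``
        matrix is returned.
        """
        single = np.asarray(X).ndim == 1
        X = self._check_X(X)
        W1, W2 = self.coef_hidden_, self.coef_output_
        A = np.tanh(X @ W1 + self.intercept_hidden_)
        P = _softmax(A @ W2 + self.intercept_output_)
        T = 1.0 - A**2                          # tanh'(z) per hidden unit
        # grad_x log p_c = W1 @ diag(T) @ (W2[:, c] - W2 @ p)
        mean_dir = P @ W2.T                     # (m, h): sum_k p_k W2[:, k]
        G = np.einsum("dh,mh,hc->mcd", W1, T, W2)
        G -= np.einsum("dh,mh->md", W1, T * mean_dir)[:, None, :]
        if single:
            return G[0]
        return G
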