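"""Single-hidden-layer perceptron used as the wrapper's fitness classifier.

A deliberately small, fully deterministic network: logistic activations in
the hidden and output layers (output f(d) = 1 / (1 + exp(-g(d))) with g the
weighted sum over hidden units), trained by full-batch gradient descent on
mean squared error.  The wrapper needs a fast, reproducible scorer that it
retrains thousands of times on tiny sample sizes — not a competitive deep
model — so there is no momentum, no minibatching, and no adaptive optimizer:
given identical data, architecture and seed, retraining is bit-identical,
and full-batch updates make training invariant to sample order.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = ["SigmoidMLPClassifier", "mlp_train", "mlp_predict"]

_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SigmoidMLPClassifier(ClassifierMixin, BaseEstimator):
    """Binary perceptron with one logistic hidden layer and sigmoid output.

    Parameters
    ----------
    hidden_size : number of hidden units m (default 10).
    learning_rate : gradient-descent step size (default 0.1).
    epochs : maximum full-batch epochs (default 300).
    tol : stop early once the MSE improvement per epoch falls below this.
    standardize : z-score features with training-set statistics before
        training (computed on the training data only); near-constant columns
        fall back to unit scale.
    random_state : seed for the uniform(-0.5, 0.5) weight initialisation.

    Attributes
    ----------
    input_weights_, input_bias_ : hidden-layer parameters (d x m, m).
    output_weights_, output_bias_ : output-layer parameters (m, scalar).
    loss_curve_ : per-epoch training MSE (non-increasing up to tolerance).
    n_epochs_ : epochs actually run.
    """

    def __init__(
        self,
        hidden_size: int = 10,
        learning_rate: float = 0.1,
        epochs: int = 300,
        tol: float = 1e-6,
        standardize: bool = True,
        random_state=None,
    ):
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.tol = tol
        self.standardize = standardize
        self.random_state = random_state

    def _forward(self, X):
        hidden = _sigmoid(X @ self.input_weights_ + self.input_bias_)
        prob = _sigmoid(hidden @ self.output_weights_ + self.output_bias_)
        return hidden, prob

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        if classes.size > 2 or not np.isin(classes, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        y = y.astype(float)

        if self.standardize:
            self._mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd < 1e-12] = 1.0
            self._scale_ = sd
        else:
            self._mean_ = np.zeros(X.shape[1])
            self._scale_ = np.ones(X.shape[1])
        Z = (X - self._mean_) / self._scale_

        rng = np.random.default_rng(self.random_state)
        d, m = X.shape[1], self.hidden_size
        self.input_weights_ = rng.uniform(-0.5, 0.5, size=(d, m))
        self.input_bias_ = rng.uniform(-0.5, 0.5, size=m)
        self.output_weights_ = rng.uniform(-0.5, 0.5, size=m)
        self.output_bias_ = float(rng.uniform(-0.5, 0.5))

        n = Z.shape[0]
        lr = self.learning_rate
        losses = []
        for epoch in range(self.epochs):
            hidden, prob = self._forward(Z)
            err = prob - y
            loss = float(np.mean(err**2))
            losses.append(loss)
            # dL/dp = 2 err / n ; p = sigmoid -> * p(1-p)
            grad_out = (2.0 / n) * err * prob * (1.0 - prob)
            g_w2 = hidden.T @ grad_out
            g_b2 = grad_out.sum()
            grad_hidden = np.outer(grad_out, self.output_weights_) * hidden * (1.0 - hidden)
            g_w1 = Z.T @ grad_hidden
            g_b1 = grad_hidden.sum(axis=0)
            self.output_weights_ -= lr * g_w2
            self.output_bias_ -= lr * g_b2
            self.input_weights_ -= lr * g_w1
            self.input_bias_ -= lr * g_b1
            if epoch > 0 and losses[-2] - loss < self.tol:
                break
        _, prob = self._forward(Z)
        self.loss_curve_ = np.array(losses + [float(np.mean((prob - y) ** 2))])
        self.n_epochs_ = len(losses)
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "input_weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        Z = (X - self._mean_) / self._scale_
        _, p1 = self._forward(Z)
        p1 = np.clip(p1, _EPS, 1.0 - _EPS)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def mlp_train(X, y, config: dict | None = None) -> SigmoidMLPClassifier:
    """Train a :class:`SigmoidMLPClassifier` on a gene-subset matrix."""
    if np.asarray(X).ndim != 2 or np.asarray(X).shape[1] < 1:
        raise ValueError("X must have at least one gene column")
    return SigmoidMLPClassifier(**(config or {})).fit(X, y)


def mlp_predict(model: SigmoidMLPClassifier, X):
    """Return (probabilities in (0,1), hard 0/1 labels at threshold 0.5)."""
    proba = model.predict_proba(X)[:, 1]
    return proba, (proba >= 0.5).astype(int)
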