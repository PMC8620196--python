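"""Minimal feed-forward binary classifier in numpy.

Fully connected ReLU hidden layers with a single sigmoid output,
trained by minibatch Adam on binary cross-entropy, with inverted
dropout on hidden activations and an early stop once full-pass
training accuracy reaches a configured level. Kept dependency-free so
the network's forward pass (affine pre-activation, ReLU, sigmoid
output) is exactly the documented model.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLPBinaryClassifier:
    """ReLU MLP with sigmoid output trained on binary cross-entropy."""

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (256, 64),
        learning_rate: float = 1e-4,
        batch_size: int = 128,
        epochs: int = 100,
        dropout: float = 0.25,
        early_stop_accuracy: float = 0.99,
        seed: int = 0,
    ) -> None:
        self.hidden_sizes = tuple(hidden_sizes)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.early_stop_accuracy = early_stop_accuracy
        self.seed = seed
        self.n_features_: int | None = None
        self.loss_curve_: list[float] = []
        self.stopped_early_: bool = False

    # -- internals ---------------------------------------------------------
    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = (n_features, *self.hidden_sizes, 1)
        self.W_ = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.b_ = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Returns (probabilities, activations, dropout masks)."""
        acts = [X]
        masks: list[np.ndarray] = []
        h = X
        for W, b in zip(self.W_[:-1], self.b_[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            if rng is not None and self.dropout > 0.0:
                mask = rng.random(h.shape) >= self.dropout
                h = h * mask / (1.0 - self.dropout)
                masks.append(mask)
            acts.append(h)
        p = _sigmoid((h @ self.W_[-1] + self.b_[-1]).ravel())
        return p, acts, masks

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPBinaryClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be in {0, 1}")
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes present")
        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        self.n_features_ = d
        self._init_params(d, rng)
        # Adam state
        mW = [np.zeros_like(W) for W in self.W_]
        vW = [np.zeros_like(W) for W in self.W_]
        mb = [np.zeros_like(b) for b in self.b_]
        vb = [np.zeros_like(b) for b in self.b_]
        beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
        step = 0
        self.loss_curve_ = []
        self.stopped_early_ = False
        for _epoch in range(self.epochs):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                Xb, yb = X[idx], y[idx]
                p, acts, masks = self._forward(Xb, rng)
                # d(BCE)/d(pre-sigmoid) = p - y, averaged over the batch
                delta = ((p - yb) / len(yb))[:, None]
                grads_W, grads_b = [], []
                for layer in range(len(self.W_) - 1, -1, -1):
                    grads_W.append(acts[layer].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = delta @ self.W_[layer].T
                        delta *= acts[layer] > 0
                        if self.dropout > 0.0:
                            delta *= masks[layer - 1] / (1.0 - self.dropout)
                grads_W.reverse()
                grads_b.reverse()
                step += 1
                corr1 = 1.0 - beta1**step
                corr2 = 1.0 - beta2**step
                for i in range(len(self.W_)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * grads_W[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * grads_W[i] ** 2
                    self.W_[i] -= self.learning_rate * (mW[i] / corr1) / (
                        np.sqrt(vW[i] / corr2) + eps_adam
                    )
                    mb[i] = beta1 * mb[i] + (1 - beta1) * grads_b[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * grads_b[i] ** 2
                    self.b_[i] -= self.learning_rate * (mb[i] / corr1) / (
                        np.sqrt(vb[i] / corr2) + eps_adam
                    )
            p_full = self.predict_proba(X)
            p_clip = np.clip(p_full, 1e-12, 1 - 1e-12)
            self.loss_curve_.append(
                float(-np.mean(y * np.log(p_clip) + (1 - y) * np.log(1 - p_clip)))
            )
            accuracy = float(np.mean((p_full > 0.5) == (y == 1.0)))
            if accuracy >= self.early_stop_accuracy:
                self.stopped_early_ = True
                break
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.n_features_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        p, _, _ = self._forward(X, rng=None)
        return p
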