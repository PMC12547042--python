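"""Minimal feed-forward network core (NumPy).

Dense layers with ReLU hidden activations, inverted dropout, L2 weight
penalty and an Adam optimiser — enough to express both heads used in the
package: a softmax classifier and a scalar Cox risk score.  Gradients are
analytic; the caller supplies the loss gradient at the output layer.
"""

from __future__ import annotations

import numpy as np


class DenseNet:
    """Fully connected net; ``hidden_sizes`` may be empty (linear model)."""

    def __init__(self, n_in: int, hidden_sizes, n_out: int, rng: np.random.Generator):
        sizes = [n_in, *hidden_sizes, n_out]
        self.W = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b) for b in sizes[1:]]

    @property
    def params(self):
        return self.W + self.b

    def forward(self, X: np.ndarray, dropout: float = 0.0, rng=None):
        """Return (output, cache). Dropout (inverted) on hidden activations."""
        a = X
        acts, masks = [X], []
        L = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < L - 1:
                a = np.maximum(z, 0.0)
                if dropout > 0.0:
                    mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(a)
            else:
                a = z
        return a, (acts, masks)

    def backward(self, cache, grad_out: np.ndarray, l2: float = 0.0):
        """Backpropagate d(loss)/d(output); returns grads aligned with params.

        The L2 penalty ``l2/2 * sum ||W||^2`` (weights only) is folded in.
        """
        acts, masks = cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = grad_out
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta + l2 * self.W[i]
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return gW + gb


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Scaler:
    """Column standardiser fitted on the training split only."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = mean
        self.std = np.where(std > 0, std, 1.0)

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        return cls(X.mean(axis=0), X.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std
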