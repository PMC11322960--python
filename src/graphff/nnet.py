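"""Minimal dense neural-network primitives with explicit backward passes.

The parametrization network is small (a few hundred thousand weights) and is
trained on CPU, so layers are plain NumPy matrix products with hand-derived
gradients. Weights live in flat dicts mapping ``"path/to/W"`` -> ndarray,
which makes checkpoints, Adam state, and gradient accumulation trivial.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "relu", "softplus", "softplus_inv", "sigmoid", "sigmoid_inv",
    "init_linear", "linear_forward", "linear_backward",
    "mlp2_init", "mlp2_forward", "mlp2_backward",
    "zeros_like_tree", "add_into", "AdamOptimizer",
]


def relu(x):
    return np.maximum(x, 0.0)


def softplus(x):
    # numerically stable log(1 + exp(x))
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    y = np.asarray(y, dtype=np.float64)
    return y + np.log(-np.expm1(-y))


def sigmoid(x):
    return expit(x)


def sigmoid_inv(y):
    return logit(y)


# ---------------------------------------------------------------------------
# layers


def init_linear(rng, n_in, n_out, w_std=None, bias=None):
    """He-normal weight init; optional per-channel bias values."""
    std = np.sqrt(2.0 / n_in) if w_std is None else w_std
    W = rng.normal(0.0, std, size=(n_in, n_out))
    b = np.zeros(n_out) if bias is None else np.array(bias, dtype=np.float64)
    return W, b


def linear_forward(W, b, x):
    return x @ W + b


def linear_backward(W, x, dy):
    dW = x.T @ dy
    db = dy.sum(axis=0)
    dx = dy @ W.T
    return dx, dW, db


def mlp2_init(rng, n_in, n_hidden, n_out, out_std=None, out_bias=None):
    W1, b1 = init_linear(rng, n_in, n_hidden)
    W2, b2 = init_linear(rng, n_hidden, n_out, w_std=out_std, bias=out_bias)
    return {"W1": W1, "b1": b1, "W2": W2, "b2": b2}


LEAKY_SLOPE = 0.01  # keeps head units trainable after violent early epochs


def mlp2_forward(p, x):
    """Two-layer perceptron: leaky_relu(x W1 + b1) W2 + b2.

    Returns (y, cache). The leaky activation (slope 0.01 on the negative
    side) prevents hidden units from dying irreversibly under the large
    transient gradients of early training.
    """
    h_pre = x @ p["W1"] + p["b1"]
    h = np.where(h_pre > 0.0, h_pre, LEAKY_SLOPE * h_pre)
    y = h @ p["W2"] + p["b2"]
    return y, (x, h_pre > 0.0, h)


def mlp2_backward(p, cache, dy):
    """Backward for :func:`mlp2_forward`. Returns (dx, grads dict)."""
    x, mask, h = cache
    dW2 = h.T @ dy
    db2 = dy.sum(axis=0)
    dh = dy @ p["W2"].T
    dh_pre = dh * np.where(mask, 1.0, LEAKY_SLOPE)
    dW1 = x.T @ dh_pre
    db1 = dh_pre.sum(axis=0)
    dx = dh_pre @ p["W1"].T
    return dx, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


# ---------------------------------------------------------------------------
# flat weight-tree helpers


def zeros_like_tree(tree: dict) -> dict:
    return {k: np.zeros_like(v) for k, v in tree.items()}


def add_into(acc: dict, grads: dict, prefix: str = ""):
    for k, v in grads.items():
        acc[prefix + k] += v


class AdamOptimizer:
    """Adam on a flat dict of arrays, with optional exponential lr decay."""

    def __init__(self, params: dict, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 lr_decay=1.0, weight_decay=0.0):
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.weight_decay = weight_decay
        self.t = 0
        self.t0 = 0   # schedule rebase point (see reconfigure)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def reconfigure(self, lr=None, lr_decay=None, weight_decay=None):
        """Change the schedule while keeping moment estimates and step count.

        Re-creating the optimizer between training stages discards the
        curvature information in the second moments; the resulting oversized
        first steps can throw a converging run back onto a plateau. The decay
        schedule is rebased to the current step.
        """
        if lr is not None:
            self.lr0 = lr
        if lr_decay is not None:
            self.lr_decay = lr_decay
        if weight_decay is not None:
            self.weight_decay = weight_decay
        self.t0 = self.t

    @property
    def lr(self):
        return self.lr0 * self.lr_decay ** (self.t - self.t0)

    def step(self, params: dict, grads: dict):
        self.t += 1
        lr = self.lr0 * self.lr_decay ** (self.t - self.t0)
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
            # decoupled (AdamW-style) decay on weight matrices, not biases
            if self.weight_decay and "/W" in k:
                params[k] -= lr * self.weight_decay * params[k]
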