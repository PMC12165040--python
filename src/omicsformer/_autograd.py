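"""Minimal reverse-mode building blocks for the attention networks.

The models here are small enough (one attention block per omics layer,
affine decoders, full-batch training on cohort-scale n) that explicit
NumPy forward/backward passes are simpler and faster than pulling in a
deep-learning framework.  Gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def softmax_rows(S: np.ndarray) -> np.ndarray:
    """Numerically stable row-wise softmax."""
    Z = S - S.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def attention_scale(scale_dim: int, mode: str) -> float:
    if mode == "sqrt":
        return float(np.sqrt(scale_dim))
    if mode == "linear":
        return float(scale_dim)
    raise ValueError(f"unknown attention scale mode {mode!r}")


def attention_forward(X, W_Q, W_K, W_V, scale: float):
    """H = rowsoftmax(QK^T / scale) V with Q=XW_Q, K=XW_K, V=XW_V.

    Returns (H, cache) where cache feeds :func:`attention_backward`.
    """
    Q = X @ W_Q
    K = X @ W_K
    V = X @ W_V
    A = softmax_rows((Q @ K.T) / scale)
    H = A @ V
    return H, (X, Q, K, V, A, scale)


def attention_backward(dH, cache, W_Q, W_K, W_V):
    """Gradients of a scalar loss through attention_forward.

    Returns (dX, dW_Q, dW_K, dW_V).
    """
    X, Q, K, V, A, scale = cache
    dA = dH @ V.T
    dV = A.T @ dH
    # softmax Jacobian applied row-wise
    dS = A * (dA - (dA * A).sum(axis=1, keepdims=True))
    dQ = (dS @ K) / scale
    dK = (dS.T @ Q) / scale
    dW_Q = X.T @ dQ
    dW_K = X.T @ dK
    dW_V = X.T @ dV
    dX = dQ @ W_Q.T + dK @ W_K.T + dV @ W_V.T
    return dX, dW_Q, dW_K, dW_V


def affine_forward(H, W, b):
    return H @ W + b


def affine_backward(dY, H, W):
    """Returns (dH, dW, db) for Y = HW + b."""
    return dY @ W.T, H.T @ dY, dY.sum(axis=0)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list length mismatch")
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def init_matrix(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    """Seeded scaled-normal initialization, std 1/sqrt(d_in)."""
    return rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_out))
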