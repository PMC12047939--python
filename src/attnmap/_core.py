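"""Shared numerics: attention stack forward/backward and the Adam optimizer.

The attention layer here is deliberately minimal: a single head, no score
scaling, no bias vectors, no output projection, no normalization and no
feed-forward sublayer.  For a token matrix Z (tokens x width) and learned
projections W_Q, W_K, W_V it computes

    Z' = softmax(Z W_Q (Z W_K)^T) Z W_V,

with the softmax applied row-wise.  Gradients are derived by hand (reverse
mode) so the models run on plain numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax_rows", "attention_layer", "stack_forward",
           "stack_backward", "Adam"]


def softmax_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety.

    Works on the last axis of any array; raises on NaN input.
    """
    M = np.asarray(M)
    if not np.issubdtype(M.dtype, np.floating):
        M = M.astype(float)
    if np.isnan(M).any():
        raise ValueError("softmax input contains NaN")
    shifted = M - M.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def attention_layer(Z: np.ndarray, W_Q: np.ndarray, W_K: np.ndarray,
                    W_V: np.ndarray) -> np.ndarray:
    """One unscaled single-head attention layer applied to token matrix Z.

    Z may be a single (L, d) matrix or a batch (n, L, d); the projections
    are shared across the batch and attention is independent per item.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[-1] != W_Q.shape[0]:
        raise ValueError(
            f"token width {Z.shape[-1]} incompatible with projection {W_Q.shape}")
    Q = Z @ W_Q
    K = Z @ W_K
    V = Z @ W_V
    scores = Q @ np.swapaxes(K, -1, -2)
    return softmax_rows(scores) @ V


def stack_forward(Z0: np.ndarray, layers: list[tuple[np.ndarray, np.ndarray, np.ndarray]]):
    """Run a batch of token matrices through stacked attention layers.

    Returns the final token tensor and per-layer caches for backprop.
    """
    Z = Z0
    caches = []
    for (W_Q, W_K, W_V) in layers:
        Q = Z @ W_Q
        K = Z @ W_K
        V = Z @ W_V
        A = softmax_rows(Q @ np.swapaxes(K, -1, -2))
        Z_next = A @ V
        caches.append((Z, Q, K, V, A))
        Z = Z_next
    return Z, caches


def stack_backward(dZ: np.ndarray, caches, layers):
    """Backpropagate through the attention stack.

    Parameters
    ----------
    dZ : gradient of the loss w.r.t. the stack's output tokens.
    caches, layers : as produced by / passed to :func:`stack_forward`.

    Returns
    -------
    dZ0 : gradient w.r.t. the input tokens.
    grads : list of (dW_Q, dW_K, dW_V) per layer, summed over the batch.
    """
    grads: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [None] * len(layers)
    for i in range(len(layers) - 1, -1, -1):
        W_Q, W_K, W_V = layers[i]
        Z_in, Q, K, V, A = caches[i]
        dA = dZ @ np.swapaxes(V, -1, -2)
        dV = np.swapaxes(A, -1, -2) @ dZ
        # softmax Jacobian, row-wise
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = dS @ K
        dK = np.swapaxes(dS, -1, -2) @ Q
        dW_Q = np.einsum("nld,nle->de", Z_in, dQ)
        dW_K = np.einsum("nld,nle->de", Z_in, dK)
        dW_V = np.einsum("nld,nle->de", Z_in, dV)
        grads[i] = (dW_Q, dW_K, dW_V)
        dZ = dQ @ W_Q.T + dK @ W_K.T + dV @ W_V.T
    return dZ, grads


class Adam:
    """Adam optimizer over a named dict of numpy parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain gradient descent over a named dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3):
        self.params = params
        self.lr = lr

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            self.params[k] -= self.lr * g
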