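"""Single-environment attention model for genotype-phenotype regression.

Architecture, for a genotype x in {-1, +1}^L:

1.  Signed one-hot encoding: locus l is a one-hot row whose single nonzero
    entry is x_l.  Multiplying by a learned L x d embedding matrix W_embed
    gives token z_l = x_l * W_embed[l] — computed directly, without
    materializing the sparse one-hot matrix.
2.  NL stacked single-head attention layers (default 3), each with its own
    d x d query/key/value projections; no score scaling, biases,
    normalization, residual connections or feed-forward sublayers.
3.  A regression head: y_pred = beta0 + sum_l <reg_weights[l], z'''_l>.

The trainable-parameter count is therefore exactly
``2*L*d + 3*d**2*NL + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import stack_backward, stack_forward

__all__ = ["AttentionGPModel", "TokenEmbedding", "count_parameters", "init_model"]


@dataclass
class TokenEmbedding:
    """Per-locus embedded tokens for one individual (row l = z_l)."""

    Z: np.ndarray


def count_parameters(L: int, d: int, NL: int) -> int:
    """Closed-form trainable parameter count of the attention model.

    Embedding (L*d) + regression weights (L*d) + NL layers of three d x d
    projections + one scalar bias.
    """
    if L <= 0 or d <= 0 or NL < 0:
        raise ValueError("dimensions must be positive (NL may be 0)")
    return 2 * L * d + 3 * d * d * NL + 1


class AttentionGPModel:
    """Attention-based genotype-phenotype regression model.

    Parameters are held as plain numpy arrays; ``params`` maps names to the
    live arrays so an optimizer can update them in place.
    """

    def __init__(self, L: int, d: int, NL: int = 3, seed: int = 0,
                 dtype=np.float64):
        if L <= 0 or d <= 0 or NL < 0:
            raise ValueError("dimensions must be positive (NL may be 0)")
        self.L, self.d, self.NL = L, d, NL
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(d)
        self.params: dict[str, np.ndarray] = {
            "W_embed": rng.normal(0.0, scale, size=(L, d)).astype(self.dtype),
            "reg_weights": np.zeros((L, d), dtype=self.dtype),
            "beta0": np.zeros((), dtype=self.dtype),
        }
        for i in range(NL):
            for name in ("W_Q", "W_K", "W_V"):
                self.params[f"{name}_{i}"] = rng.normal(
                    0.0, scale, size=(d, d)).astype(self.dtype)

    # -- structure -------------------------------------------------------
    @property
    def layers(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        return [(self.params[f"W_Q_{i}"], self.params[f"W_K_{i}"],
                 self.params[f"W_V_{i}"]) for i in range(self.NL)]

    def n_parameters(self) -> int:
        """Enumerate trainable scalars (cross-checks the closed form)."""
        return sum(int(np.asarray(v).size) for v in self.params.values())

    # -- forward ---------------------------------------------------------
    def embed(self, genotype_row: np.ndarray) -> TokenEmbedding:
        """Embed one genotype: row l of Z equals x_l * W_embed[l]."""
        x = np.asarray(genotype_row, dtype=float)
        if x.shape != (self.L,):
            raise ValueError(f"expected genotype of length {self.L}, got {x.shape}")
        return TokenEmbedding(x[:, None] * self.params["W_embed"])

    def _embed_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.L:
            raise ValueError(f"expected {self.L} loci, got {X.shape[1]}")
        return X[:, :, None] * self.params["W_embed"][None, :, :]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted phenotypes for a (n, L) genotype matrix of +/-1."""
        Z0 = self._embed_batch(X)
        Z, _ = stack_forward(Z0, self.layers)
        return (np.einsum("nld,ld->n", Z, self.params["reg_weights"])
                + float(self.params["beta0"]))

    def forward(self, genotype_row: np.ndarray) -> float:
        """Predicted phenotype of a single genotype vector."""
        return float(self.predict(np.asarray(genotype_row)[None, :])[0])

    # -- training support ------------------------------------------------
    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean-squared-error loss and parameter gradients on a batch."""
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=self.dtype)
        n = len(y)
        Z0 = self._embed_batch(X)
        Z, caches = stack_forward(Z0, self.layers)
        B = self.params["reg_weights"]
        pred = np.einsum("nld,ld->n", Z, B) + float(self.params["beta0"])
        resid = pred - y
        loss = float(np.mean(resid ** 2))
        dpred = 2.0 * resid / n
        grads: dict[str, np.ndarray] = {
            "reg_weights": np.einsum("n,nld->ld", dpred, Z),
            "beta0": np.array(dpred.sum()),
        }
        dZ = dpred[:, None, None] * B[None, :, :]
        dZ0, layer_grads = stack_backward(dZ, caches, self.layers)
        for i, (dW_Q, dW_K, dW_V) in enumerate(layer_grads):
            grads[f"W_Q_{i}"] = dW_Q
            grads[f"W_K_{i}"] = dW_K
            grads[f"W_V_{i}"] = dW_V
        grads["W_embed"] = np.einsum("nl,nld->ld", X, dZ0)
        return loss, grads

    # -- persistence -----------------------------------------------------
    def save(self, path: str, **metadata) -> None:
        """Checkpoint all matrices plus dims/seed; round-trip bit-exact."""
        np.savez(path, _dims=np.array([self.L, self.d, self.NL, self.seed]),
                 **self.params, **{f"_meta_{k}": np.asarray(v)
                                   for k, v in metadata.items()})

    @classmethod
    def load(cls, path: str) -> "AttentionGPModel":
        with np.load(path) as data:
            L, d, NL, seed = (int(v) for v in data["_dims"])
            model = cls(L, d, NL, seed)
            for k in model.params:
                model.params[k] = np.array(data[k])
        return model


def init_model(L: int, d: int, NL: int = 3, seed: int = 0,
               dtype=np.float64) -> AttentionGPModel:
    """Fresh model: Gaussian(sd=1/sqrt(d)) embeddings and projections,
    zero regression weights and bias; reproducible under ``seed``."""
    return AttentionGPModel(L, d, NL, seed, dtype)
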