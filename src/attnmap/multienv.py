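"""Multi-environment attention model with environment tokens.

One model is trained jointly on records from several environments.  Each
individual contributes L locus tokens plus one environment token:

* locus token l:  [ x_l * W_embed[l] | 0_E | 1 ]
* env token:      [ 0_d | e_alpha | 1 ]

where e_alpha is the one-hot vector of the record's environment, so every
token has width d + E + 1 and carries a trailing ones column.  The L + 1
tokens pass through NL shared attention layers (projections of size
(d+E+1) x (d+E+1)); the regression head reads all L + 1 output tokens (a
flag restricts it to locus tokens for ablation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core import stack_backward, stack_forward

__all__ = ["MultiEnvGPModel", "EnvironmentIndex", "count_parameters_multi_env"]


@dataclass
class EnvironmentIndex:
    """Ordered environment labels with one-hot encoding."""

    labels: list[str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("environment labels must be unique")

    @property
    def E(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown environment: {label!r}") from None

    def one_hot(self, alpha: int) -> np.ndarray:
        if not 0 <= alpha < self.E:
            raise KeyError(f"environment index {alpha} out of range")
        v = np.zeros(self.E)
        v[alpha] = 1.0
        return v


def count_parameters_multi_env(L: int, d: int, E: int, NL: int) -> int:
    """Trainable scalars: embedding, NL x 3 projections of width d+E+1,
    regression weights over L+1 tokens, one bias."""
    D = d + E + 1
    return L * d + 3 * D * D * NL + (L + 1) * D + 1


class MultiEnvGPModel:
    """Joint attention model over genotype tokens plus an environment token."""

    def __init__(self, L: int, d: int, env_labels: list[str], NL: int = 3,
                 seed: int = 0, head_locus_only: bool = False,
                 dtype=np.float64):
        if L <= 0 or d <= 0 or NL < 0:
            raise ValueError("dimensions must be positive (NL may be 0)")
        self.L, self.d, self.NL = L, d, NL
        self.envs = EnvironmentIndex(list(env_labels))
        self.seed = seed
        self.head_locus_only = head_locus_only
        self.dtype = np.dtype(dtype)
        E = self.envs.E
        self.D = d + E + 1  # token width
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(self.D)
        self.params: dict[str, np.ndarray] = {
            "W_embed": rng.normal(0.0, 1.0 / np.sqrt(d),
                                  size=(L, d)).astype(self.dtype),
            "reg_weights": np.zeros((L + 1, self.D), dtype=self.dtype),
            "beta0": np.zeros((), dtype=self.dtype),
        }
        for i in range(NL):
            for name in ("W_Q", "W_K", "W_V"):
                self.params[f"{name}_{i}"] = rng.normal(
                    0.0, scale, size=(self.D, self.D)).astype(self.dtype)

    @property
    def E(self) -> int:
        return self.envs.E

    @property
    def layers(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        return [(self.params[f"W_Q_{i}"], self.params[f"W_K_{i}"],
                 self.params[f"W_V_{i}"]) for i in range(self.NL)]

    def n_parameters(self) -> int:
        return sum(int(np.asarray(v).size) for v in self.params.values())

    # -- token construction ---------------------------------------------
    def build_tokens(self, genotype_row: np.ndarray, alpha: int) -> np.ndarray:
        """Token matrix (L+1) x (d+E+1) for one individual in env alpha."""
        return self._build_batch(np.asarray(genotype_row)[None, :],
                                 np.array([alpha]))[0]

    def _build_batch(self, X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        alphas = np.asarray(alphas, dtype=np.intp)
        if X.shape[1] != self.L:
            raise ValueError(f"expected {self.L} loci, got {X.shape[1]}")
        if alphas.min(initial=0) < 0 or alphas.max(initial=0) >= self.E:
            raise KeyError("environment index out of range")
        n = X.shape[0]
        T = np.zeros((n, self.L + 1, self.D), dtype=self.dtype)
        T[:, :self.L, :self.d] = X[:, :, None] * self.params["W_embed"][None]
        T[np.arange(n), self.L, self.d + alphas] = 1.0
        T[:, :, -1] = 1.0  # ones column on every token
        return T

    def _head_mask(self) -> np.ndarray:
        mask = np.ones((self.L + 1, 1), dtype=self.dtype)
        if self.head_locus_only:
            mask[self.L, 0] = 0.0
        return mask

    # -- forward ---------------------------------------------------------
    def predict(self, X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        T0 = self._build_batch(X, alphas)
        T, _ = stack_forward(T0, self.layers)
        B = self.params["reg_weights"] * self._head_mask()
        return np.einsum("ntd,td->n", T, B) + float(self.params["beta0"])

    def forward(self, genotype_row: np.ndarray, alpha: int) -> float:
        return float(self.predict(np.asarray(genotype_row)[None, :],
                                  np.array([alpha]))[0])

    # -- training support ------------------------------------------------
    def loss_and_grads(self, X: np.ndarray, alphas: np.ndarray, y: np.ndarray):
        y = np.asarray(y, dtype=self.dtype)
        n = len(y)
        T0 = self._build_batch(X, alphas)
        T, caches = stack_forward(T0, self.layers)
        mask = self._head_mask()
        B = self.params["reg_weights"] * mask
        pred = np.einsum("ntd,td->n", T, B) + float(self.params["beta0"])
        resid = pred - y
        loss = float(np.mean(resid ** 2))
        dpred = 2.0 * resid / n
        grads: dict[str, np.ndarray] = {
            "reg_weights": np.einsum("n,ntd->td", dpred, T) * mask,
            "beta0": np.array(dpred.sum()),
        }
        dT = dpred[:, None, None] * B[None]
        dT0, layer_grads = stack_backward(dT, caches, self.layers)
        for i, (dW_Q, dW_K, dW_V) in enumerate(layer_grads):
            grads[f"W_Q_{i}"] = dW_Q
            grads[f"W_K_{i}"] = dW_K
            grads[f"W_V_{i}"] = dW_V
        X = np.asarray(X, dtype=self.dtype)
        grads["W_embed"] = np.einsum("nl,nld->ld", X, dT0[:, :self.L, :self.d])
        return loss, grads

    # -- persistence -----------------------------------------------------
    def save(self, path: str, **metadata) -> None:
        np.savez(path,
                 _dims=np.array([self.L, self.d, self.NL, self.seed,
                                 int(self.head_locus_only)]),
                 _labels=np.array(self.envs.labels),
                 **self.params,
                 **{f"_meta_{k}": np.asarray(v) for k, v in metadata.items()})

    @classmethod
    def load(cls, path: str) -> "MultiEnvGPModel":
        with np.load(path, allow_pickle=False) as data:
            L, d, NL, seed, locus_only = (int(v) for v in data["_dims"])
            labels = [str(s) for s in data["_labels"]]
            model = cls(L, d, labels, NL, seed, bool(locus_only))
            for k in model.params:
                model.params[k] = np.array(data[k])
        return model
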