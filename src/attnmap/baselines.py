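"""Regularized linear and linear+pairwise regression baselines.

These implement the classical genotype-phenotype expansion truncated at
first or second order,

    y_pred = beta0 + sum_j beta_j x_j  (+ sum_{j<k} beta_jk x_j x_k),

fit by penalized least squares (ridge by default, lasso by flag) with the
intercept never penalized.  The pairwise variant has L(L+1)/2 + 1
parameters and is typically restricted to a causal-locus subset, since a
full-genome pairwise fit is computationally infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression, Ridge

from .genotypes import GenotypeMatrix

__all__ = ["LinearGPModel", "fit_linear", "fit_linear_pairwise",
           "count_parameters_pairwise", "predict_linear",
           "DEFAULT_LAMBDA_GRID"]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)

#: refuse pairwise expansions beyond this many features
PAIR_FEATURE_CAP = 10_000_000


@dataclass
class LinearGPModel:
    """Fitted (restricted) linear or linear+pairwise regression model."""

    intercept: float
    linear_coeffs: dict[str, float]
    pairwise_coeffs: dict[tuple[str, str], float] = field(default_factory=dict)
    reg_kind: str = "ridge"
    reg_lambda: float = 0.0
    loci_subset: list[str] | None = None

    def __post_init__(self) -> None:
        for (j, k) in self.pairwise_coeffs:
            if not j < k:
                raise ValueError(f"pairwise key {(j, k)} must be ordered j < k")

    @property
    def loci(self) -> list[str]:
        return list(self.linear_coeffs)

    def n_parameters(self) -> int:
        return 1 + len(self.linear_coeffs) + len(self.pairwise_coeffs)

    def effect_size(self, locus: str) -> float:
        """Background-independent per-flip effect 2*beta_l of the linear part."""
        return 2.0 * self.linear_coeffs.get(locus, 0.0)

    def export_coefficients(self, path: str) -> None:
        rows = [("intercept", "", self.intercept)]
        rows += [("linear", l, c) for l, c in self.linear_coeffs.items()]
        rows += [("pairwise", f"{j},{k}", c)
                 for (j, k), c in self.pairwise_coeffs.items()]
        pd.DataFrame(rows, columns=["term", "loci", "coefficient"]).to_csv(
            path, sep="\t", index=False)


def count_parameters_pairwise(L: int) -> int:
    """Parameter count of the linear+pairwise model: L(L+1)/2 + 1."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return L * (L + 1) // 2 + 1


def _make_estimator(kind: str, lam: float):
    if lam < 0:
        raise ValueError("regularization strength must be >= 0")
    if kind == "ridge":
        if lam == 0:
            return LinearRegression()
        return Ridge(alpha=lam, solver="cholesky")
    if kind == "lasso":
        if lam == 0:
            return LinearRegression()
        return Lasso(alpha=lam, max_iter=50_000)
    raise ValueError(f"unknown regularization kind {kind!r}")


def _fit_design(F_train: np.ndarray, y_train: np.ndarray, lam, kind: str,
                F_val: np.ndarray | None, y_val: np.ndarray | None):
    """Fit a penalized regression, selecting lambda on validation if a grid
    is given.  Returns (intercept, coefficient vector, chosen lambda)."""
    lams = np.atleast_1d(np.asarray(lam, dtype=float))
    if len(lams) > 1 and (F_val is None or y_val is None):
        raise ValueError("a lambda grid requires a validation set")
    best = None
    for l in lams:
        est = _make_estimator(kind, float(l))
        est.fit(F_train, y_train)
        if len(lams) == 1:
            return float(est.intercept_), np.asarray(est.coef_), float(l)
        val_mse = float(np.mean((est.predict(F_val) - y_val) ** 2))
        if best is None or val_mse < best[0]:
            best = (val_mse, float(est.intercept_), np.asarray(est.coef_), float(l))
    return best[1], best[2], best[3]


def _subset(G: GenotypeMatrix, loci_subset: list[str] | None) -> GenotypeMatrix:
    return G if loci_subset is None else G.subset_loci(loci_subset)


def fit_linear(G_train: GenotypeMatrix, y_train: np.ndarray, lam=1e-3,
               kind: str = "ridge", loci_subset: list[str] | None = None,
               G_val: GenotypeMatrix | None = None,
               y_val: np.ndarray | None = None) -> LinearGPModel:
    """Fit the additive baseline.  ``lam`` may be a scalar or a grid; a grid
    is resolved by validation mean-squared error."""
    if G_train.n_individuals < 2:
        raise ValueError("need at least 2 training individuals")
    Gt = _subset(G_train, loci_subset)
    F_val = None
    if G_val is not None:
        F_val = _subset(G_val, loci_subset).values.astype(float)
    b0, coef, chosen = _fit_design(Gt.values.astype(float), np.asarray(y_train, float),
                                   lam, kind, F_val,
                                   None if y_val is None else np.asarray(y_val, float))
    return LinearGPModel(b0, dict(zip(Gt.locus_ids, coef.tolist())),
                         {}, kind, chosen, loci_subset)


def _pairwise_features(X: np.ndarray, locus_ids: list[str]):
    L = X.shape[1]
    n_feat = L * (L + 1) // 2
    if n_feat > PAIR_FEATURE_CAP:
        raise ValueError(
            f"pairwise expansion would need {n_feat} features (cap "
            f"{PAIR_FEATURE_CAP}); restrict to a locus subset")
    pairs = list(combinations(range(L), 2))
    F = np.empty((X.shape[0], L + len(pairs)))
    F[:, :L] = X
    for p, (j, k) in enumerate(pairs):
        F[:, L + p] = X[:, j] * X[:, k]
    pair_ids = [(locus_ids[j], locus_ids[k]) for j, k in pairs]
    return F, pair_ids


def fit_linear_pairwise(G_train: GenotypeMatrix, y_train: np.ndarray, lam=1e-3,
                        kind: str = "ridge",
                        loci_subset: list[str] | None = None,
                        G_val: GenotypeMatrix | None = None,
                        y_val: np.ndarray | None = None) -> LinearGPModel:
    """Fit the additive + pairwise-interaction baseline over the feature map
    {x_j} union {x_j * x_k, j < k}."""
    Gt = _subset(G_train, loci_subset)
    F, pair_ids = _pairwise_features(Gt.values.astype(float), Gt.locus_ids)
    F_val = None
    if G_val is not None:
        F_val, _ = _pairwise_features(
            _subset(G_val, loci_subset).values.astype(float), Gt.locus_ids)
    b0, coef, chosen = _fit_design(F, np.asarray(y_train, float), lam, kind,
                                   F_val,
                                   None if y_val is None else np.asarray(y_val, float))
    L = Gt.n_loci
    pair_coeffs = {tuple(sorted(p)): float(c)
                   for p, c in zip(pair_ids, coef[L:])}
    return LinearGPModel(b0, dict(zip(Gt.locus_ids, coef[:L].tolist())),
                         pair_coeffs, kind, chosen, loci_subset)


def predict_linear(model: LinearGPModel, G: GenotypeMatrix) -> np.ndarray:
    """Evaluate the fitted truncation exactly on a genotype panel."""
    for locus in model.linear_coeffs:
        if locus not in G.locus_ids:
            raise KeyError(f"locus {locus!r} absent from genotype matrix")
    col = {l: j for j, l in enumerate(G.locus_ids)}
    X = G.values.astype(float)
    y = np.full(G.n_individuals, model.intercept)
    for locus, c in model.linear_coeffs.items():
        y += c * X[:, col[locus]]
    for (j, k), c in model.pairwise_coeffs.items():
        y += c * X[:, col[j]] * X[:, col[k]]
    return y
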