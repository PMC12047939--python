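"""Synthetic genotype-phenotype maps with tunable higher-order epistasis.

The synthetic phenotype of an individual with genotype x in {-1, +1}^L is

    y = beta0 + eps * sum_l beta_l x_l
            + (1 - eps) * sum_{(i,j,k,l)} beta_ijkl x_i x_j x_k x_l + eta,

where the sums run over a designated set of causal loci, the fourth-order
sum runs over as many random quadruplets of causal loci as there are causal
loci, and eta is Gaussian noise whose standard deviation is a fixed
fraction (default 20%) of the standard deviation of the noise-free
phenotype.  The mixing weight eps interpolates from purely additive
(eps = 1) to purely fourth-order epistatic (eps = 0) architectures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EpistasisSpec",
    "PhenotypeSet",
    "sample_epistasis_spec",
    "evaluate_map",
    "add_noise",
    "true_effect_sizes",
    "sample_multi_env_specs",
]


@dataclass
class EpistasisSpec:
    """Ground-truth synthetic genotype-phenotype map.

    ``quad_terms`` holds ``(loci_quadruplet, coefficient)`` pairs; each
    quadruplet is a sorted tuple of 4 distinct causal locus ids.
    """

    causal_loci: list[str]
    beta0: float
    linear_coeffs: dict[str, float]
    quad_terms: list[tuple[tuple[str, str, str, str], float]]
    epsilon: float
    coeff_dist: str = "gaussian"
    noise_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        causal = set(self.causal_loci)
        if set(self.linear_coeffs) != causal:
            raise ValueError("linear_coeffs keys must equal causal_loci")
        for quad, _ in self.quad_terms:
            if len(set(quad)) != 4 or not causal.issuperset(quad):
                raise ValueError(f"invalid quadruplet {quad}")
            if tuple(sorted(quad)) != tuple(quad):
                raise ValueError(f"quadruplet {quad} must be stored sorted")

    # -- serialization: round-trip exact via JSON text -------------------
    def to_json(self) -> str:
        return json.dumps({
            "causal_loci": self.causal_loci,
            "beta0": self.beta0,
            "linear_coeffs": self.linear_coeffs,
            "quad_terms": [[list(q), c] for q, c in self.quad_terms],
            "epsilon": self.epsilon,
            "coeff_dist": self.coeff_dist,
            "noise_frac": self.noise_frac,
            "seed": self.seed,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EpistasisSpec":
        d = json.loads(text)
        d["quad_terms"] = [(tuple(q), c) for q, c in d["quad_terms"]]
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "EpistasisSpec":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class PhenotypeSet:
    """Observed and noise-free phenotypes for a panel of individuals."""

    individual_ids: list[str]
    noise_free_values: np.ndarray
    observed_values: np.ndarray
    environment_label: str = "env0"

    def __post_init__(self) -> None:
        self.noise_free_values = np.asarray(self.noise_free_values, dtype=float)
        self.observed_values = np.asarray(self.observed_values, dtype=float)
        if not (len(self.individual_ids) == len(self.noise_free_values)
                == len(self.observed_values)):
            raise ValueError("id and value vectors must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual_id": self.individual_ids,
            "environment": self.environment_label,
            "observed": self.observed_values,
            "noise_free": self.noise_free_values,
        })

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw_coeffs(rng: np.random.Generator, size: int, coeff_dist: str,
                 random_sign: bool = True) -> np.ndarray:
    """Draw i.i.d. coefficients: standard Gaussian or rate-1 exponential.

    Exponential draws get a random +/-1 sign by default so the quartic sum
    is not pathologically one-sided.
    """
    if coeff_dist == "gaussian":
        return rng.standard_normal(size)
    if coeff_dist == "exponential":
        mags = rng.exponential(scale=1.0, size=size)
        if random_sign:
            mags *= rng.integers(0, 2, size=size) * 2 - 1
        return mags
    raise ValueError(f"unknown coeff_dist {coeff_dist!r}")


def _sample_quadruplets(rng: np.random.Generator, causal: list[str],
                        n_quads: int) -> list[tuple[str, str, str, str]]:
    """Draw distinct sorted quadruplets of causal loci, no repeats."""
    from math import comb
    if comb(len(causal), 4) < n_quads:
        raise ValueError(
            f"cannot draw {n_quads} distinct quadruplets from {len(causal)} causal loci")
    seen: set[tuple[str, ...]] = set()
    quads: list[tuple[str, str, str, str]] = []
    while len(quads) < n_quads:
        idx = rng.choice(len(causal), size=4, replace=False)
        q = tuple(sorted(causal[i] for i in idx))
        if q in seen:
            continue
        seen.add(q)
        quads.append(q)
    return quads


def sample_epistasis_spec(
    locus_ids: list[str],
    n_causal: int,
    epsilon: float,
    coeff_dist: str = "gaussian",
    seed: int = 0,
    noise_frac: float = 0.2,
    beta0: float = 0.0,
    exp_random_sign: bool = True,
) -> EpistasisSpec:
    """Draw a random synthetic map over ``n_causal`` causal loci.

    Causal loci are drawn uniformly without replacement; the number of
    fourth-order quadruplets equals the number of causal loci.
    """
    if n_causal > len(locus_ids):
        raise ValueError("n_causal exceeds number of loci")
    if n_causal < 4 and epsilon < 1.0:
        raise ValueError("need at least 4 causal loci for quartic terms (epsilon < 1)")
    rng = np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(len(locus_ids), size=n_causal, replace=False))
    causal = [locus_ids[i] for i in causal_idx]
    lin = _draw_coeffs(rng, n_causal, coeff_dist, exp_random_sign)
    linear_coeffs = dict(zip(causal, lin.tolist()))
    from math import comb
    n_quads = n_causal if n_causal >= 4 else 0
    if epsilon == 1.0:
        # quartic terms carry zero weight; cap at what is drawable
        n_quads = min(n_quads, comb(max(n_causal, 0), 4))
    if n_quads:
        quads = _sample_quadruplets(rng, causal, n_quads)
        qcoef = _draw_coeffs(rng, n_quads, coeff_dist, exp_random_sign)
        quad_terms = list(zip(quads, qcoef.tolist()))
    else:
        quad_terms = []
    return EpistasisSpec(causal, beta0, linear_coeffs, quad_terms,
                         epsilon, coeff_dist, noise_frac, seed)


def _spec_arrays(spec: EpistasisSpec, G: GenotypeMatrix):
    """Resolve the spec's locus ids to column indices of G."""
    for locus in spec.causal_loci:
        if locus not in G.locus_ids:
            raise KeyError(f"causal locus {locus!r} absent from genotype matrix")
    col = {l: j for j, l in enumerate(G.locus_ids)}
    lin_idx = np.array([col[l] for l in spec.causal_loci], dtype=np.intp)
    lin_coef = np.array([spec.linear_coeffs[l] for l in spec.causal_loci])
    if spec.quad_terms:
        quad_idx = np.array([[col[l] for l in q] for q, _ in spec.quad_terms],
                            dtype=np.intp)
        quad_coef = np.array([c for _, c in spec.quad_terms])
    else:
        quad_idx = np.zeros((0, 4), dtype=np.intp)
        quad_coef = np.zeros(0)
    return lin_idx, lin_coef, quad_idx, quad_coef


def evaluate_map(spec: EpistasisSpec, G: GenotypeMatrix) -> np.ndarray:
    """Noise-free phenotype of every individual under the synthetic map."""
    lin_idx, lin_coef, quad_idx, quad_coef = _spec_arrays(spec, G)
    X = G.values.astype(np.float64)
    y = np.full(G.n_individuals, spec.beta0, dtype=float)
    y += spec.epsilon * (X[:, lin_idx] @ lin_coef)
    if len(quad_coef):
        prods = X[:, quad_idx].prod(axis=2)  # (n, n_quads)
        y += (1.0 - spec.epsilon) * (prods @ quad_coef)
    return y


def add_noise(noise_free: np.ndarray, noise_frac: float = 0.2,
              seed: int = 0, individual_ids: list[str] | None = None,
              environment_label: str = "env0") -> PhenotypeSet:
    """Add Gaussian noise scaled to a fraction of the noise-free signal sd."""
    noise_free = np.asarray(noise_free, dtype=float)
    if len(noise_free) < 2:
        raise ValueError("need at least 2 values to scale noise")
    sd = float(noise_free.std())
    if sd == 0.0:
        logger.warning("add_noise: constant noise-free phenotype, zero noise added")
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, noise_frac * sd, size=len(noise_free))
    ids = individual_ids or [f"g{i:05d}" for i in range(len(noise_free))]
    return PhenotypeSet(ids, noise_free, noise_free + eta, environment_label)


def true_effect_sizes(spec: EpistasisSpec, G: GenotypeMatrix,
                      locus: str) -> tuple[np.ndarray, float]:
    """Per-background and averaged effect of flipping one locus.

    For each individual the noise-free map is evaluated with the locus
    forced to +1 and to -1, all other alleles fixed; the per-background
    effect is the difference, and the average is its mean over individuals.
    A non-causal locus yields exact zeros.
    """
    j = G.locus_index(locus)
    if locus not in spec.causal_loci:
        logger.info("true_effect_sizes: locus %s is not causal; zeros", locus)
        return np.zeros(G.n_individuals), 0.0
    Gp = GenotypeMatrix(np.array(G.values), list(G.locus_ids), list(G.individual_ids))
    Gp.values[:, j] = 1
    y_plus = evaluate_map(spec, Gp)
    Gp.values[:, j] = -1
    y_minus = evaluate_map(spec, Gp)
    delta = y_plus - y_minus
    return delta, float(delta.mean())


def sample_multi_env_specs(
    env_labels: list[str],
    locus_ids: list[str],
    n_causal: int,
    epsilon: float,
    env_correlation: np.ndarray,
    seed: int = 0,
    noise_frac: float = 0.2,
) -> list[EpistasisSpec]:
    """Correlated synthetic maps across environments.

    All environments share the same causal loci and quadruplet index sets;
    each coefficient (linear and quartic) is drawn jointly across
    environments from a zero-mean multivariate Gaussian with the given
    correlation matrix and unit marginal variance, so cross-environment
    coefficient correlations match the requested structure.
    """
    E = len(env_labels)
    C = np.asarray(env_correlation, dtype=float)
    if C.shape != (E, E):
        raise ValueError("env_correlation must be E x E")
    eigvals = np.linalg.eigvalsh((C + C.T) / 2)
    if eigvals.min() < -1e-8:
        raise ValueError("env_correlation must be positive semi-definite")
    rng = np.random.default_rng(seed)
    base = sample_epistasis_spec(locus_ids, n_causal, epsilon,
                                 seed=int(rng.integers(2**31)),
                                 noise_frac=noise_frac)
    n_quads = len(base.quad_terms)
    # Joint draw: rows = coefficients, columns = environments.  An
    # eigendecomposition factor handles singular correlation matrices
    # (e.g. all-ones) exactly.
    w, V = np.linalg.eigh((C + C.T) / 2)
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    lin_all = rng.standard_normal((n_causal, E)) @ factor.T
    quad_all = rng.standard_normal((n_quads, E)) @ factor.T
    specs = []
    for a, label in enumerate(env_labels):
        specs.append(EpistasisSpec(
            causal_loci=list(base.causal_loci),
            beta0=base.beta0,
            linear_coeffs=dict(zip(base.causal_loci, lin_all[:, a].tolist())),
            quad_terms=[(q, float(quad_all[i, a]))
                        for i, (q, _) in enumerate(base.quad_terms)],
            epsilon=epsilon,
            noise_frac=noise_frac,
            seed=seed,
        ))
    return specs
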