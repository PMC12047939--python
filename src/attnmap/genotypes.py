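"""Simulated F1-cross genotype panels, locus pruning, and dataset splits.

Genotypes are biallelic and coded +1/-1 per locus (one row per haploid
individual).  The simulator emulates the linkage structure of an F1 haploid
cross: along each chromosome the parental origin follows a two-state Markov
chain, switching parent between adjacent loci with a fixed recombination
probability, independently across chromosomes and individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "CrossSimConfig",
    "SplitIndices",
    "simulate_cross_genotypes",
    "prune_correlated_loci",
    "split_dataset",
    "read_genotype_matrix",
    "write_genotype_matrix",
]


@dataclass
class GenotypeMatrix:
    """A panel of biallelic genotypes, individuals x loci, entries exactly +/-1.

    Parameters
    ----------
    values : ndarray of shape (n_individuals, n_loci)
        Allele codes, every entry +1 or -1.
    locus_ids : sequence of str
        Unique, ordered locus identifiers (columns).
    individual_ids : sequence of str, optional
        Row identifiers; defaults to ``g0000, g0001, ...``.
    chromosome_of_locus : dict, optional
        Maps locus id to a chromosome index.
    """

    values: np.ndarray
    locus_ids: list[str]
    individual_ids: list[str] = field(default_factory=list)
    chromosome_of_locus: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if not np.isin(self.values, (-1, 1)).all():
            raise ValueError("genotype entries must be exactly +1 or -1")
        self.locus_ids = [str(l) for l in self.locus_ids]
        if len(self.locus_ids) != self.values.shape[1]:
            raise ValueError("locus_ids length must equal number of columns")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids must be unique")
        if not self.individual_ids:
            self.individual_ids = [f"g{i:05d}" for i in range(self.values.shape[0])]
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError("individual_ids length must equal number of rows")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"unknown locus id: {locus_id!r}") from None

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        chrom = None
        if self.chromosome_of_locus is not None:
            chrom = {l: self.chromosome_of_locus[l] for l in locus_ids
                     if l in self.chromosome_of_locus}
        return GenotypeMatrix(self.values[:, idx], list(locus_ids),
                              list(self.individual_ids), chrom)

    def subset_individuals(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(self.values[indices], list(self.locus_ids),
                              [self.individual_ids[i] for i in indices],
                              self.chromosome_of_locus)


@dataclass(frozen=True)
class CrossSimConfig:
    """Settings for the haploid F1-cross genotype simulator.

    ``recomb_prob`` is the probability of a parental switch between adjacent
    loci on a chromosome; 0.5 makes loci independent, 0 makes each
    chromosome a single block.
    """

    n_individuals: int
    n_chromosomes: int
    loci_per_chromosome: int
    recomb_prob: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_chromosomes <= 0 or self.loci_per_chromosome <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.recomb_prob <= 0.5:
            raise ValueError("recomb_prob must lie in [0, 0.5]")


def simulate_cross_genotypes(config: CrossSimConfig) -> GenotypeMatrix:
    """Simulate a panel of haploid F1-cross genotypes with linkage.

    Each chromosome is an independent two-state Markov chain over parental
    origin: the first locus is +/-1 with probability 1/2 and each subsequent
    locus flips parent with probability ``config.recomb_prob``.  Adjacent
    same-chromosome loci then have expected correlation ``1 - 2*recomb_prob``;
    loci on different chromosomes are independent.
    """
    rng = np.random.default_rng(config.seed)
    n, c, m = config.n_individuals, config.n_chromosomes, config.loci_per_chromosome
    # First locus of each chromosome, then cumulative flips along it.
    start = rng.integers(0, 2, size=(n, c, 1), dtype=np.int8) * 2 - 1
    flips = rng.random(size=(n, c, m - 1)) < config.recomb_prob if m > 1 else \
        np.zeros((n, c, 0), dtype=bool)
    signs = np.concatenate(
        [np.ones((n, c, 1), dtype=np.int8),
         np.where(flips, -1, 1).astype(np.int8)], axis=2)
    values = (start * np.cumprod(signs, axis=2)).reshape(n, c * m)
    locus_ids = [f"chr{ci + 1}_l{li + 1}" for ci in range(c) for li in range(m)]
    chrom = {f"chr{ci + 1}_l{li + 1}": ci for ci in range(c) for li in range(m)}
    return GenotypeMatrix(values, locus_ids, chromosome_of_locus=chrom)


def _pairwise_abs_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r| between two +/-1 columns; conventions for constant columns.

    Two zero-variance columns are maximally redundant (treated as r=1); a
    constant against a varying column carries no collinearity (treated as 0).
    """
    sa, sb = a.std(), b.std()
    if sa == 0 and sb == 0:
        return 1.0
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def prune_correlated_loci(
    G: GenotypeMatrix, threshold: float = 0.94
) -> tuple[GenotypeMatrix, list[str]]:
    """Greedy left-to-right pruning of loci correlated above ``threshold``.

    Scans loci in order and keeps a locus iff its absolute Pearson
    correlation with every already-kept locus is strictly below the
    threshold.  The result is deterministic and idempotent: the kept set's
    columns pairwise satisfy ``|r| < threshold``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    X = G.values.astype(np.float64)
    n_const = int((X.std(axis=0) == 0).sum())
    if n_const:
        logger.info("prune_correlated_loci: %d constant columns present", n_const)
    kept: list[int] = []
    for j in range(X.shape[1]):
        ok = True
        for k in kept:
            if _pairwise_abs_correlation(X[:, k], X[:, j]) >= threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    kept_ids = [G.locus_ids[j] for j in kept]
    return G.subset_loci(kept_ids), kept_ids


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/validation/test index arrays."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split indices overlap")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    n: int,
    train_val_frac: float = 0.85,
    train_frac_within: float = 0.85,
    seed: int = 0,
) -> SplitIndices:
    """Shuffle ``n`` indices into train/validation/test sets.

    ``train_val_frac`` of the data is retained for training+validation (the
    rest is the test set); within that block ``train_frac_within`` goes to
    training and the remainder to validation.  Block sizes round half-up;
    every set must be nonempty.
    """
    if not (0 < train_val_frac < 1 and 0 < train_frac_within < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if n < 3:
        raise ValueError("need n >= 3 for three nonempty splits")
    n_trainval = _round_half_up(n * train_val_frac)
    n_test = n - n_trainval
    n_train = _round_half_up(n_trainval * train_frac_within)
    n_val = n_trainval - n_train
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"splits of n={n} with fractions ({train_val_frac}, {train_frac_within}) "
            f"leave an empty set (train={n_train}, val={n_val}, test={n_test})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitIndices(
        train=perm[:n_train],
        val=perm[n_train:n_train + n_val],
        test=perm[n_train + n_val:],
    )


def write_genotype_matrix(G: GenotypeMatrix, path: str) -> None:
    """Write a genotype matrix as tab-delimited text (+1/-1 body entries)."""
    df = pd.DataFrame(G.values, index=G.individual_ids, columns=G.locus_ids)
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_genotype_matrix(path: str, recode01: bool = False) -> GenotypeMatrix:
    """Read a tab-delimited genotype matrix.

    First row holds locus ids, first column individual ids, body entries in
    {+1, -1}.  With ``recode01=True`` a {0, 1} coding is accepted and 0 is
    recoded to -1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if recode01:
        if not np.isin(values, (0, 1)).all():
            raise ValueError("recode01=True requires entries in {0, 1}")
        values = values * 2 - 1
    return GenotypeMatrix(values, [str(c) for c in df.columns],
                          [str(i) for i in df.index])
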