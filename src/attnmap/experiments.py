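"""Benchmark drivers: epsilon sweep, data-size sweep, multi-environment
comparison, and transfer learning.

Each driver simulates genotypes and synthetic phenotype maps, trains the
requested models, and returns a long-format :class:`EvalReport` table with
one row per (model, condition) carrying seeds and a config hash so runs
are reproducible and paired: genotypes are shared across models within a
condition, and test individuals never enter training or validation.

Default sizes are desk scale — each sweep cell trains in minutes on one
CPU; larger panels are reachable through the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .attention import init_model
from .baselines import (DEFAULT_LAMBDA_GRID, fit_linear, fit_linear_pairwise,
                        predict_linear)
from .genotypes import CrossSimConfig, GenotypeMatrix, simulate_cross_genotypes, split_dataset
from .multienv import MultiEnvGPModel
from .phenotypes import add_noise, evaluate_map, sample_epistasis_spec, sample_multi_env_specs
from .training import EvalReport, TrainConfig, r_squared, train

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_epsilon_sweep", "run_datasize_sweep",
           "run_multienv_comparison", "run_transfer", "temperature_kernel",
           "simulate_panel"]


@dataclass
class ExperimentConfig:
    """Serializable settings shared by the experiment drivers."""

    kind: str = "epsilon_sweep"
    n_individuals: int = 20_000
    n_causal: int = 20
    epsilon: float = 0.3
    epsilon_grid: list[float] = field(default_factory=lambda: [0.0, 0.5, 1.0])
    n_grid: list[int] = field(default_factory=lambda: [1_000, 5_000, 20_000])
    n_new_grid: list[int] = field(default_factory=lambda: [1, 10, 100, 1_000])
    models: list[str] = field(default_factory=lambda: ["linear", "pairwise", "attention"])
    d: int = 12
    n_layers: int = 3
    noise_frac: float = 0.2
    recomb_prob: float = 0.5
    loci_per_chromosome: int = 1
    env_labels: list[str] = field(default_factory=list)
    temperatures: list[float] = field(default_factory=list)
    kernel_tau: float = 20.0
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def simulate_panel(n_individuals: int, n_loci: int, seed: int,
                   recomb_prob: float = 0.5,
                   loci_per_chromosome: int = 1) -> GenotypeMatrix:
    """Simulated genotype panel for benchmarks.

    The default (one locus per chromosome, i.e. independent loci) emulates
    a panel already pruned to near-independent markers.
    """
    if n_loci % loci_per_chromosome:
        raise ValueError("n_loci must be divisible by loci_per_chromosome")
    cfg = CrossSimConfig(n_individuals, n_loci // loci_per_chromosome,
                         loci_per_chromosome, recomb_prob, seed)
    return simulate_cross_genotypes(cfg)


def _seed_ladder(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _fit_and_score(model_name: str, G: GenotypeMatrix, y: np.ndarray, splits,
                   cfg: ExperimentConfig, seed: int) -> float:
    """Train one model on the split and return its test R^2."""
    X = G.values
    tr, va, te = splits.train, splits.val, splits.test
    if model_name == "linear":
        m = fit_linear(G.subset_individuals(tr), y[tr], DEFAULT_LAMBDA_GRID,
                       G_val=G.subset_individuals(va), y_val=y[va])
        pred = predict_linear(m, G.subset_individuals(te))
    elif model_name == "pairwise":
        m = fit_linear_pairwise(G.subset_individuals(tr), y[tr],
                                DEFAULT_LAMBDA_GRID,
                                G_val=G.subset_individuals(va), y_val=y[va])
        pred = predict_linear(m, G.subset_individuals(te))
    elif model_name == "attention":
        tc = TrainConfig(**{**asdict(cfg.train), "seed": seed})
        # standardize the target on training statistics so the loss scale
        # (and hence the learning rate) is comparable across maps
        mu, sd = float(y[tr].mean()), float(y[tr].std())
        if sd == 0.0:
            raise ValueError("training phenotypes are constant")
        ys = ((y - mu) / sd).astype(np.float32)
        m = init_model(G.n_loci, cfg.d, cfg.n_layers, seed=seed,
                       dtype=np.float32)
        m, _ = train(m, (X[tr], ys[tr]), (X[va], ys[va]), tc)
        pred = m.predict(X[te]).astype(float) * sd + mu
    else:
        raise ValueError(f"unknown model {model_name!r}")
    return r_squared(y[te], pred)


def run_epsilon_sweep(cfg: ExperimentConfig) -> EvalReport:
    """Test R^2 of each model as a function of the epistasis weight.

    Genotypes are simulated once and shared; a fresh synthetic map is drawn
    per epsilon from a fixed seed ladder.
    """
    report = EvalReport()
    chash = cfg.config_hash()
    G = simulate_panel(cfg.n_individuals, cfg.n_causal, cfg.seed,
                       recomb_prob=cfg.recomb_prob,
                       loci_per_chromosome=cfg.loci_per_chromosome)
    seeds = _seed_ladder(cfg.seed, len(cfg.epsilon_grid))
    splits = split_dataset(cfg.n_individuals, seed=cfg.seed)
    for eps, s in zip(cfg.epsilon_grid, seeds):
        spec = sample_epistasis_spec(G.locus_ids, cfg.n_causal, eps, seed=s,
                                     noise_frac=cfg.noise_frac)
        y = add_noise(evaluate_map(spec, G), cfg.noise_frac, seed=s).observed_values
        for model_name in cfg.models:
            try:
                r2 = _fit_and_score(model_name, G, y, splits, cfg, s)
                report.add_row(model=model_name, epsilon=eps, test_r2=r2,
                               n_train=len(splits.train), d=cfg.d, seed=s,
                               config_hash=chash, error="")
            except Exception as exc:  # record and continue the sweep
                logger.exception("run failed: %s at eps=%s", model_name, eps)
                report.add_row(model=model_name, epsilon=eps, test_r2=np.nan,
                               n_train=len(splits.train), d=cfg.d, seed=s,
                               config_hash=chash, error=str(exc))
    return report


def run_datasize_sweep(cfg: ExperimentConfig) -> EvalReport:
    """Test R^2 at fixed epsilon for nested training-set sizes.

    Smaller training sets are prefixes of larger ones; validation and test
    sets are fixed at the maximum size.
    """
    if sorted(cfg.n_grid) != list(cfg.n_grid):
        raise ValueError("n_grid must be ascending")
    report = EvalReport()
    chash = cfg.config_hash()
    n_max = cfg.n_grid[-1]
    # simulate enough individuals that the largest grid point fills the train split
    n_total = int(np.ceil(n_max / (0.85 * 0.85)))
    G = simulate_panel(n_total, cfg.n_causal, cfg.seed,
                       recomb_prob=cfg.recomb_prob,
                       loci_per_chromosome=cfg.loci_per_chromosome)
    s = _seed_ladder(cfg.seed, 1)[0]
    spec = sample_epistasis_spec(G.locus_ids, cfg.n_causal, cfg.epsilon, seed=s,
                                 noise_frac=cfg.noise_frac)
    y = add_noise(evaluate_map(spec, G), cfg.noise_frac, seed=s).observed_values
    splits = split_dataset(n_total, seed=cfg.seed)
    for n_sub in cfg.n_grid:
        if n_sub > len(splits.train):
            raise ValueError(f"n_grid point {n_sub} exceeds train split size")
        sub = type(splits)(train=splits.train[:n_sub], val=splits.val,
                           test=splits.test)
        for model_name in cfg.models:
            r2 = _fit_and_score(model_name, G, y, sub, cfg, s)
            report.add_row(model=model_name, epsilon=cfg.epsilon, n_train=n_sub,
                           test_r2=r2, d=cfg.d, seed=s, config_hash=chash)
    return report


def temperature_kernel(temperatures: list[float], tau: float) -> np.ndarray:
    """Exponential correlation kernel exp(-|T_a - T_b| / tau) over
    temperature-labelled environments."""
    T = np.asarray(temperatures, dtype=float)
    return np.exp(-np.abs(T[:, None] - T[None, :]) / tau)


def _multi_env_datasets(cfg: ExperimentConfig, env_correlation: np.ndarray):
    """Shared genotypes plus per-environment phenotypes and splits."""
    env_labels = cfg.env_labels or [f"T{t:g}" for t in cfg.temperatures]
    G = simulate_panel(cfg.n_individuals, cfg.n_causal, cfg.seed,
                       recomb_prob=cfg.recomb_prob,
                       loci_per_chromosome=cfg.loci_per_chromosome)
    specs = sample_multi_env_specs(env_labels, G.locus_ids, cfg.n_causal,
                                   cfg.epsilon, env_correlation, seed=cfg.seed,
                                   noise_frac=cfg.noise_frac)
    seeds = _seed_ladder(cfg.seed + 1, len(env_labels))
    ys = {}
    splits = {}
    for a, (label, spec) in enumerate(zip(env_labels, specs)):
        ys[label] = add_noise(evaluate_map(spec, G), cfg.noise_frac,
                              seed=seeds[a], environment_label=label).observed_values
        splits[label] = split_dataset(cfg.n_individuals, seed=seeds[a])
    return env_labels, G, specs, ys, splits


def _pool_env_records(G, ys, splits, env_labels, take_train: dict[str, int]):
    """Pool (X, alpha, y) training and validation records across envs.

    ``take_train[label]`` limits how many training records of that
    environment are included (-1 = all).
    """
    Xtr, atr, ytr, Xva, ava, yva = [], [], [], [], [], []
    for a, label in enumerate(env_labels):
        k = take_train.get(label, -1)
        tr = splits[label].train if k < 0 else splits[label].train[:k]
        va = splits[label].val
        if len(tr):
            Xtr.append(G.values[tr]); atr.append(np.full(len(tr), a)); ytr.append(ys[label][tr])
        Xva.append(G.values[va]); ava.append(np.full(len(va), a)); yva.append(ys[label][va])
    cat = lambda parts: np.concatenate(parts) if parts else np.empty((0,))
    return (cat(Xtr), cat(atr), cat(ytr)), (cat(Xva), cat(ava), cat(yva))


def run_multienv_comparison(cfg: ExperimentConfig,
                            env_correlation: np.ndarray | None = None) -> EvalReport:
    """Per environment: single-env linear, pairwise and attention models,
    plus one jointly trained multi-environment attention model."""
    if env_correlation is None:
        env_correlation = temperature_kernel(cfg.temperatures, cfg.kernel_tau)
    env_labels, G, specs, ys, splits = _multi_env_datasets(cfg, env_correlation)
    report = EvalReport()
    chash = cfg.config_hash()
    for label in env_labels:
        for model_name in cfg.models:
            r2 = _fit_and_score(model_name, G, ys[label], splits[label], cfg,
                                cfg.seed)
            report.add_row(model=model_name, environment=label, test_r2=r2,
                           n_train=len(splits[label].train), d=cfg.d,
                           seed=cfg.seed, config_hash=chash)
    # joint model, trained on the standardized pooled target
    me = MultiEnvGPModel(G.n_loci, cfg.d, env_labels, cfg.n_layers,
                         seed=cfg.seed, dtype=np.float32)
    train_rec, val_rec = _pool_env_records(G, ys, splits, env_labels, {})
    tc = TrainConfig(**{**asdict(cfg.train), "seed": cfg.seed})
    mu, sd = float(train_rec[2].mean()), float(train_rec[2].std())
    scale = lambda rec: (rec[0], rec[1],
                         ((rec[2] - mu) / sd).astype(np.float32))
    me, _ = train(me, scale(train_rec), scale(val_rec), tc)
    for a, label in enumerate(env_labels):
        te = splits[label].test
        pred = me.predict(G.values[te], np.full(len(te), a)).astype(float) * sd + mu
        report.add_row(model="multienv_attention", environment=label,
                       test_r2=r_squared(ys[label][te], pred),
                       n_train=len(train_rec[2]), d=cfg.d, seed=cfg.seed,
                       config_hash=chash)
    return report


def run_transfer(cfg: ExperimentConfig, held_env: str | None = None,
                 env_correlation: np.ndarray | None = None,
                 baseline_models: tuple[str, ...] = ("linear",)) -> EvalReport:
    """Transfer learning to a data-poor environment.

    The joint model trains on all training data of the other environments
    plus ``n_new`` records from the held environment (grid over n_new);
    test R^2 is always measured in the held environment.  Single-env
    baselines are fit on only the n_new records for comparison.
    """
    if env_correlation is None:
        env_correlation = temperature_kernel(cfg.temperatures, cfg.kernel_tau)
    env_labels, G, specs, ys, splits = _multi_env_datasets(cfg, env_correlation)
    if held_env is None:
        held_env = env_labels[-1]
    if held_env not in env_labels:
        raise ValueError(f"held environment {held_env!r} not in {env_labels}")
    if len(env_labels) < 2:
        raise ValueError("transfer needs at least 2 environments")
    report = EvalReport()
    chash = cfg.config_hash()
    a_held = env_labels.index(held_env)
    te = splits[held_env].test
    y_te = ys[held_env][te]
    for n_new in cfg.n_new_grid:
        me = MultiEnvGPModel(G.n_loci, cfg.d, env_labels, cfg.n_layers,
                             seed=cfg.seed, dtype=np.float32)
        train_rec, val_rec = _pool_env_records(G, ys, splits, env_labels,
                                               {held_env: n_new})
        tc = TrainConfig(**{**asdict(cfg.train), "seed": cfg.seed})
        mu, sd = float(train_rec[2].mean()), float(train_rec[2].std())
        scale = lambda rec: (rec[0], rec[1],
                             ((rec[2] - mu) / sd).astype(np.float32))
        me, _ = train(me, scale(train_rec), scale(val_rec), tc)
        pred = me.predict(G.values[te], np.full(len(te), a_held)).astype(float) * sd + mu
        report.add_row(model="multienv_attention", environment=held_env,
                       n_new=n_new, test_r2=r_squared(y_te, pred),
                       zero_shot=(n_new == 0), d=cfg.d, seed=cfg.seed,
                       config_hash=chash)
        # single-env baselines on only the n_new records
        for model_name in baseline_models:
            if n_new < 3:
                report.add_row(model=f"singleenv_{model_name}",
                               environment=held_env, n_new=n_new,
                               test_r2=np.nan, zero_shot=(n_new == 0),
                               d=cfg.d, seed=cfg.seed, config_hash=chash)
                continue
            tr = splits[held_env].train[:n_new]
            sub = type(splits[held_env])(
                train=tr[:max(1, int(len(tr) * 0.85))],
                val=tr[max(1, int(len(tr) * 0.85)):] if len(tr) > 3 else tr[-1:],
                test=te)
            r2 = _fit_and_score(model_name, G, ys[held_env], sub, cfg, cfg.seed)
            report.add_row(model=f"singleenv_{model_name}", environment=held_env,
                           n_new=n_new, test_r2=r2, zero_shot=False, d=cfg.d,
                           seed=cfg.seed, config_hash=chash)
    return report
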