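"""Training loop, model selection, and evaluation metrics.

Models are trained by minimizing mean squared error with Adam (or plain
gradient descent) over minibatches; early stopping returns the parameter
snapshot with the best validation loss.  Evaluation uses the coefficient
of determination R^2 and Pearson correlation on a held-out test split, and
model effect sizes are measured by in-silico allele flipping: predict with
a locus forced to +1 and to -1 in every genetic background and take the
difference.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import SGD, Adam
from .genotypes import GenotypeMatrix

__all__ = ["TrainConfig", "EvalReport", "EffectSizeTable", "train",
           "select_embedding_dim", "r_squared", "pearson_r",
           "model_effect_sizes"]


@dataclass
class TrainConfig:
    """Hyperparameters for gradient-based training."""

    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    optimizer: str = "adam"
    seed: int = 0
    d_candidates: list[int] | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class EvalReport:
    """Long-format evaluation table, one row per (model, condition)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def add_row(self, **kwargs) -> None:
        self.table = pd.concat([self.table, pd.DataFrame([kwargs])],
                               ignore_index=True)

    def save(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class EffectSizeTable:
    """Per-locus allele-flip effects of a model on a panel of backgrounds.

    ``per_background`` has one column per locus and one row per individual;
    ``averaged`` is its column mean.
    """

    loci: list[str]
    per_background: np.ndarray
    model_name: str = ""

    @property
    def averaged(self) -> np.ndarray:
        return self.per_background.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_background, columns=self.loci)
        df.loc["averaged"] = self.averaged
        return df


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def train(model, train_data: tuple, val_data: tuple, config: TrainConfig):
    """Minibatch MSE training with early stopping on validation loss.

    ``train_data`` and ``val_data`` are tuples whose last element is the
    target vector and whose leading elements are the model's inputs (the
    genotype matrix, plus environment indices for the multi-environment
    model).  Returns the model with the best-validation parameters
    restored and a per-epoch loss history.
    """
    *train_inputs, y_train = (np.asarray(a) for a in train_data)
    *val_inputs, y_val = (np.asarray(a) for a in val_data)
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    opt_cls = Adam if config.optimizer == "adam" else SGD
    opt = opt_cls(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(y_train)
    best_val = np.inf
    best_params = copy.deepcopy(model.params)
    best_epoch = -1
    history = []
    t0 = time.time()
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            loss, grads = model.loss_and_grads(
                *[a[idx] for a in train_inputs], y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}")
            opt.step(grads)
            batch_losses.append(loss)
        val_loss = _mse(model.predict(*val_inputs), y_val)
        history.append({"epoch": epoch, "train_loss": float(np.mean(batch_losses)),
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(model.params)
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    for k in model.params:
        model.params[k][...] = best_params[k]
    hist = pd.DataFrame(history)
    hist.attrs["runtime_s"] = time.time() - t0
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS; may be negative."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0:
        raise ValueError("y_true is constant; R^2 undefined")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / tss


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient; errors on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def model_effect_sizes(model, G: GenotypeMatrix, loci: list[str],
                       predict_fn=None, model_name: str = "") -> EffectSizeTable:
    """In-silico allele-flip effect sizes of a fitted model.

    For every requested locus and every individual, the model predicts the
    phenotype with that allele forced to +1 and to -1 (all other loci
    fixed); the per-background effect is the difference of the two
    predictions.  ``predict_fn`` overrides ``model.predict`` (used, e.g.,
    to bind an environment index for multi-environment models).
    """
    if predict_fn is None:
        from .baselines import LinearGPModel, predict_linear
        if isinstance(model, LinearGPModel):
            predict_fn = lambda X: predict_linear(
                model, GenotypeMatrix(X, G.locus_ids))
        else:
            predict_fn = model.predict
    X = G.values.astype(np.int8)
    deltas = np.empty((G.n_individuals, len(loci)))
    for c, locus in enumerate(loci):
        j = G.locus_index(locus)
        Xp = np.array(X)
        Xp[:, j] = 1
        y_plus = predict_fn(Xp)
        Xp[:, j] = -1
        y_minus = predict_fn(Xp)
        deltas[:, c] = np.asarray(y_plus) - np.asarray(y_minus)
    return EffectSizeTable(list(loci), deltas, model_name)


def select_embedding_dim(d_candidates: list[int], G: GenotypeMatrix,
                         y: np.ndarray, splits, config: TrainConfig,
                         NL: int = 3):
    """Train one attention model per candidate embedding dimension and pick
    the one with the highest validation R^2 (ties go to the smaller d).

    Returns ``(best_d, table)`` where the table logs validation R^2 per
    candidate.
    """
    from .attention import init_model
    if len(d_candidates) < 1:
        raise ValueError("need at least one candidate")
    y = np.asarray(y, dtype=float)
    X = G.values
    rows = []
    best = None
    for d in sorted(d_candidates):
        model = init_model(G.n_loci, d, NL, seed=config.seed)
        model, _ = train(model, (X[splits.train], y[splits.train]),
                         (X[splits.val], y[splits.val]), config)
        r2 = r_squared(y[splits.val], model.predict(X[splits.val]))
        rows.append({"d": d, "val_r2": r2})
        if best is None or r2 > best[1] + 1e-12:
            best = (d, r2)
    return best[0], pd.DataFrame(rows)
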