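"""Model validation: k-fold cross-validation, skill metrics, and two
self-contained baselines (ordinary least squares; a small back-propagation
network).

Skill is reported the way the study's comparison table reads: Pearson r
between observed and predicted NPP, and the *relative* absolute error in
percent, ``100 * sum|pred - obs| / sum|obs - mean(obs)|`` — the
normalisation under which "predict the mean" scores 100% and errors above
100% are possible.  The raw-unit mean absolute error is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expressions import FEATURE_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "CVReport",
    "FoldResult",
    "MLPConfig",
    "kfold_split",
    "cross_validate",
    "pearson_r",
    "relative_mae",
    "ols_fit",
    "LinearModel",
    "mlp_train",
    "MLPModel",
]


def pearson_r(predictions, observations) -> float:
    """Product-moment correlation; errors out if either vector is constant."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError("prediction/observation length mismatch")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(p, o)[0, 1])


def relative_mae(predictions, observations) -> float:
    """Relative absolute error in percent:
    ``100 * sum|pred - obs| / sum|obs - mean(obs)|``."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    denom = np.sum(np.abs(o - o.mean()))
    if denom == 0:
        raise ValueError("relative error undefined: constant observations")
    return float(100.0 * np.sum(np.abs(p - o)) / denom)


def kfold_split(n_rows: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """k disjoint index groups of size floor(n/k) or ceil(n/k), from a
    seeded random permutation; deterministic."""
    if k < 2 or k > n_rows:
        raise ValueError(f"k must lie in 2..n_rows, got k={k}, n={n_rows}")
    perm = np.random.default_rng(seed).permutation(n_rows)
    return [np.sort(g) for g in np.array_split(perm, k)]


@dataclass
class FoldResult:
    fold: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    model_text: str
    r: float | None
    error_pct: float | None
    failed: bool = False
    failure: str | None = None


@dataclass
class CVReport:
    """Per-fold and pooled skill.  Pooled metrics are computed on the
    concatenated held-out predictions (every row predicted exactly once)."""

    k: int
    folds: list[FoldResult]
    pooled_predictions: np.ndarray
    pooled_observations: np.ndarray
    pooled_r: float
    pooled_error_pct: float
    pooled_mae: float
    mean_fold_r: float
    mean_fold_error_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"fold": f.fold, "n_test": f.test_ids.size, "r": f.r,
              "error_pct": f.error_pct, "failed": f.failed,
              "model": f.model_text} for f in self.folds])


def cross_validate(trainer, table: pd.DataFrame, k: int = 10,
                   seed: int = 0) -> CVReport:
    """k-fold cross-validation of ``trainer`` on a complete-case table.

    ``trainer(train_table)`` must return a model with
    ``predict(table) -> ndarray``; each fold is fitted on the other k-1
    groups and evaluated on the held-out group, the per-fold score is
    retained and the model discarded.  A failing fold is recorded as such;
    if at least half the folds fail, the whole validation errors out.
    """
    n = len(table)
    if n < 2 * k and k != n:  # leave-one-out (k == n) is allowed
        raise ValueError(f"need n >= 2k rows (n={n}, k={k})")
    groups = kfold_split(n, k, seed)
    table = table.reset_index(drop=True)
    y = table["npp"].to_numpy(dtype=float)

    folds: list[FoldResult] = []
    pooled_pred = np.full(n, np.nan)
    n_failed = 0
    for fold_no, test_ids in enumerate(groups, start=1):
        train_ids = np.setdiff1d(np.arange(n), test_ids)
        try:
            model = trainer(table.iloc[train_ids])
            pred = np.asarray(model.predict(table.iloc[test_ids]), dtype=float)
            if pred.shape != (test_ids.size,) or not np.all(np.isfinite(pred)):
                raise ValueError("trainer returned non-finite or misshapen predictions")
        except Exception as exc:  # noqa: BLE001 - fold failure is data, not fatal
            n_failed += 1
            folds.append(FoldResult(fold_no, train_ids, test_ids, "", None,
                                    None, failed=True, failure=str(exc)))
            continue
        pooled_pred[test_ids] = pred
        obs = y[test_ids]
        try:
            r = pearson_r(pred, obs)
        except ValueError:
            r = None
        try:
            err = relative_mae(pred, obs)
        except ValueError:
            err = None
        folds.append(FoldResult(fold_no, train_ids, test_ids,
                                getattr(model, "text", repr(model)), r, err))
    if n_failed * 2 >= k:
        raise RuntimeError(f"{n_failed}/{k} folds failed")
    if n_failed:
        log.warning("%d/%d folds failed; pooled metrics use the rest",
                    n_failed, k)

    ok = np.isfinite(pooled_pred)
    pooled_r = pearson_r(pooled_pred[ok], y[ok])
    pooled_err = relative_mae(pooled_pred[ok], y[ok])
    pooled_mae = float(np.mean(np.abs(pooled_pred[ok] - y[ok])))
    fold_rs = [f.r for f in folds if f.r is not None]
    fold_errs = [f.error_pct for f in folds if f.error_pct is not None]
    return CVReport(k=k, folds=folds, pooled_predictions=pooled_pred,
                    pooled_observations=y, pooled_r=pooled_r,
                    pooled_error_pct=pooled_err, pooled_mae=pooled_mae,
                    mean_fold_r=float(np.mean(fold_rs)) if fold_rs else float("nan"),
                    mean_fold_error_pct=(float(np.mean(fold_errs))
                                         if fold_errs else float("nan")))


# ---------------------------------------------------------------------------
# Ordinary least squares baseline
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    predictors: list[str]
    intercept: float
    coefficients: dict[str, float]
    ridge_fallback: bool = False

    @property
    def text(self) -> str:
        terms = [f"{self.intercept:.6g}"]
        for name, c in self.coefficients.items():
            terms.append(f"{c:+.6g}*{name}")
        return " ".join(terms)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.predictors].to_numpy(dtype=float)
        beta = np.array([self.coefficients[p] for p in self.predictors])
        return self.intercept + X @ beta


def ols_fit(table: pd.DataFrame, predictors=None,
            response: str = "npp") -> LinearModel:
    """Least squares via the normal equations, with a small-ridge fallback
    (lambda = 1e-8, scaled to the design) when the design is rank deficient
    — duplicated predictors then log a warning instead of failing."""
    predictors = list(predictors) if predictors is not None else list(FEATURE_COLUMNS)
    X = table[predictors].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    A = np.column_stack([np.ones(len(table)), X])
    ridge = False
    G = A.T @ A
    if np.linalg.matrix_rank(A) < A.shape[1]:
        ridge = True
        log.warning("rank-deficient design; engaging ridge fallback (1e-8)")
        lam = 1e-8 * np.trace(G) / A.shape[1]
        beta = np.linalg.solve(G + lam * np.eye(A.shape[1]), A.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(predictors, float(beta[0]),
                       dict(zip(predictors, map(float, beta[1:]))),
                       ridge_fallback=ridge)


# ---------------------------------------------------------------------------
# Small back-propagation network baseline
# ---------------------------------------------------------------------------

@dataclass
class MLPConfig:
    """One sigmoid hidden layer of 3 neurons by default — the topology the
    pruning/growing selection arrived at in the study — with input width
    following the data (12 predictors)."""

    hidden_layers: tuple[int, ...] = (3,)
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 2000
    patience: int = 50
    validation_fraction: float = 0.2
    weight_init_range: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not self.hidden_layers or min(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden unit")


@dataclass
class MLPModel:
    predictors: list[str]
    weights: list[np.ndarray]       # per layer, shape (n_in+1, n_out), bias row last
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    epochs_trained: int = 0

    text: str = field(init=False)

    def __post_init__(self) -> None:
        sizes = "-".join(str(w.shape[1]) for w in self.weights[:-1])
        self.text = f"mlp[{len(self.predictors)}-{sizes}-1]"

    def _forward(self, Xz: np.ndarray) -> np.ndarray:
        a = Xz
        for w in self.weights[:-1]:
            a = 1.0 / (1.0 + np.exp(-(np.column_stack([a, np.ones(len(a))]) @ w)))
        out = np.column_stack([a, np.ones(len(a))]) @ self.weights[-1]
        return out[:, 0]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.predictors].to_numpy(dtype=float)
        Xz = (X - self.x_mean) / self.x_sd
        return self._forward(Xz) * self.y_sd + self.y_mean


def mlp_train(table: pd.DataFrame, config: MLPConfig | None = None,
              predictors=None, response: str = "npp") -> MLPModel:
    """Train a feed-forward net (sigmoid hidden units, linear output) by
    full-batch back-propagation with momentum.

    Inputs are standardised with z-scores computed on the training rows
    only.  Training stops when the internal validation error has not
    improved for ``patience`` epochs.  Deterministic given the seed.
    Diverging loss raises with advice to lower the learning rate.
    """
    if config is None:
        config = MLPConfig()
    config.validate()
    predictors = list(predictors) if predictors is not None else list(FEATURE_COLUMNS)
    rng = np.random.default_rng(config.seed)

    X = table[predictors].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
    Xz = (X - x_mean) / x_sd
    yz = (y - y_mean) / y_sd

    n = len(table)
    n_val = max(1, int(round(config.validation_fraction * n))) if n >= 5 else 0
    perm = rng.permutation(n)
    val_ids, train_ids = perm[:n_val], perm[n_val:]
    if train_ids.size == 0:
        train_ids, val_ids = perm, perm[:0]

    sizes = [len(predictors), *config.hidden_layers, 1]
    weights = [rng.uniform(-config.weight_init_range, config.weight_init_range,
                           size=(sizes[i] + 1, sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    velocity = [np.zeros_like(w) for w in weights]

    def forward(Xb):
        acts = [Xb]
        a = Xb
        for w in weights[:-1]:
            a = 1.0 / (1.0 + np.exp(-(np.column_stack([a, np.ones(len(a))]) @ w)))
            acts.append(a)
        out = np.column_stack([a, np.ones(len(a))]) @ weights[-1]
        acts.append(out[:, 0])
        return acts

    def val_error() -> float:
        if val_ids.size == 0:
            acts = forward(Xz[train_ids])
            return float(np.mean((acts[-1] - yz[train_ids]) ** 2))
        acts = forward(Xz[val_ids])
        return float(np.mean((acts[-1] - yz[val_ids]) ** 2))

    best_val = val_error()
    best_weights = [w.copy() for w in weights]
    stall = 0
    epochs = 0
    Xt, yt = Xz[train_ids], yz[train_ids]
    m = len(Xt)
    for epoch in range(config.max_epochs):
        acts = forward(Xt)
        err = acts[-1] - yt
        loss = float(np.mean(err ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); reduce learning_rate")
        delta = (err / m)[:, None]  # dL/d(output), L = mean squared error / 2
        grads: list[np.ndarray] = [None] * len(weights)
        for li in range(len(weights) - 1, -1, -1):
            a_in = np.column_stack([acts[li], np.ones(m)])
            grads[li] = a_in.T @ delta
            if li > 0:
                back = delta @ weights[li][:-1].T
                delta = back * acts[li] * (1.0 - acts[li])
        for li, g in enumerate(grads):
            velocity[li] = config.momentum * velocity[li] - config.learning_rate * g
            weights[li] = weights[li] + velocity[li]
        epochs = epoch + 1
        v = val_error()
        if v < best_val - 1e-12:
            best_val = v
            best_weights = [w.copy() for w in weights]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    return MLPModel(predictors, best_weights, x_mean, x_sd, y_mean, y_sd,
                    epochs_trained=epochs)
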