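"""Per-variable impact analysis of a fitted NPP model.

Realises the five-metric reporting vocabulary of symbolic-regression
tools — Sensitivity, %Positive, Positive Magnitude, %Negative, Negative
Magnitude — as scaled finite-difference derivatives evaluated at the
observed rows:

* ``d_ij`` = central-difference partial derivative of the model with
  respect to variable j at row i, step ``h = max(1e-6, 1e-4 * sd(x_j))``;
* ``sensitivity_j = mean_i |d_ij| * sd(x_j) / sd(yhat)`` (dimensionless;
  for a purely linear model this is exactly ``|c_j| * sd(x_j)/sd(yhat)``);
* ``pct_positive_j`` / ``pct_negative_j`` = percent of rows with positive /
  negative derivative (the remainder is zero-derivative or excluded rows);
* ``positive_magnitude_j`` = mean of ``d_ij * sd(x_j)/sd(yhat)`` over the
  positive rows (0 if none), and symmetrically with ``|d|`` for the
  negative magnitude.

Rows where the probe points evaluate non-finite are excluded and counted.
The fold-level report fits the model on each of k training folds and, by
default, computes the report on that fold's held-out rows, yielding the
"percent of folds in which the variable acts negatively (positively)"
summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expressions import FEATURE_COLUMNS
from .evaluation import kfold_split

__all__ = [
    "SensitivityReport",
    "partial_derivative",
    "sensitivity_report",
    "fold_sign_probability",
    "ExpressionModel",
]


class ExpressionModel:
    """Adapter giving an Expression the trainer-model interface."""

    def __init__(self, expr) -> None:
        from .expressions import to_text
        self.expr = expr
        self.text = to_text(expr)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        from .expressions import evaluate
        X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        return evaluate(self.expr, X)


@dataclass
class SensitivityReport:
    """Five-metric table, one row per variable (x1..x12).

    Columns: variable, name, sensitivity, pct_positive, positive_magnitude,
    pct_negative, negative_magnitude, pct_zero, pct_excluded.
    Invariant: pct_positive + pct_negative + pct_zero + pct_excluded = 100.
    """

    table: pd.DataFrame
    n_rows: int

    def metric(self, variable: int, column: str) -> float:
        return float(self.table.loc[self.table["variable"] == variable,
                                    column].iloc[0])


def _fd_step(x: np.ndarray) -> float:
    return max(1e-6, 1e-4 * float(np.std(x)))


def partial_derivative(model, variable: int, table: pd.DataFrame,
                       h: float | None = None) -> np.ndarray:
    """Central finite-difference derivative of the model with respect to
    variable ``variable`` (1-based), one value per row; non-finite where a
    probe point failed.  Exact for linear terms."""
    if not (1 <= variable <= len(FEATURE_COLUMNS)):
        raise ValueError(f"variable index {variable} outside 1..{len(FEATURE_COLUMNS)}")
    name = FEATURE_COLUMNS[variable - 1]
    if h is None:
        h = _fd_step(table[name].to_numpy(dtype=float))
    hi = table.copy()
    lo = table.copy()
    hi[name] = hi[name] + h
    lo[name] = lo[name] - h
    with np.errstate(all="ignore"):
        up = np.asarray(model.predict(hi), dtype=float)
        dn = np.asarray(model.predict(lo), dtype=float)
    return (up - dn) / (2.0 * h)


def sensitivity_report(model, table: pd.DataFrame,
                       scaled: bool = True) -> SensitivityReport:
    """Five-metric impact report of ``model`` over the rows of ``table``.

    ``scaled=False`` reports raw derivatives (no sd(x)/sd(yhat) scaling).
    Errors out when the model is degenerate (sd of predictions is 0).
    """
    n = len(table)
    if n < 2:
        raise ValueError("sensitivity needs >= 2 rows")
    with np.errstate(all="ignore"):
        yhat = np.asarray(model.predict(table), dtype=float)
    sd_y = float(np.std(yhat[np.isfinite(yhat)]))
    if not np.isfinite(sd_y) or sd_y == 0:
        raise ValueError("degenerate model: predictions have zero variance")

    rows = []
    for j, name in enumerate(FEATURE_COLUMNS, start=1):
        d = partial_derivative(model, j, table)
        finite = np.isfinite(d)
        scale = (float(np.std(table[name].to_numpy(dtype=float))) / sd_y
                 if scaled else 1.0)
        df = d[finite]
        pos = df > 0
        neg = df < 0
        n_excl = int((~finite).sum())
        rows.append({
            "variable": j,
            "name": name,
            "sensitivity": float(np.mean(np.abs(df)) * scale) if df.size else 0.0,
            "pct_positive": 100.0 * int(pos.sum()) / n,
            "positive_magnitude": (float(np.mean(df[pos]) * scale)
                                   if pos.any() else 0.0),
            "pct_negative": 100.0 * int(neg.sum()) / n,
            "negative_magnitude": (float(np.mean(np.abs(df[neg])) * scale)
                                   if neg.any() else 0.0),
            "pct_zero": 100.0 * int((df == 0).sum()) / n,
            "pct_excluded": 100.0 * n_excl / n,
        })
    return SensitivityReport(pd.DataFrame(rows), n_rows=n)


def dominant_sign(report: SensitivityReport, variable: int) -> str:
    """'negative', 'positive', 'zero', or 'mixed' (tie) for one variable."""
    pp = report.metric(variable, "pct_positive")
    pn = report.metric(variable, "pct_negative")
    if pp == 0 and pn == 0:
        return "zero"
    if pn > pp:
        return "negative"
    if pp > pn:
        return "positive"
    return "mixed"


def fold_sign_probability(trainer, table: pd.DataFrame, k: int = 10,
                          seed: int = 0, on_held_out: bool = True,
                          ) -> pd.DataFrame:
    """Percent of k folds in which each variable's dominant derivative sign
    is negative (positive, zero, mixed).

    The model is refitted on each fold's training rows; the sensitivity
    report is computed on the held-out rows by default (``on_held_out=False``
    uses the training rows instead).
    """
    n = len(table)
    table = table.reset_index(drop=True)
    groups = kfold_split(n, k, seed)
    counts = {j: {"negative": 0, "positive": 0, "zero": 0, "mixed": 0}
              for j in range(1, len(FEATURE_COLUMNS) + 1)}
    for test_ids in groups:
        train_ids = np.setdiff1d(np.arange(n), test_ids)
        model = trainer(table.iloc[train_ids])
        rows = table.iloc[test_ids] if on_held_out else table.iloc[train_ids]
        rep = sensitivity_report(model, rows)
        for j in counts:
            counts[j][dominant_sign(rep, j)] += 1
    out = []
    for j, c in counts.items():
        out.append({"variable": j, "name": FEATURE_COLUMNS[j - 1],
                    "pct_folds_negative": 100.0 * c["negative"] / k,
                    "pct_folds_positive": 100.0 * c["positive"] / k,
                    "pct_folds_zero": 100.0 * c["zero"] / k,
                    "pct_folds_mixed": 100.0 * c["mixed"] / k})
    return pd.DataFrame(out)
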