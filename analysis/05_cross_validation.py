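#!/usr/bin/env python
"""10-fold cross-validation of the model families on the synthetic record.

Compares ordinary least squares, the small back-propagation network, and
desk-scale GP under the same 10-fold split; writes per-model fold reports
and a comparison table under results/validation/.
"""

from pathlib import Path

import pandas as pd

from gyretrend import dataset
from gyretrend.evaluation import MLPConfig, cross_validate, mlp_train, ols_fit
from gyretrend.gp import GPConfig, evolve
from gyretrend.sensitivity import ExpressionModel

ROOT = Path(__file__).resolve().parents[1] / "results"

GP_CONFIG = GPConfig(population_size=300, generations=150, seed=1)


def main() -> None:
    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    features = dataset.read_feature_csv(ROOT / "synthetic" / "features.csv")
    table, _ = dataset.complete_cases(
        features, columns=[*dataset.FEATURE_TABLE_COLUMNS])

    trainers = {
        "ols": lambda t: ols_fit(t),
        "mlp": lambda t: mlp_train(t, MLPConfig(seed=1)),
        "gp": lambda t: ExpressionModel(evolve(t, GP_CONFIG).best),
    }
    rows = []
    for name, trainer in trainers.items():
        report = cross_validate(trainer, table, k=10, seed=1)
        report.to_frame().to_csv(out / f"cv_{name}.csv", index=False)
        rows.append({"model": name, "pooled_r": report.pooled_r,
                     "pooled_error_pct": report.pooled_error_pct,
                     "mean_fold_r": report.mean_fold_r,
                     "mean_fold_error_pct": report.mean_fold_error_pct})
        print(f"{name:>4}: pooled r={report.pooled_r:.3f} "
              f"error={report.pooled_error_pct:.1f}%")
    pd.DataFrame(rows).to_csv(out / "comparison.csv", index=False)
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
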