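#!/usr/bin/env python
"""Structural sign analysis of the ten published replicate equations.

Labels every predictor in each equation (positive / negative / mixed /
absent) and tabulates the cross-replicate counts that summarise the
consensus: temperature and the density gradient act negatively in most
replicates, fucoxanthin positively, day of year not at all.
"""

from pathlib import Path

import pandas as pd

from gyretrend.expressions import (FEATURE_COLUMNS, fixture_equations,
                                   sign_table)

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    eqs = fixture_equations()
    rows = []
    for i, eq in enumerate(eqs, start=1):
        labels = sign_table(eq)
        rows.append({"equation": i,
                     **{FEATURE_COLUMNS[j - 1]: labels[j] for j in labels}})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "sign_table.csv", index=False)

    counts = []
    for j, name in enumerate(FEATURE_COLUMNS, start=1):
        col = table[name]
        counts.append({"variable": f"x{j}", "name": name,
                       "negative": int((col == "negative").sum()),
                       "positive": int((col == "positive").sum()),
                       "mixed": int((col == "mixed").sum()),
                       "absent": int((col == "absent").sum())})
    summary = pd.DataFrame(counts)
    summary.to_csv(OUT / "sign_counts.csv", index=False)

    print(summary.to_string(index=False))
    temp = summary[summary["name"] == "temp"].iloc[0]
    dgrad = summary[summary["name"] == "dgrad"].iloc[0]
    print(f"\ntemperature negative in {temp['negative']}/10 equations; "
          f"density gradient negative in {dgrad['negative']}/10")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
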