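"""End-to-end study orchestration.

``run_study`` reproduces the full analysis sequence on one data source
(synthetic record or feature CSV): feature-table construction, full-record
seasonal trend tests per variable, 10-year rolling-window scans, replicate
GP symbolic-regression experiments, 10-fold cross-validation, per-replicate
and aggregate sensitivity reports, and a manifest that makes the run
reproducible (all outputs are pure functions of the manifest).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dataset, synthetic, trend
from .evaluation import cross_validate
from .expressions import FEATURE_COLUMNS
from .gp import GPConfig, evolve, run_replicates
from .sensitivity import ExpressionModel, sensitivity_report

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study"]

TREND_VARIABLES = ("temp", "mld", "dgrad", "no3", "po4", "sio2",
                   "fuco", "chlb", "chla", "lutzea", "npp")


@dataclass
class RunConfig:
    """One study run: exactly one data source (synthetic xor a feature CSV)."""

    output_dir: str | Path = "run"
    synthetic_config: synthetic.SyntheticConfig | None = None
    feature_csv: str | Path | None = None
    window_years: int = 10
    fill_gaps: bool = True
    gp_config: GPConfig = field(default_factory=GPConfig)
    cv_k: int = 10
    cv_seed: int = 0
    sensitivity_scaled: bool = True

    def validate(self) -> None:
        if (self.synthetic_config is None) == (self.feature_csv is None):
            raise ValueError("exactly one data source: synthetic_config xor feature_csv")


def _manifest(config: RunConfig) -> dict:
    m = {
        "version": __version__,
        "window_years": config.window_years,
        "fill_gaps": config.fill_gaps,
        "cv_k": config.cv_k,
        "cv_seed": config.cv_seed,
        "gp_config": dataclasses.asdict(config.gp_config),
        "seeds": {"gp_base": config.gp_config.seed, "cv": config.cv_seed},
    }
    if config.synthetic_config is not None:
        m["data_source"] = {"synthetic": dataclasses.asdict(config.synthetic_config)}
        m["seeds"]["synthetic"] = config.synthetic_config.seed
    else:
        m["data_source"] = {"feature_csv": str(config.feature_csv)}
    return m


def _stage(name: str, t0: float, **info) -> None:
    fields = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, fields)


def run_study(config: RunConfig) -> Path:
    """Run the full study; returns the output directory.

    Outputs: ``features.csv``, ``trends.csv``, ``rolling.csv``,
    ``equations/eq_XX.txt`` (one per replicate), ``gp_summary.csv``,
    ``cv_report.csv``, ``sensitivity_rep_XX.csv``, ``sensitivity_aggregate.csv``,
    ``manifest.yaml`` and ``summary.txt``.  Fully deterministic given the
    config; a stage failure leaves earlier outputs in place and is recorded
    in the manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    manifest["started"] = dt.datetime.now().isoformat(timespec="seconds")
    manifest["failed_stage"] = None
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        manifest["failed_stage"] = f"{manifest.get('_stage')}: {exc}"
        raise
    finally:
        manifest.pop("_stage", None)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    t0 = time.perf_counter()

    manifest["_stage"] = "data"
    if config.synthetic_config is not None:
        casts, truth = synthetic.generate_casts(config.synthetic_config)
        features = dataset.build_feature_table(casts)
        truth.to_yaml(out / "ground_truth.yaml")
        dataset.write_casts_csv(casts, out / "casts.csv", out / "npp.csv")
    else:
        features = dataset.read_feature_csv(config.feature_csv)
    dataset.write_feature_csv(features, out / "features.csv")
    _stage("data", t0, rows=len(features))

    manifest["_stage"] = "trends"
    trend_rows, rolling_rows = [], []
    for var in TREND_VARIABLES:
        if var not in features.columns:
            continue
        series = dataset.monthly_aggregate(features, var)
        if config.fill_gaps:
            series = dataset.fill_gaps_month_means(series)
        try:
            res = trend.seasonal_kendall(series)
        except ValueError as exc:
            log.warning("trend %s skipped: %s", var, exc)
            continue
        trend_rows.append({"variable": var, "s": res.s, "var_s": res.var_s,
                           "z": res.z, "p": res.p,
                           "tier": trend.significance_tier(res.p),
                           "sen_slope_per_year": res.sen_slope,
                           "n_used": res.n_used})
        for w in trend.rolling_seasonal_kendall(series, config.window_years):
            row = {"variable": var, "window_start_year": w.window_start_year,
                   "window_end_year": w.window_end_year,
                   "skipped_reason": w.skipped_reason}
            if w.result is not None:
                row.update({"s": w.result.s, "z": w.result.z, "p": w.result.p,
                            "tier": trend.significance_tier(w.result.p),
                            "sen_slope_per_year": w.result.sen_slope})
            rolling_rows.append(row)
    pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)
    pd.DataFrame(rolling_rows).to_csv(out / "rolling.csv", index=False)
    _stage("trends", t0, variables=len(trend_rows))

    manifest["_stage"] = "complete_cases"
    table, removal = dataset.complete_cases(
        features, columns=[*FEATURE_COLUMNS, "npp"])
    removal.to_csv(out / "removed_rows.csv", index=False)
    if table.empty:
        raise RuntimeError("no complete-case rows; ML stages cannot run")
    _stage("complete_cases", t0, kept=len(table), removed=len(removal))

    manifest["_stage"] = "gp"
    results, summary = run_replicates(table, config.gp_config)
    eq_dir = out / "equations"
    eq_dir.mkdir(exist_ok=True)
    for i, res in enumerate(results, start=1):
        (eq_dir / f"eq_{i:02d}.txt").write_text(res.text + "\n")
    summary.to_csv(out / "gp_summary.csv", index=False)
    _stage("gp", t0, replicates=len(results))

    manifest["_stage"] = "cv"

    def gp_trainer(train_table: pd.DataFrame):
        res = evolve(train_table, config.gp_config)
        return ExpressionModel(res.best)

    cv = cross_validate(gp_trainer, table, k=config.cv_k, seed=config.cv_seed)
    cv.to_frame().to_csv(out / "cv_report.csv", index=False)
    _stage("cv", t0, pooled_r=round(cv.pooled_r, 3),
           pooled_error_pct=round(cv.pooled_error_pct, 1))

    manifest["_stage"] = "sensitivity"
    agg_frames = []
    for i, res in enumerate(results, start=1):
        rep = sensitivity_report(ExpressionModel(res.best), table,
                                 scaled=config.sensitivity_scaled)
        rep.table.to_csv(out / f"sensitivity_rep_{i:02d}.csv", index=False)
        agg_frames.append(rep.table.assign(replicate=i))
    agg = _aggregate_sensitivity(pd.concat(agg_frames, ignore_index=True))
    agg.to_csv(out / "sensitivity_aggregate.csv", index=False)
    _stage("sensitivity", t0, replicates=len(results))

    manifest["_stage"] = "summary"
    _write_summary(out, trend_rows, summary, cv, agg)
    manifest["_stage"] = None


def _aggregate_sensitivity(frames: pd.DataFrame) -> pd.DataFrame:
    """Across replicates: mean scaled magnitudes; sign by majority of
    per-replicate dominant signs, with disagreements flagged."""
    rows = []
    for (j, name), grp in frames.groupby(["variable", "name"], sort=True):
        dom = np.where(grp["pct_negative"] > grp["pct_positive"], "negative",
                       np.where(grp["pct_positive"] > grp["pct_negative"],
                                "positive", "none"))
        counts = pd.Series(dom).value_counts()
        majority = counts.index[0] if counts.iloc[0] > len(grp) / 2 else "disputed"
        rows.append({
            "variable": j, "name": name,
            "mean_sensitivity": float(grp["sensitivity"].mean()),
            "mean_positive_magnitude": float(grp["positive_magnitude"].mean()),
            "mean_negative_magnitude": float(grp["negative_magnitude"].mean()),
            "majority_sign": majority,
            "n_replicates_negative": int((dom == "negative").sum()),
            "n_replicates_positive": int((dom == "positive").sum()),
            "disagreement": bool(counts.size > 1),
        })
    return pd.DataFrame(rows)


def _write_summary(out: Path, trend_rows, gp_summary: pd.DataFrame,
                   cv, agg: pd.DataFrame) -> None:
    lines = ["study summary", "============="]
    lines.append("\nfull-record seasonal trends (Sen slope per year):")
    for r in trend_rows:
        lines.append(f"  {r['variable']:>7}: slope={r['sen_slope_per_year']:+.4g}"
                     f"  {r['tier']}")
    lines.append("\nGP replicates (r / relative error %):")
    for r in gp_summary.itertuples():
        lines.append(f"  #{r.replicate:02d}: r={r.r:.3f} error={r.error_pct:.1f}%")
    lines.append(f"\n10-fold CV (GP): pooled r={cv.pooled_r:.3f}, "
                 f"pooled error={cv.pooled_error_pct:.1f}%")
    lines.append("\naggregate sensitivity (majority sign, mean magnitude):")
    for r in agg.sort_values("mean_sensitivity", ascending=False).itertuples():
        lines.append(f"  {r.name:>7}: {r.majority_sign:>9} "
                     f"sens={r.mean_sensitivity:.3f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
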