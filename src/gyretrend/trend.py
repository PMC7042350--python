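"""Nonparametric trend detection for seasonal environmental series.

Implements the Mann-Kendall test, the Sen (median-of-pairwise) slope, the
Seasonal Kendall test (Mann-Kendall applied within each calendar month and
summed, which removes the seasonal cycle by construction), and a rolling
10-year windowed scan of the seasonal test.

Conventions
-----------
* Variance of S is tie-corrected:
  ``var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18``.
* Z uses the continuity correction: ``(S-1)/sqrt(var)`` for S > 0, 0 for
  S = 0, ``(S+1)/sqrt(var)`` for S < 0; two-sided normal p-value.
* The seasonal statistic sums the twelve monthly S and var(S) with no
  cross-season covariance term (the plain form of the test); the seasonal
  Sen slope is the median of all within-month pairwise slopes in units per
  year.
* Significance is conventionally read at the 0.001 / 0.01 / 0.05 tiers; see
  :func:`significance_tier`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import MonthlySeries

__all__ = [
    "TrendResult",
    "RollingTrendResult",
    "mann_kendall",
    "sen_slope",
    "seasonal_kendall",
    "rolling_seasonal_kendall",
    "significance_tier",
]


@dataclass
class TrendResult:
    """Kendall statistic bundle for one series (or one window).

    ``s`` is the signed concordant-discordant pair count, ``var_s`` its
    tie-corrected variance, ``z`` the continuity-corrected normal deviate,
    ``p`` the two-sided p-value, ``sen_slope`` the median pairwise slope in
    variable units per time unit, and ``n_used`` the number of non-missing
    values.  ``all_tied`` flags a fully tied series (p reported as 1).
    """

    s: int
    var_s: float
    z: float
    p: float
    sen_slope: float
    n_used: int
    all_tied: bool = False


@dataclass
class RollingTrendResult:
    window_start_year: int
    window_end_year: int
    result: TrendResult | None
    skipped_reason: str | None = None


def significance_tier(p: float) -> str:
    """Conventional reporting tier for a p-value."""
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "n.s."


def _s_and_var(x: np.ndarray) -> tuple[int, float]:
    """Kendall S and tie-corrected variance for a 1-D array (no NaN)."""
    n = x.size
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var_s)


def _z_from_s(s: int, var_s: float) -> float:
    if var_s <= 0:
        return 0.0
    if s > 0:
        return (s - 1) / np.sqrt(var_s)
    if s < 0:
        return (s + 1) / np.sqrt(var_s)
    return 0.0


def _pairwise_slopes(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(x.size, k=1)
    dt = t[j] - t[i]
    keep = dt != 0
    return (x[j] - x[i])[keep] / dt[keep]


def sen_slope(times, values) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(t_j - t_i), i < j.

    ``times`` are in years if a per-year slope is wanted.  Pairs with equal
    times are skipped.  A constant series has slope 0.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x) & np.isfinite(t)
    t, x = t[mask], x[mask]
    if x.size < 2:
        raise ValueError("sen_slope needs at least two values")
    slopes = _pairwise_slopes(t, x)
    if slopes.size == 0:
        raise ValueError("no pairs with distinct times")
    return float(np.median(slopes))


def mann_kendall(values, times=None) -> TrendResult:
    """Mann-Kendall trend test on an ordered sequence (NaN = missing).

    ``times`` defaults to the 0-based observation index; supply times in
    years to obtain a per-year Sen slope.
    """
    x = np.asarray(values, dtype=float)
    t = (np.arange(x.size, dtype=float) if times is None
         else np.asarray(times, dtype=float))
    mask = np.isfinite(x)
    x, t = x[mask], t[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"mann_kendall needs >= 3 non-missing values, got {n}")
    s, var_s = _s_and_var(x)
    if var_s == 0:  # all values tied
        return TrendResult(s=0, var_s=0.0, z=0.0, p=1.0, sen_slope=0.0,
                           n_used=n, all_tied=True)
    z = _z_from_s(s, var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(s=s, var_s=var_s, z=float(z), p=float(p),
                       sen_slope=sen_slope(t, x), n_used=n)


def seasonal_kendall(series: MonthlySeries) -> TrendResult:
    """Seasonal Kendall test of a monthly series.

    S and var(S) are summed over the twelve calendar-month sub-series
    (months contribute once they hold >= 2 non-missing values; at least one
    month must hold >= 3).  The slope is the median of within-month pairwise
    slopes, in units per year.
    """
    s_total = 0
    var_total = 0.0
    slopes = []
    n_used = 0
    max_month_n = 0
    for m in range(1, 13):
        years, vals = series.month_values(m)
        mask = np.isfinite(vals)
        x = vals[mask]
        t = years[mask].astype(float)
        max_month_n = max(max_month_n, x.size)
        if x.size < 2:
            continue
        s_m, var_m = _s_and_var(x)
        s_total += s_m
        var_total += var_m
        slopes.append(_pairwise_slopes(t, x))
        n_used += x.size
    if max_month_n < 3:
        raise ValueError("seasonal_kendall needs >= 3 years of data in at "
                         "least one calendar month")
    all_slopes = np.concatenate(slopes) if slopes else np.array([])
    if var_total == 0:
        return TrendResult(s=0, var_s=0.0, z=0.0, p=1.0, sen_slope=0.0,
                           n_used=n_used, all_tied=True)
    z = _z_from_s(s_total, var_total)
    p = 2.0 * stats.norm.sf(abs(z))
    slope = float(np.median(all_slopes)) if all_slopes.size else 0.0
    return TrendResult(s=s_total, var_s=var_total, z=float(z), p=float(p),
                       sen_slope=slope, n_used=n_used)


def rolling_seasonal_kendall(series: MonthlySeries, width_years: int = 10,
                             min_fraction: float = 0.5,
                             ) -> list[RollingTrendResult]:
    """Seasonal Kendall test in rolling windows of ``width_years``,
    advancing one year at a time.

    A window whose non-missing fraction of months falls below
    ``min_fraction`` is emitted as skipped with a reason rather than
    silently dropped.
    """
    if width_years < 2:
        raise ValueError("window width must be >= 2 years")
    y0, y1 = int(series.years.min()), int(series.years.max())
    n_years = y1 - y0 + 1
    if width_years > n_years:
        raise ValueError(f"window ({width_years} y) exceeds series span ({n_years} y)")
    out: list[RollingTrendResult] = []
    for start in range(y0, y1 - width_years + 2):
        end = start + width_years - 1
        sel = (series.years >= start) & (series.years <= end)
        sub = MonthlySeries(series.years[sel], series.months[sel],
                            series.values[sel])
        frac = float(np.isfinite(sub.values).mean())
        if frac < min_fraction:
            out.append(RollingTrendResult(start, end, None,
                                          f"only {frac:.0%} of months present "
                                          f"(< {min_fraction:.0%})"))
            continue
        try:
            res = seasonal_kendall(sub)
        except ValueError as exc:
            out.append(RollingTrendResult(start, end, None, str(exc)))
            continue
        out.append(RollingTrendResult(start, end, res))
    return out
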