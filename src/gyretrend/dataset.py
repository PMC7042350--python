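"""From depth-resolved casts to analysis variables.

A *cast* is one station visit: a date plus depth profiles of temperature,
density and the chemical/biological variables, and (when measured) the
depth-integrated net primary productivity.  This module turns casts into the
twelve predictors used everywhere downstream:

==== ======== ==============================================================
x1   jday     Julian day (whole days since the series origin)
x2   yday     day of the year (1-366)
x3   mld      mixed-layer depth, m (density-threshold criterion)
x4   dgrad    density gradient: ratio of densities at 20 m and 120 m
x5   temp     mean temperature 0-120 m, deg C
x6   no3      nitrate,   trapezoid-integrated 0-120 m
x7   po4      phosphate, integrated 0-120 m
x8   sio2     silicate,  integrated 0-120 m
x9   fuco     fucoxanthin,        integrated 0-120 m
x10  chlb     chlorophyll b,      integrated 0-120 m
x11  chla     chlorophyll a,      integrated 0-120 m
x12  lutzea   lutein+zeaxanthin,  integrated 0-120 m
y    npp      net primary productivity, integrated 0-120 m, mg C m-2 d-1
==== ======== ==============================================================

Integration is the oceanographic default for bottle profiles: trapezoid over
[0, 120] m with linear interpolation to the interval boundaries and
nearest-sample extension where the profile does not reach a boundary.
Depths are positive downward, in meters.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CastRecord",
    "MonthlySeries",
    "PROFILE_VARIABLES",
    "FEATURE_TABLE_COLUMNS",
    "integrate_profile",
    "mean_temperature",
    "density_gradient",
    "mixed_layer_depth",
    "time_features",
    "monthly_aggregate",
    "fill_gaps_month_means",
    "complete_cases",
    "build_feature_table",
    "write_casts_csv",
    "read_casts_csv",
    "write_feature_csv",
    "read_feature_csv",
]

PROFILE_VARIABLES = ("temp", "dens", "no3", "po4", "sio2",
                     "chla", "chlb", "fuco", "lutzea")

#: Fixed header of the 13-column feature table (plus a leading date column).
FEATURE_TABLE_COLUMNS = ("jday", "yday", "mld", "dgrad", "temp", "no3", "po4",
                         "sio2", "fuco", "chlb", "chla", "lutzea", "npp")

Z_TOP = 0.0
Z_BOT = 120.0
MAX_DEPTH = 200.0


@dataclass
class CastRecord:
    """One station visit: date, depth profiles, and measured integrated NPP.

    ``profiles`` maps variable name -> (depths, values) array pair with
    strictly increasing depths in [0, 200] m (levels below 120 m are kept
    but ignored by the 0-120 m integration).
    """

    date: dt.date
    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    npp: float | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (z, v) in self.profiles.items():
            z = np.asarray(z, dtype=float)
            v = np.asarray(v, dtype=float)
            if z.shape != v.shape or z.ndim != 1:
                raise ValueError(f"profile {name!r}: depths and values must be 1-D and equal length")
            if z.size and (np.any(np.diff(z) <= 0)):
                raise ValueError(f"profile {name!r}: depths must be strictly increasing")
            if z.size and (z[0] < 0 or z[-1] > MAX_DEPTH):
                raise ValueError(f"profile {name!r}: depths must lie in [0, {MAX_DEPTH}] m")
            clean[name] = (z, v)
        self.profiles = clean


def _as_profile(profile) -> tuple[np.ndarray, np.ndarray]:
    """Accept (depths, values) pairs or an Nx2 array."""
    if isinstance(profile, tuple) and len(profile) == 2:
        z, v = profile
    else:
        arr = np.asarray(profile, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("profile must be (depths, values) or an Nx2 array")
        z, v = arr[:, 0], arr[:, 1]
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)
    mask = np.isfinite(v) & np.isfinite(z)
    z, v = z[mask], v[mask]
    if z.size == 0:
        raise ValueError("empty profile")
    order = np.argsort(z)
    return z[order], v[order]


def integrate_profile(profile, z_lo: float = Z_TOP, z_hi: float = Z_BOT) -> float:
    """Trapezoidal integral of a bottle profile over [z_lo, z_hi].

    Boundary values come from linear interpolation between bracketing
    samples; where no sample brackets a boundary the nearest sample value is
    extended (constant).  A single-sample profile integrates as a constant,
    with a logged warning.
    """
    z, v = _as_profile(profile)
    if z_hi <= z_lo:
        raise ValueError("z_hi must exceed z_lo")
    if z.size == 1:
        log.warning("single-sample profile: integrating as constant %.4g", v[0])
        return float(v[0] * (z_hi - z_lo))
    grid = np.unique(np.concatenate([z[(z > z_lo) & (z < z_hi)], [z_lo, z_hi]]))
    vals = np.interp(grid, z, v)  # np.interp clamps: nearest-sample extension
    return float(np.trapezoid(vals, grid))


def mean_temperature(profile, z_lo: float = Z_TOP, z_hi: float = Z_BOT) -> float:
    """Depth-mean of a profile over [z_lo, z_hi] (integral / layer thickness)."""
    return integrate_profile(profile, z_lo, z_hi) / (z_hi - z_lo)


def _interp_at(profile, z: float) -> float:
    zz, vv = _as_profile(profile)
    if zz.size < 2 or z < zz[0] or z > zz[-1]:
        raise ValueError(f"profile does not bracket {z} m")
    return float(np.interp(z, zz, vv))


def density_gradient(profile, z_shallow: float = 20.0, z_deep: float = Z_BOT,
                     orientation: str = "shallow_over_deep") -> float:
    """Stratification index: the ratio of densities at 20 m and 120 m.

    The literal (default) orientation is rho(20)/rho(120), which is < 1 and
    decreases as the column stratifies; ``orientation='deep_over_shallow'``
    returns the inverse.  Both anchor densities are linearly interpolated;
    a profile that cannot bracket either anchor raises ``ValueError`` and the
    record is treated as missing x4 by the feature-table builder.
    """
    rho_s = _interp_at(profile, z_shallow)
    rho_d = _interp_at(profile, z_deep)
    if orientation == "shallow_over_deep":
        return rho_s / rho_d
    if orientation == "deep_over_shallow":
        return rho_d / rho_s
    raise ValueError(f"unknown orientation {orientation!r}")


def mixed_layer_depth(density_profile, threshold: float = 0.125) -> float:
    """Mixed-layer depth by the potential-density threshold criterion.

    The shallowest depth where density exceeds the shallowest sample's by
    ``threshold`` (kg m-3), linearly interpolated within the crossing
    interval; if the excess never occurs the deepest sampled depth is
    returned.  Requires at least two samples, the first at <= 10 m.
    """
    z, rho = _as_profile(density_profile)
    if z.size < 2:
        raise ValueError("mixed-layer depth needs at least two samples")
    if z[0] > 10.0:
        raise ValueError("shallowest density sample must be at <= 10 m")
    if threshold <= 0:
        return float(z[0])
    excess = rho - rho[0]
    above = np.nonzero(excess > threshold)[0]
    if above.size == 0:
        return float(z[-1])
    i = above[0]
    if i == 0:
        return float(z[0])
    # linear crossing within [z[i-1], z[i]]
    frac = (threshold - excess[i - 1]) / (excess[i] - excess[i - 1])
    return float(z[i - 1] + frac * (z[i] - z[i - 1]))


def time_features(date: dt.date, origin: dt.date,
                  periodic: bool = False):
    """Time encodings: x1 = whole days since ``origin`` (origin -> 0) and
    x2 = calendar day of the year (1-366).

    With ``periodic=True`` also returns the seasonal phase pair
    (sin, cos of 2*pi*x2/365.25), the standard encoding when day-of-year is
    wanted as a circular covariate.
    """
    if date < origin:
        raise ValueError(f"date {date} precedes origin {origin}")
    x1 = (date - origin).days
    x2 = date.timetuple().tm_yday
    if not periodic:
        return x1, x2
    ang = 2.0 * math.pi * x2 / 365.25
    return x1, x2, (math.sin(ang), math.cos(ang))


@dataclass
class MonthlySeries:
    """A (year, month) -> value series with at most one entry per month.

    ``values`` uses NaN for missing months.  The series covers the full
    rectangular year x month grid between its first and last year, which is
    what the seasonal trend tests expect.
    """

    years: np.ndarray
    months: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.years.shape == self.months.shape == self.values.shape):
            raise ValueError("years, months, values must be equal length")
        if self.years.size and (self.months.min() < 1 or self.months.max() > 12):
            raise ValueError("months must lie in 1..12")
        keys = list(zip(self.years.tolist(), self.months.tolist()))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (year, month) entry")

    @classmethod
    def from_pairs(cls, pairs) -> "MonthlySeries":
        """Build from an iterable of (year, month, value-or-None) triples,
        expanded onto the full monthly grid."""
        recs = {(int(y), int(m)): (math.nan if v is None else float(v))
                for y, m, v in pairs}
        if not recs:
            raise ValueError("no entries")
        y0 = min(y for y, _ in recs)
        y1 = max(y for y, _ in recs)
        years, months, values = [], [], []
        for y in range(y0, y1 + 1):
            for m in range(1, 13):
                years.append(y)
                months.append(m)
                values.append(recs.get((y, m), math.nan))
        return cls(np.array(years), np.array(months), np.array(values))

    def month_values(self, month: int) -> tuple[np.ndarray, np.ndarray]:
        """(years, values) sub-series for one calendar month, ordered by year."""
        sel = self.months == month
        order = np.argsort(self.years[sel])
        return self.years[sel][order], self.values[sel][order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "month": self.months,
                             "value": self.values})

    def __len__(self) -> int:
        return int(self.values.size)


def monthly_aggregate(records, variable: str | None = None,
                      statistic: str = "mean") -> MonthlySeries:
    """Aggregate cast-level values into one value per (year, month).

    ``records`` may be a DataFrame with a ``date`` column (``variable``
    selects the value column) or an iterable of (date, value) pairs.
    Months with no casts are missing in the result.
    """
    if isinstance(records, pd.DataFrame):
        if variable is None:
            raise ValueError("variable column name required for DataFrame input")
        dates = pd.to_datetime(records["date"])
        vals = pd.to_numeric(records[variable], errors="coerce")
    else:
        pairs = list(records)
        dates = pd.to_datetime([d for d, _ in pairs])
        vals = pd.Series([v for _, v in pairs], dtype=float)
    df = pd.DataFrame({"year": dates.dt.year if hasattr(dates, "dt") else dates.year,
                       "month": dates.dt.month if hasattr(dates, "dt") else dates.month,
                       "value": np.asarray(vals, dtype=float)})
    if statistic == "mean":
        g = df.groupby(["year", "month"])["value"].mean()
    elif statistic == "median":
        g = df.groupby(["year", "month"])["value"].median()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return MonthlySeries.from_pairs((y, m, v) for (y, m), v in g.items())


def fill_gaps_month_means(series: MonthlySeries) -> MonthlySeries:
    """Fill each missing (year, month) with the mean of that calendar month
    across all years; idempotent.  Calendar months missing in every year stay
    missing and are reported with a logged warning."""
    values = series.values.copy()
    never = []
    for m in range(1, 13):
        sel = series.months == m
        obs = series.values[sel]
        if np.all(np.isnan(obs)):
            if np.any(sel):
                never.append(m)
            continue
        clim = np.nanmean(obs)
        gap = sel & np.isnan(values)
        values[gap] = clim
    if never:
        log.warning("months with no observations in any year remain missing: %s", never)
    return MonthlySeries(series.years.copy(), series.months.copy(), values)


def complete_cases(table: pd.DataFrame,
                   columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with any missing value (among ``columns``, default all).

    Returns the surviving rows (values untouched) and a removal log listing,
    per dropped row, which columns were missing.  An empty result logs a
    warning; downstream model fitting refuses empty tables on its own.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    missing = table[cols].isna()
    bad = missing.any(axis=1)
    removal_log = pd.DataFrame({
        "row": table.index[bad],
        "missing_columns": [",".join(missing.columns[m]) for m in
                            missing[bad].to_numpy()],
    })
    kept = table.loc[~bad].copy()
    if kept.empty:
        log.warning("complete-case filter removed every row")
    return kept, removal_log


# ---------------------------------------------------------------------------
# Feature-table construction and CSV I/O
# ---------------------------------------------------------------------------

_INTEGRATED_FEATURES = {"no3": "no3", "po4": "po4", "sio2": "sio2",
                        "fuco": "fuco", "chlb": "chlb", "chla": "chla",
                        "lutzea": "lutzea"}


def build_feature_table(casts, origin: dt.date | None = None,
                        mld_threshold: float = 0.125,
                        dgrad_orientation: str = "shallow_over_deep",
                        ) -> pd.DataFrame:
    """Compute the 13-column feature table (one row per cast, NaN where a
    quantity cannot be derived).  ``origin`` defaults to the first cast date.
    """
    casts = sorted(casts, key=lambda c: c.date)
    if not casts:
        raise ValueError("no casts")
    if origin is None:
        origin = casts[0].date
    rows = []
    for c in casts:
        row: dict[str, float | str] = {"date": c.date.isoformat()}
        x1, x2 = time_features(c.date, origin)
        row["jday"], row["yday"] = float(x1), float(x2)
        dens = c.profiles.get("dens")
        row["mld"] = np.nan
        row["dgrad"] = np.nan
        if dens is not None:
            try:
                row["mld"] = mixed_layer_depth(dens, mld_threshold)
            except ValueError:
                pass
            try:
                row["dgrad"] = density_gradient(dens, orientation=dgrad_orientation)
            except ValueError:
                pass
        temp = c.profiles.get("temp")
        row["temp"] = mean_temperature(temp) if temp is not None else np.nan
        for col, var in _INTEGRATED_FEATURES.items():
            prof = c.profiles.get(var)
            row[col] = integrate_profile(prof) if prof is not None else np.nan
        row["npp"] = np.nan if c.npp is None else float(c.npp)
        rows.append(row)
    return pd.DataFrame(rows, columns=["date", *FEATURE_TABLE_COLUMNS])


_CAST_CSV_COLUMNS = ("date", "depth", "temp", "dens", "no3", "po4", "sio2",
                     "chla", "chlb", "fuco", "lutzea")


def write_casts_csv(casts, path, npp_path=None) -> None:
    """Write casts in long format (one row per date x depth) with the fixed
    header ``date, depth, temp, dens, no3, po4, sio2, chla, chlb, fuco,
    lutzea``.  Integrated NPP, which has no depth axis, goes to ``npp_path``
    (columns ``date, npp``) when given."""
    rows = []
    for c in sorted(casts, key=lambda c: c.date):
        depths = np.unique(np.concatenate(
            [z for z, _ in c.profiles.values()] or [np.array([])]))
        for z in depths:
            row = {"date": c.date.isoformat(), "depth": z}
            for var in _CAST_CSV_COLUMNS[2:]:
                prof = c.profiles.get(var)
                if prof is None:
                    row[var] = np.nan
                else:
                    zz, vv = prof
                    hit = np.nonzero(np.isclose(zz, z))[0]
                    row[var] = vv[hit[0]] if hit.size else np.nan
            rows.append(row)
    pd.DataFrame(rows, columns=_CAST_CSV_COLUMNS).to_csv(path, index=False)
    if npp_path is not None:
        npp_rows = [{"date": c.date.isoformat(), "npp": c.npp}
                    for c in sorted(casts, key=lambda c: c.date)]
        pd.DataFrame(npp_rows, columns=["date", "npp"]).to_csv(npp_path, index=False)


def read_casts_csv(path, npp_path=None) -> list[CastRecord]:
    """Inverse of :func:`write_casts_csv`."""
    df = pd.read_csv(path)
    npp_map: dict[str, float] = {}
    if npp_path is not None:
        ndf = pd.read_csv(npp_path)
        npp_map = {str(r.date): (None if pd.isna(r.npp) else float(r.npp))
                   for r in ndf.itertuples()}
    casts = []
    for date_str, grp in df.groupby("date", sort=True):
        grp = grp.sort_values("depth")
        profiles = {}
        for var in _CAST_CSV_COLUMNS[2:]:
            vals = grp[var].to_numpy(dtype=float)
            mask = np.isfinite(vals)
            if mask.any():
                profiles[var] = (grp["depth"].to_numpy(dtype=float)[mask], vals[mask])
        casts.append(CastRecord(dt.date.fromisoformat(str(date_str)), profiles,
                                npp_map.get(str(date_str))))
    return casts


def write_feature_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("date", *FEATURE_TABLE_COLUMNS) if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV lacks columns: {missing}")
    return df
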