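"""Synthetic generator for a BATS-like multidecadal station record.

Emulates the structure of the observational record the pipeline is built
for: monthly casts (fortnightly during the January-April winter/spring
mixing period) over 1990-2016, depth profiles on a 0-120 m grid, seasonal
cycles, long-term linear trends, a planted linear law mapping the twelve
predictors to depth-integrated net primary productivity, Gaussian noise,
and value-wise missingness.  Everything is a pure function of
(config, seed), and the generating parameters are returned verbatim as a
:class:`GroundTruth` so downstream stages can be tested for parameter
recovery.

The water column is a caricature, not a simulation: temperature is a
seasonal surface signal mixed down to a seasonally varying mixed-layer
depth and relaxing linearly to a fixed deep value at 120 m; density is a
linear function of temperature (no equation of state); nutrients increase
below a fixed nutricline and are suppressed in the mixed layer under
stratification; pigments carry a subsurface (deep chlorophyll maximum)
peak.  See docs/methods.md for what this does and does not emulate.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import dataset
from .dataset import CastRecord, MonthlySeries, build_feature_table

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_casts",
    "planted_npp",
    "generate_feature_table",
    "monthly_series",
    "DEFAULT_PLANTED_COEFFICIENTS",
]

#: Planted NPP law: negative weight on mean temperature (x5) and on the
#: density-gradient ratio (x4), positive on nitrate (x6), fucoxanthin (x9)
#: and chlorophyll a (x11).  The x4 scale mirrors the fact that the ratio
#: varies only in the third decimal, so a large coefficient is needed for a
#: visible effect; the intercept offsets it to a realistic ~400 mg C m-2 d-1.
DEFAULT_PLANTED_COEFFICIENTS: dict[str, float] = {
    "intercept": 1.011e5,
    "x4": -1.0e5,
    "x5": -50.0,
    "x6": 1.5,
    "x9": 6.0,
    "x11": 4.0,
}

_VALID_COEF_KEYS = {"intercept"} | {f"x{i}" for i in range(1, 13)}

_DEFAULT_DEPTHS = tuple(float(z) for z in range(0, 121, 10))  # includes 20 m

_DEFAULT_TRENDS = {"temp": 0.021}  # deg C per year, applied to the whole column

_DEFAULT_NOISE_SD = {
    "temp": 0.15, "no3": 0.05, "po4": 0.004, "sio2": 0.08,
    "chla": 0.02, "chlb": 0.01, "fuco": 0.015, "lutzea": 0.01,
}

_DEFAULT_SEASONAL_AMPLITUDE = {"temp": 3.5}  # surface seasonal amplitude, deg C

# Event-scale (per-cast) anomaly magnitudes: a column temperature anomaly in
# deg C, and log-normal sigma for mixing-depth, nutrient-supply and
# bloom-magnitude fluctuations.  These decorrelate the predictors from the
# shared seasonal cycle, the way storms and bloom events do in real records,
# so that the planted attribution is identifiable and not just seasonal.
_DEFAULT_ANOMALY = {"temp": 0.4, "mld": 0.3, "nutrient": 0.25, "pigment": 0.3}


@dataclass
class SyntheticConfig:
    """Generating conditions for the synthetic station record.

    Defaults reproduce the record's stated design: a 27-year series starting
    1990, one cast per month with two per month January-April (the
    winter/spring mixing period) when ``fortnightly`` is set, a 10-m depth
    grid from 0 to 120 m (so the 20 m and 120 m density anchors exist
    without interpolation), a +0.021 deg C/yr column warming trend, and a
    planted linear NPP law.
    """

    start_year: int = 1990
    n_years: int = 27
    fortnightly: bool = True
    depth_levels: tuple[float, ...] = _DEFAULT_DEPTHS
    seasonal_amplitude: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEASONAL_AMPLITUDE))
    trend_per_year: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRENDS))
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    anomaly_sd: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ANOMALY))
    planted_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_COEFFICIENTS))
    npp_noise_sd: float = 40.0
    missing_rate: float = 0.0
    seed: int = 0

    # climatological anchors (deg C, kg m-3 per deg C, m)
    surface_temp_mean: float = 22.5
    deep_temp: float = 18.5
    density_ref: float = 1026.5
    density_slope: float = 0.22  # kg m-3 decrease per deg C above 20 deg C

    def validate(self) -> None:
        z = np.asarray(self.depth_levels, dtype=float)
        if z.size < 2 or np.any(np.diff(z) <= 0):
            raise ValueError("depth_levels: must be strictly increasing")
        if z[0] < 0 or z[-1] > 120:
            raise ValueError("depth_levels: must lie within [0, 120] m")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate: must lie in [0, 1)")
        if self.n_years < 1:
            raise ValueError("n_years: must be >= 1")
        bad = set(self.planted_coefficients) - _VALID_COEF_KEYS
        if bad:
            raise ValueError(f"planted_coefficients: unknown variable(s) {sorted(bad)}")


@dataclass
class GroundTruth:
    """The generating parameters, stored verbatim from the config."""

    trend_per_year: dict[str, float]
    planted_coefficients: dict[str, float]
    noise_sd: dict[str, float]
    npp_noise_sd: float
    seed: int

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _cast_dates(config: SyntheticConfig) -> list[dt.date]:
    dates = []
    for year in range(config.start_year, config.start_year + config.n_years):
        for month in range(1, 13):
            if config.fortnightly and month <= 4:
                dates.append(dt.date(year, month, 7))
                dates.append(dt.date(year, month, 21))
            else:
                dates.append(dt.date(year, month, 15))
    return dates


def _seasonal_mld(doy: float) -> float:
    """Deep winter mixing (~115 m in February), shallow summer layer (~15 m)."""
    return 65.0 + 50.0 * math.cos(2 * math.pi * (doy - 50.0) / 365.25)


def planted_npp(features, coefficients: dict[str, float],
                noise_sd: float, rng: np.random.Generator) -> float:
    """Planted response law: intercept + sum_j c_j * x_j + Normal(0, sd).

    ``features`` maps feature names to values; coefficient keys are
    ``intercept`` and ``x1``..``x12`` (``x5`` is mean temperature, etc.).
    """
    bad = set(coefficients) - _VALID_COEF_KEYS
    if bad:
        raise ValueError(f"unknown variable(s) in coefficients: {sorted(bad)}")
    y = float(coefficients.get("intercept", 0.0))
    cols = dataset.FEATURE_TABLE_COLUMNS
    for key, c in coefficients.items():
        if key == "intercept":
            continue
        idx = int(key[1:])
        name = cols[idx - 1]
        y += c * float(features[name])
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd)
    return y


def generate_casts(config: SyntheticConfig | None = None,
                   ) -> tuple[list[CastRecord], GroundTruth]:
    """Generate the synthetic cast record. Deterministic given the seed."""
    if config is None:
        config = SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    z = np.asarray(config.depth_levels, dtype=float)
    dates = _cast_dates(config)
    origin = dates[0]

    temp_amp = config.seasonal_amplitude.get("temp", 3.5)
    temp_trend = config.trend_per_year.get("temp", 0.0)
    casts: list[CastRecord] = []
    for date in dates:
        years_elapsed = (date - origin).days / 365.25
        doy = date.timetuple().tm_yday

        # event-scale anomalies, one draw per cast
        t_anom = rng.normal(0.0, config.anomaly_sd.get("temp", 0.0))
        mld_factor = math.exp(rng.normal(0.0, config.anomaly_sd.get("mld", 0.0)))
        nut_factor = math.exp(rng.normal(0.0, config.anomaly_sd.get("nutrient", 0.0)))
        bloom_factor = math.exp(rng.normal(0.0, config.anomaly_sd.get("pigment", 0.0)))
        mld = float(np.clip(_seasonal_mld(doy) * mld_factor, 10.0, 118.0))

        # temperature: mixed-layer value, relaxing linearly to the deep value
        t_surf = (config.surface_temp_mean
                  + temp_amp * math.cos(2 * math.pi * (doy - 240.0) / 365.25)
                  + temp_trend * years_elapsed + t_anom)
        t_deep = config.deep_temp + temp_trend * years_elapsed + 0.3 * t_anom
        temp = np.where(
            z <= mld, t_surf,
            t_surf + (t_deep - t_surf) * np.clip((z - mld) / max(120.0 - mld, 1e-9),
                                                 0.0, 1.0))
        temp = np.minimum.accumulate(temp)  # monotone non-increasing with depth
        temp = temp + rng.normal(0.0, config.noise_sd.get("temp", 0.0), z.size)

        # density: linear anti-correlation with temperature (no EOS)
        dens = config.density_ref - config.density_slope * (temp - 20.0)
        dens = np.maximum.accumulate(dens)  # keep statically stable

        # nutrients: increase below a fixed nutricline; mixed-layer surface
        # values are suppressed when the layer is shallow (stratified) and
        # enhanced after deep winter mixing entrains nutrient-rich water
        mix_boost = 0.4 * (mld / 120.0) * nut_factor
        ramp = np.clip((z - 60.0) / 60.0, 0.0, 1.0)
        no3 = (0.02 + 2.2 * ramp) * nut_factor + np.where(z <= mld, mix_boost, 0.0)
        po4 = 0.005 + 0.14 * ramp + np.where(z <= mld, mix_boost / 16.0, 0.0)
        sio2 = 0.6 + 1.0 * ramp + np.where(z <= mld, mix_boost / 2.0, 0.0)

        # pigments: subsurface (deep chlorophyll maximum) peak near 90 m,
        # with a winter/spring bloom component following deep mixing and an
        # event-scale bloom-magnitude factor
        dcm = np.exp(-((z - 90.0) / 25.0) ** 2)
        bloom = (mld / 120.0) * bloom_factor
        chla = 0.05 + (0.30 * dcm + 0.10 * bloom) * bloom_factor
        chlb = 0.02 + 0.08 * dcm
        fuco = 0.02 + (0.12 * dcm + 0.15 * bloom) * bloom_factor
        lutzea = 0.015 + 0.06 * dcm + 0.02 * np.clip(1.0 - bloom, 0.0, 1.0)

        profiles = {}
        for name, base in (("temp", temp), ("dens", dens), ("no3", no3),
                           ("po4", po4), ("sio2", sio2), ("chla", chla),
                           ("chlb", chlb), ("fuco", fuco), ("lutzea", lutzea)):
            sd = config.noise_sd.get(name, 0.0)
            if name in ("temp", "dens"):
                vals = base  # temp already noised; dens derives from temp
            elif sd > 0:
                vals = np.maximum(base + rng.normal(0.0, sd, z.size), 0.0)
            else:
                vals = base
            profiles[name] = (z.copy(), np.asarray(vals, dtype=float))
        casts.append(CastRecord(date, profiles, npp=None))

    # planted NPP from the features the dataset module itself derives,
    # so the law is exactly linear in the stored predictors
    features = build_feature_table(casts, origin=origin)
    for cast, (_, row) in zip(casts, features.iterrows()):
        cast.npp = planted_npp(row, config.planted_coefficients,
                               config.npp_noise_sd, rng)

    # value-wise missingness: each cast x variable (profiles and NPP)
    # independently deleted with probability missing_rate
    if config.missing_rate > 0:
        names = list(dataset.PROFILE_VARIABLES) + ["npp"]
        drop = rng.random((len(casts), len(names))) < config.missing_rate
        for i, cast in enumerate(casts):
            for j, name in enumerate(names):
                if not drop[i, j]:
                    continue
                if name == "npp":
                    cast.npp = None
                else:
                    cast.profiles.pop(name, None)

    truth = GroundTruth(trend_per_year=dict(config.trend_per_year),
                        planted_coefficients=dict(config.planted_coefficients),
                        noise_sd=dict(config.noise_sd),
                        npp_noise_sd=config.npp_noise_sd,
                        seed=config.seed)
    return casts, truth


def generate_feature_table(config: SyntheticConfig | None = None):
    """Convenience: generate casts and return (feature table, ground truth)."""
    if config is None:
        config = SyntheticConfig()
    casts, truth = generate_casts(config)
    return build_feature_table(casts), truth


def monthly_series(rate_per_year: float, n_years: int = 27,
                   seasonal_amplitude: float = 4.0, noise_sd: float = 0.3,
                   base: float = 0.0, start_year: int = 1990,
                   seed: int = 0) -> MonthlySeries:
    """A plain monthly series: linear trend + sinusoidal seasonal cycle +
    i.i.d. Gaussian noise, the canonical test bed for the seasonal trend
    stage.  Month (year y, month m) sits at time y + (m - 0.5)/12 years."""
    rng = np.random.default_rng(seed)
    years = np.repeat(np.arange(start_year, start_year + n_years), 12)
    months = np.tile(np.arange(1, 13), n_years)
    t = (years - start_year) + (months - 0.5) / 12.0
    values = (base + rate_per_year * t
              + seasonal_amplitude * np.sin(2 * np.pi * months / 12.0)
              + rng.normal(0.0, noise_sd, years.size))
    return MonthlySeries(years, months, values)
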