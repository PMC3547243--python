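"""Synthetic multi-year weather and birch pollen series.

The generator emulates the study conditions of a Central-European
(Cracow-like) monitoring series: 18-20 years of daily meteorological
observations with the station's monthly climate normals, and a spring
birch pollen season whose start is linked to late-winter temperature
and early-April humidity through a known, configurable linear model:

    start = a0 + a1 * Temp_6 + a2 * (Hum_10 - hum10_normal) + N(0, sigma_start)

where Temp_6 is the mean daily temperature over days 51-60 and Hum_10
the mean relative humidity over days 91-100 of the same year.  The
defaults take a0 = 102.94 and a1 = -1.51 from the published
one-variable season-start model and a2 = 0.59 from the two-variable
model; the humidity effect acts on the anomaly from its climatological
normal so the mean start stays near day 101.

Weather: daily climatological cycles interpolate the monthly normals
with per-month mean-preserving correction (so with zero noise every
monthly mean equals its normal exactly), plus AR(1) anomalies.
Rainfall is a wet-day occurrence chain whose monthly totals match the
normals in expectation, with amounts below 0.05 mm recorded as the
0.01 trace sentinel.  Pollen: a right-skewed lognormal-shaped daily
kernel scaled to a lognormally drawn seasonal pollen index (SPI), with
a handful of stray out-of-season grains.

Determinism: each year draws from its own generator seeded by
(root seed, year), so adding a year never perturbs earlier years.
"""

from __future__ import annotations

import calendar
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from pollencast.io_core import (
    DailyMetSeries,
    DailyPollenSeries,
    ValidationError,
    days_in_year,
)

logger = logging.getLogger(__name__)

# Monthly climate normals, Jan..Dec (20-year station means; Cracow-like).
MONTHLY_TEMP = (-1.2, 0.1, 3.7, 9.3, 14.6, 17.9, 19.8, 18.9, 13.6, 8.9, 3.8, -0.7)
MONTHLY_RAIN = (37.6, 32.2, 41.8, 48.3, 80.6, 81.7, 103.7, 75.0, 68.9, 48.7, 44.5, 34.6)
MONTHLY_HUMIDITY = (82.6, 79.9, 74.6, 67.4, 68.2, 69.2, 70.6, 73.3, 79.8, 82.9, 85.1, 84.9)
MONTHLY_SUNSHINE = (18.6, 22.6, 28.1, 39.2, 44.3, 43.6, 47.6, 47.8, 37.2, 30.2, 18.5, 15.2)
MONTHLY_CLOUD = (73.4, 71.9, 67.0, 61.5, 61.2, 62.5, 58.4, 55.2, 59.0, 65.1, 75.2, 76.1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator."""

    n_years: int = 18
    first_year: int = 1991
    seed: int = 0
    latitude_deg: float = 50.07

    monthly_temp: tuple[float, ...] = MONTHLY_TEMP
    monthly_rain: tuple[float, ...] = MONTHLY_RAIN  # monthly totals, mm
    monthly_humidity: tuple[float, ...] = MONTHLY_HUMIDITY
    monthly_sunshine: tuple[float, ...] = MONTHLY_SUNSHINE  # relative sunshine %
    monthly_cloud: tuple[float, ...] = MONTHLY_CLOUD  # cloudiness %

    # AR(1) anomaly processes (daily innovations).  The defaults are
    # calibrated so the inter-annual SD of a generated monthly mean,
    # SD_month ~= 0.84 * innovation_sd at phi = 0.8, matches the
    # station climate table's printed SD rows for the pre-season months
    # (temperature ~2.0 deg C, humidity ~4 %, cloudiness ~9 %,
    # relative sunshine ~7 %).
    ar_phi: float = 0.8
    temp_innovation_sd: float = 2.4  # deg C
    humidity_innovation_sd: float = 4.7  # percentage points
    cloud_innovation_sd: float = 10.5
    sunshine_innovation_sd: float = 8.5
    diurnal_half_range: float = 4.0  # (tmax - tmin) / 2
    morning_evening_half_range: float = 2.0  # (t19 - t7) / 2
    wet_day_probability: float = 0.45
    rain_stochastic: bool = True

    # season-start linkage (published birch start models)
    start_intercept: float = 102.94  # a0, day-of-year
    start_temp_coef: float = -1.51  # a1, days per deg C of Temp_6
    start_hum_coef: float = 0.59  # a2, days per % anomaly of Hum_10
    start_noise_sd: float = 2.0  # days
    start_bounds: tuple[float, float] = (60.0, 150.0)

    # season shape
    peak_offset_days: float = 8.0  # mode of the kernel after season start
    shape_log_sd: float = 0.55  # lognormal kernel shape
    spi_log_mean: float = math.log(3500.0)  # log PG/m3, within-season total
    spi_log_sd: float = 0.75
    daily_noise_log_sd: float = 0.3  # multiplicative day-to-day scatter
    stray_grains: int = 5  # out-of-season single grains per year

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValidationError("n_years must be >= 2")
        for name in ("monthly_temp", "monthly_rain", "monthly_humidity",
                     "monthly_sunshine", "monthly_cloud"):
            if len(getattr(self, name)) != 12:
                raise ValidationError(f"{name} needs 12 monthly values")
        for h in self.monthly_humidity:
            if not 0 <= h <= 100:
                raise ValidationError("monthly humidity normal outside [0, 100]")
        for sd in (self.temp_innovation_sd, self.humidity_innovation_sd,
                   self.cloud_innovation_sd, self.sunshine_innovation_sd,
                   self.start_noise_sd, self.spi_log_sd, self.daily_noise_log_sd):
            if sd < 0:
                raise ValidationError("noise standard deviations must be >= 0")

    @property
    def years(self) -> range:
        return range(self.first_year, self.first_year + self.n_years)

    def zero_noise(self) -> "GeneratorConfig":
        """Fully deterministic study conditions (closure testing)."""
        return replace(
            self,
            temp_innovation_sd=0.0,
            humidity_innovation_sd=0.0,
            cloud_innovation_sd=0.0,
            sunshine_innovation_sd=0.0,
            rain_stochastic=False,
            start_noise_sd=0.0,
            spi_log_sd=0.0,
            daily_noise_log_sd=0.0,
            stray_grains=0,
        )


def _year_rng(config: GeneratorConfig, year: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(year, stream))
    )


def _month_of_doy(year: int) -> np.ndarray:
    dates = pd.date_range(f"{year}-01-01", periods=days_in_year(year), freq="D")
    return dates.month.to_numpy()


def daily_climatology(monthly: tuple[float, ...], year: int) -> np.ndarray:
    """Smooth daily cycle through 12 monthly normals, monthly means exact.

    Linear interpolation between month midpoints (periodic), then a
    per-month constant correction so that every month's mean equals its
    normal — the correction keeps the zero-noise series faithful to the
    normals at monthly resolution.
    """
    n = days_in_year(year)
    months = _month_of_doy(year)
    # month midpoints as day-of-year, padded periodically
    mids = []
    for m in range(1, 13):
        first = int(pd.Timestamp(year, m, 1).dayofyear)
        mids.append(first - 1 + calendar.monthrange(year, m)[1] / 2.0)
    mids = np.array(mids)
    vals = np.asarray(monthly, dtype=float)
    xs = np.concatenate([[mids[-1] - n], mids, [mids[0] + n]])
    ys = np.concatenate([[vals[-1]], vals, [vals[0]]])
    doy = np.arange(1, n + 1, dtype=float)
    daily = np.interp(doy, xs, ys)
    for m in range(1, 13):
        mask = months == m
        daily[mask] += vals[m - 1] - daily[mask].mean()
    return daily


def _ar1(rng: np.random.Generator, n: int, phi: float, innovation_sd: float) -> np.ndarray:
    if innovation_sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, innovation_sd, size=n)
    out = np.empty(n)
    # stationary start
    out[0] = eps[0] / math.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def day_length_hours(latitude_deg: float, doy: np.ndarray) -> np.ndarray:
    """Astronomical day length (sunrise to sunset) from solar declination."""
    decl = np.radians(23.44) * np.sin(2.0 * np.pi * (284 + doy) / 365.0)
    lat = np.radians(latitude_deg)
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def generate_met_year(config: GeneratorConfig, year: int) -> DailyMetSeries:
    """One calendar year of daily meteorological observations."""
    n = days_in_year(year)
    doy = np.arange(1, n + 1)
    months = _month_of_doy(year)
    rng = _year_rng(config, year, stream=0)

    temp_mean = daily_climatology(config.monthly_temp, year) + _ar1(
        rng, n, config.ar_phi, config.temp_innovation_sd
    )
    a = config.diurnal_half_range
    b = config.morning_evening_half_range
    tmin = temp_mean - a
    tmax = temp_mean + a
    t7 = temp_mean - b
    t19 = temp_mean + b

    hum = daily_climatology(config.monthly_humidity, year) + _ar1(
        rng, n, config.ar_phi, config.humidity_innovation_sd
    )
    hum = np.clip(hum, 10.0, 95.0)
    f7 = hum + 5.0
    f13 = hum - 10.0
    f19 = hum  # weighted mean (2 f7 + f13 + f19)/4 = hum exactly

    cloud = daily_climatology(config.monthly_cloud, year) + _ar1(
        rng, n, config.ar_phi, config.cloud_innovation_sd
    )
    cloud = np.clip(cloud, 0.0, 100.0) / 10.0  # all three obs equal, 0-10 scale

    sun_pct = daily_climatology(config.monthly_sunshine, year) + _ar1(
        rng, n, config.ar_phi, config.sunshine_innovation_sd
    )
    sun_pct = np.clip(sun_pct, 0.0, 100.0)
    dl = day_length_hours(config.latitude_deg, doy)
    sun_hours = sun_pct / 100.0 * dl

    rain = np.zeros(n)
    for m in range(1, 13):
        mask = months == m
        n_days = int(mask.sum())
        total = config.monthly_rain[m - 1]
        if config.rain_stochastic:
            p = config.wet_day_probability
            wet = rng.random(n_days) < p
            amounts = rng.exponential(total / (n_days * p), size=n_days)
            vals = np.where(wet, amounts, 0.0)
            vals[(vals > 0.0) & (vals < 0.05)] = 0.01  # trace of rain
            rain[mask] = vals
        else:
            rain[mask] = total / n_days

    frame = pd.DataFrame(
        {
            "tmin": tmin,
            "tmax": tmax,
            "t7": t7,
            "t19": t19,
            "rain": rain,
            "f7": f7,
            "f13": f13,
            "f19": f19,
            "cloud6": cloud,
            "cloud12": cloud,
            "cloud18": cloud,
            "sun_hours": sun_hours,
            "day_length": dl,
        },
        index=pd.RangeIndex(1, n + 1, name="doy"),
    )
    return DailyMetSeries(year, frame)


def _window_mean(daily: np.ndarray, lo: int, hi: int) -> float:
    return float(daily[lo - 1 : hi].mean())


def hum10_normal(config: GeneratorConfig, year: int) -> float:
    """Climatological Hum_10 (days 91-100 humidity) used to centre the linkage."""
    return _window_mean(daily_climatology(config.monthly_humidity, year), 91, 100)


def true_season_start(
    config: GeneratorConfig, met: DailyMetSeries, rng: np.random.Generator
) -> float:
    """Linkage-model season start for one generated met year (continuous days)."""
    from pollencast.met_features import daily_indicators  # local: avoid cycle

    ind = daily_indicators(met)
    temp6 = float(ind["temperature"].loc[51:60].mean())
    hum10 = float(ind["humidity"].loc[91:100].mean())
    base = (
        config.start_intercept
        + config.start_temp_coef * temp6
        + config.start_hum_coef * (hum10 - hum10_normal(config, met.year))
    )
    lo, hi = config.start_bounds
    for _ in range(100):
        start = base + rng.normal(0.0, config.start_noise_sd) if config.start_noise_sd else base
        if lo <= start <= hi:
            return float(start)
        if config.start_noise_sd == 0.0:
            break
    logger.warning(
        "year %d: linkage start %.1f outside [%g, %g]; clipped", met.year, base, lo, hi
    )
    return float(np.clip(base, lo, hi))


def generate_pollen_year(
    met: DailyMetSeries, config: GeneratorConfig
) -> tuple[DailyPollenSeries, dict]:
    """One pollen year driven by the met year's linkage features.

    Returns the series and a truth record (true start, SPI draw,
    linkage features) for recovery tests.
    """
    year = met.year
    n = days_in_year(year)
    rng = _year_rng(config, year, stream=1)

    start = true_season_start(config, met, rng)
    spi = float(np.exp(rng.normal(config.spi_log_mean, config.spi_log_sd))
                if config.spi_log_sd else math.exp(config.spi_log_mean))

    # lognormal kernel: mode at start + peak_offset, 1 % quantile at the start
    sig = config.shape_log_sd
    mu = math.log(config.peak_offset_days) + sig * sig
    q01 = math.exp(mu + sig * stats.norm.ppf(0.01))
    anchor = start - q01
    doy = np.arange(1, n + 1, dtype=float)
    x = doy - anchor
    dens = np.zeros(n)
    pos = x > 0
    dens[pos] = stats.lognorm.pdf(x[pos], s=sig, scale=math.exp(mu))
    # scale so the kernel's central 1 %..97.5 % mass carries the SPI draw
    central_mass = 0.975 - 0.01
    values = dens / dens.sum() * (spi / central_mass)

    if config.daily_noise_log_sd > 0.0:
        noise = np.exp(rng.normal(0.0, config.daily_noise_log_sd, size=n))
        values = values * noise
    values[values < 1e-6] = 0.0

    if config.stray_grains > 0:
        k = int(rng.integers(0, config.stray_grains + 1))
        if k:
            upper = math.exp(mu + sig * stats.norm.ppf(0.999))
            lo_day = int(min(n - 1, anchor + upper + 10))
            days = rng.integers(lo_day, n, size=k)
            for d in days:
                values[d] += 1.0

    series = DailyPollenSeries(year, pd.Series(values, index=pd.RangeIndex(1, n + 1)))
    truth = {
        "year": year,
        "true_start": start,
        "spi_draw": spi,
        "anchor": anchor,
    }
    return series, truth


def generate_study(
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[dict[int, DailyMetSeries], dict[int, DailyPollenSeries], pd.DataFrame]:
    """All study years: met + pollen series and the truth sidecar.

    With ``out_dir`` set, writes ``met.csv``, ``pollen.csv`` and
    ``truth.txt`` (key-value text recording the linkage parameters and
    per-year true values); existing files raise unless ``overwrite``.
    """
    met: dict[int, DailyMetSeries] = {}
    pollen: dict[int, DailyPollenSeries] = {}
    truths = []
    for year in config.years:
        met[year] = generate_met_year(config, year)
        series, truth = generate_pollen_year(met[year], config)
        pollen[year] = series
        truths.append(truth)
    truth_table = pd.DataFrame(truths).set_index("year")

    if out_dir is not None:
        from pollencast.io_core import write_met_csv, write_pollen_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {p: out / p for p in ("met.csv", "pollen.csv", "truth.txt")}
        clash = [str(p) for p in paths.values() if p.exists()]
        if clash and not overwrite:
            raise ValidationError(f"output exists: {clash}")
        write_met_csv(paths["met.csv"], met)
        write_pollen_csv(paths["pollen.csv"], pollen)
        with open(paths["truth.txt"], "w") as fh:
            fh.write(f"start_intercept = {config.start_intercept}\n")
            fh.write(f"start_temp_coef = {config.start_temp_coef}\n")
            fh.write(f"start_hum_coef = {config.start_hum_coef}\n")
            fh.write(f"start_noise_sd = {config.start_noise_sd}\n")
            fh.write(f"seed = {config.seed}\n")
            for year, row in truth_table.iterrows():
                fh.write(
                    f"year_{year} = start={row['true_start']:.4f} "
                    f"spi={row['spi_draw']:.2f}\n"
                )
    return met, pollen, truth_table
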