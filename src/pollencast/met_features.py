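"""Daily meteorological indicators and windowed predictor features.

Daily indicators follow the Polish climatological-station conventions:

* mean daily temperature  (t_max + t_min + t_7 + t_19) / 4
* mean daily relative humidity  (2*f_7 + f_13 + f_19) / 4
* daily cloudiness  mean of the 6/12/18 UTC observations on the 0-10
  scale, rescaled to percent (100 % = full cloudiness)
* relative sunshine  sunshine hours as a percentage of day length

Features aggregate an indicator over a window: a fixed 10-day decade
(decade k = days 10(k-1)+1 .. 10k from 1 January), an explicit
day-of-year range, or a set of calendar months.  Multi-month windows
average daily values over the whole span, not monthly means of means.
A window tolerates up to 20 % missing days (mean over the available
days); beyond that the feature is marked unavailable (NaN).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from pollencast.io_core import DailyMetSeries, ValidationError, days_in_year

KINDS = ("temperature", "rainfall", "humidity", "cloudiness", "relative_sunshine")

MAX_MISSING_FRACTION = 0.2


def mean_daily_temperature(t_min, t_max, t_7, t_19):
    """(t_max + t_min + t_7 + t_19) / 4, in deg C.

    Accepts scalars or aligned arrays; any missing input yields a
    missing result for that day.
    """
    t_min = np.asarray(t_min, dtype=float)
    t_max = np.asarray(t_max, dtype=float)
    if np.any((t_min > t_max) & ~np.isnan(t_min) & ~np.isnan(t_max)):
        raise ValidationError("t_min > t_max")
    out = (np.asarray(t_max, float) + t_min + np.asarray(t_7, float) + np.asarray(t_19, float)) / 4.0
    return out if out.ndim else float(out)


def mean_daily_humidity(f_7, f_13, f_19):
    """(2*f_7 + f_13 + f_19) / 4, in percent; the 7 a.m. reading weighs double."""
    arrs = [np.asarray(a, dtype=float) for a in (f_7, f_13, f_19)]
    for a in arrs:
        if np.any((a < 0) | (a > 100)):
            raise ValidationError("humidity outside [0, 100]")
    out = (2.0 * arrs[0] + arrs[1] + arrs[2]) / 4.0
    return out if out.ndim else float(out)


def daily_cloudiness_percent(c_6, c_12, c_18):
    """Mean of three 0-10 cloud observations rescaled to percent."""
    arrs = [np.asarray(a, dtype=float) for a in (c_6, c_12, c_18)]
    for a in arrs:
        if np.any((a < 0) | (a > 10)):
            raise ValidationError("cloud observation outside [0, 10]")
    out = (arrs[0] + arrs[1] + arrs[2]) / 3.0 * 10.0
    return out if out.ndim else float(out)


def relative_sunshine(sunshine_hours, day_length):
    """100 * sunshine_hours / day_length, in percent of the possible day."""
    sun = np.asarray(sunshine_hours, dtype=float)
    dl = np.asarray(day_length, dtype=float)
    if np.any(dl <= 0):
        raise ValidationError("day length must be positive")
    if np.any((sun < 0) | (sun > dl + 1e-9)):
        raise ValidationError("sunshine hours outside [0, day_length]")
    out = 100.0 * sun / dl
    return out if out.ndim else float(out)


def daily_indicators(met: DailyMetSeries) -> pd.DataFrame:
    """Per-day indicator table (one column per indicator kind)."""
    f = met.frame
    return pd.DataFrame(
        {
            "temperature": mean_daily_temperature(f["tmin"], f["tmax"], f["t7"], f["t19"]),
            "rainfall": met.rainfall(),
            "humidity": (2.0 * f["f7"] + f["f13"] + f["f19"]) / 4.0,
            "cloudiness": (f["cloud6"] + f["cloud12"] + f["cloud18"]) / 3.0 * 10.0,
            "relative_sunshine": 100.0 * f["sun_hours"] / f["day_length"],
        },
        index=f.index,
    )


@dataclass(frozen=True)
class WindowSpec:
    """A named feature window over one indicator kind.

    Exactly one of ``decade``, ``days`` or ``months`` defines the
    window.  ``statistic`` is ``"mean"`` (default for every kind,
    including the decade rainfall features, which the source tables
    label as mean daily rainfall) or ``"sum"``.
    """

    name: str
    kind: str
    decade: int | None = None
    days: tuple[int, int] | None = None
    months: tuple[int, ...] | None = None
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown indicator kind {self.kind!r}")
        given = sum(x is not None for x in (self.decade, self.days, self.months))
        if given != 1:
            raise ValidationError(
                f"feature {self.name}: exactly one of decade/days/months required"
            )
        if self.decade is not None and not 1 <= self.decade <= 36:
            raise ValidationError(f"decade index {self.decade} outside 1..36")
        if self.statistic not in ("mean", "sum"):
            raise ValidationError(f"unknown statistic {self.statistic!r}")

    def day_range(self, year: int) -> range:
        """Inclusive day-of-year window resolved for ``year``."""
        if self.decade is not None:
            lo = 10 * (self.decade - 1) + 1
            return range(lo, lo + 10)
        if self.days is not None:
            a, b = self.days
            if not 1 <= a <= b <= days_in_year(year):
                raise ValidationError(
                    f"feature {self.name}: day range {a}-{b} outside year {year}"
                )
            return range(a, b + 1)
        assert self.months is not None
        doys = []
        for month in sorted(self.months):
            for day in range(1, calendar.monthrange(year, month)[1] + 1):
                doys.append(pd.Timestamp(year, month, day).dayofyear)
        return range(min(doys), max(doys) + 1)


@dataclass(frozen=True)
class MetFeature:
    name: str
    kind: str
    year: int
    value: float
    window: tuple[int, int]
    n_days: int
    n_available: int


def window_aggregate(
    daily: pd.Series, window: WindowSpec, year: int
) -> MetFeature:
    """Aggregate one indicator series over one window.

    ``daily`` must be indexed by day-of-year.  Returns NaN when more
    than 20 % of the window's days are missing.
    """
    rng = window.day_range(year)
    days = list(rng)
    vals = daily.reindex(days)
    n_avail = int(vals.notna().sum())
    if n_avail < (1.0 - MAX_MISSING_FRACTION) * len(days):
        value = float("nan")
    elif window.statistic == "sum":
        value = float(vals.sum())
    else:
        value = float(vals.mean())
    return MetFeature(
        name=window.name,
        kind=window.kind,
        year=year,
        value=value,
        window=(days[0], days[-1]),
        n_days=len(days),
        n_available=n_avail,
    )


def feature_matrix(
    met: Mapping[int, DailyMetSeries], spec: Iterable[WindowSpec]
) -> pd.DataFrame:
    """Year x feature table for a collection of met years.

    Unavailable features (completeness rule violated) are NaN, never 0.
    """
    spec = list(spec)
    if not spec:
        raise ValidationError("empty feature specification")
    if not met:
        raise ValidationError("no meteorological years supplied")
    rows = {}
    for year in sorted(met):
        ind = daily_indicators(met[year])
        rows[year] = {
            w.name: window_aggregate(ind[w.kind], w, year).value for w in spec
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "year"
    return table[[w.name for w in spec]]


# Predictor windows named in the source study's model tables:
# Temp_k / Hum_k / Cloud_k / Rain_k are decade-k means of the daily
# indicator; Temp_M4 is the April mean and Temp_M23 the March-April
# mean over the concatenated daily span.
DEFAULT_FEATURE_SPEC: tuple[WindowSpec, ...] = (
    WindowSpec("Temp_6", "temperature", decade=6),
    WindowSpec("Temp_9", "temperature", decade=9),
    WindowSpec("Temp_M23", "temperature", months=(3, 4)),
    WindowSpec("Temp_M4", "temperature", months=(4,)),
    WindowSpec("Rain_12", "rainfall", decade=12),
    WindowSpec("Hum_4", "humidity", decade=4),
    WindowSpec("Hum_10", "humidity", decade=10),
    WindowSpec("Cloud_6", "cloudiness", decade=6),
)


def monthly_summary(met: Mapping[int, DailyMetSeries], kind: str) -> pd.DataFrame:
    """Climatological monthly summary of one indicator over many years.

    Rows mean/min/max/SD/V% over the per-year monthly values, columns
    months 1..12 — the layout of a descriptive station-climate table.
    SD uses the sample (n-1) convention.
    """
    per_year: dict[int, list[float]] = {}
    for year, series in met.items():
        ind = daily_indicators(series)[kind]
        dates = pd.date_range(f"{year}-01-01", periods=days_in_year(year), freq="D")
        monthly = ind.groupby(dates.month).mean()
        if kind == "rainfall":
            monthly = ind.groupby(dates.month).sum()
        per_year[year] = [float(monthly.get(m, np.nan)) for m in range(1, 13)]
    table = pd.DataFrame.from_dict(per_year, orient="index", columns=range(1, 13))
    mean = table.mean()
    sd = table.std(ddof=1)
    return pd.DataFrame(
        {
            "mean": mean,
            "min": table.min(),
            "max": table.max(),
            "sd": sd,
            "v_pct": 100.0 * sd / mean,
        }
    ).T
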