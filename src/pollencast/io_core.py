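"""Tabular input/output for daily pollen and meteorological series.

Conventions shared by every module:

* day-of-year is 1-based from 1 January ("days from 1 January"); leap
  years run to day 366;
* pollen concentrations are daily means in pollen grains per cubic
  metre (PG/m3) and are never negative;
* rainfall uses the climatological-station convention ``0`` = no rain,
  ``0.01`` = trace of rain (the trace keeps its numeric value 0.01 in
  aggregates unless explicitly zeroed);
* CSV files are comma-separated UTF-8 with a mandatory header row and
  ``.`` as the decimal separator.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACE_RAIN = 0.01

MET_COLUMNS = [
    "tmin",
    "tmax",
    "t7",
    "t19",
    "rain",
    "f7",
    "f13",
    "f19",
    "cloud6",
    "cloud12",
    "cloud18",
    "sun_hours",
    "day_length",
]


class ValidationError(ValueError):
    """Raised when an input file or series violates a domain invariant."""


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def day_of_year(date: pd.Timestamp) -> int:
    """1-based ordinal day within the calendar year (Jan 1 = 1)."""
    return int(date.dayofyear)


@dataclass
class DailyPollenSeries:
    """One calendar year of daily mean pollen concentrations.

    ``values`` is indexed by day-of-year (1..365/366); missing days are
    NaN, never silently zero.
    """

    year: int
    values: pd.Series  # index: day-of-year, float values, NaN = missing

    def __post_init__(self) -> None:
        n = days_in_year(self.year)
        full = pd.RangeIndex(1, n + 1, name="doy")
        self.values = self.values.reindex(full).astype(float)
        finite = self.values.dropna()
        if (finite < 0).any():
            bad = int(finite[finite < 0].index[0])
            raise ValidationError(
                f"negative pollen concentration at day {bad} of {self.year}"
            )

    @property
    def n_days(self) -> int:
        return len(self.values)

    @property
    def missing_days(self) -> list[int]:
        return [int(d) for d in self.values.index[self.values.isna()]]

    def annual_total(self, missing_as_zero: bool = True) -> float:
        if not missing_as_zero and self.values.isna().any():
            raise ValidationError(
                f"year {self.year} has missing days; cannot form a strict total"
            )
        return float(self.values.fillna(0.0).sum())


@dataclass
class DailyMetSeries:
    """One calendar year of sub-daily meteorological observations.

    ``frame`` is indexed by day-of-year with columns :data:`MET_COLUMNS`
    plus the boolean ``rain_trace`` flag.  Missing days hold NaN rows.
    """

    year: int
    frame: pd.DataFrame
    trace_as_zero: bool = field(default=False)

    def __post_init__(self) -> None:
        n = days_in_year(self.year)
        full = pd.RangeIndex(1, n + 1, name="doy")
        frame = self.frame.reindex(full)
        for col in MET_COLUMNS:
            if col not in frame.columns:
                frame[col] = np.nan
        if "rain_trace" not in frame.columns:
            frame["rain_trace"] = np.isclose(frame["rain"], TRACE_RAIN)
        frame["rain_trace"] = frame["rain_trace"].fillna(False).astype(bool)
        self.frame = frame
        _validate_met_frame(frame, self.year)

    def rainfall(self) -> pd.Series:
        """Daily rainfall with the trace convention applied."""
        rain = self.frame["rain"].copy()
        if self.trace_as_zero:
            rain[self.frame["rain_trace"]] = 0.0
        return rain


def _validate_met_frame(frame: pd.DataFrame, year: int) -> None:
    both = frame[["tmin", "tmax"]].dropna()
    bad = both.index[both["tmin"] > both["tmax"]]
    if len(bad):
        raise ValidationError(
            f"tmin > tmax at day {int(bad[0])} of {year}"
        )
    for col in ("f7", "f13", "f19"):
        vals = frame[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError(f"humidity {col} outside [0, 100] in {year}")
    for col in ("cloud6", "cloud12", "cloud18"):
        vals = frame[col].dropna()
        if ((vals < 0) | (vals > 10)).any():
            raise ValidationError(f"cloud observation {col} outside [0, 10] in {year}")
    rain = frame["rain"].dropna()
    if (rain < 0).any():
        raise ValidationError(f"negative rainfall in {year}")
    sun = frame[["sun_hours", "day_length"]].dropna()
    if (sun["sun_hours"] < 0).any() or (
        sun["sun_hours"] > sun["day_length"] + 1e-9
    ).any():
        raise ValidationError(f"sunshine hours outside [0, day_length] in {year}")


def _read_dated_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise ValidationError(f"{path}: missing 'date' column")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    dup = df["date"].duplicated()
    if dup.any():
        first = df.loc[dup, "date"].iloc[0].date()
        raise ValidationError(f"{path}: duplicate date {first}")
    return df


def read_pollen_csv(path) -> dict[int, DailyPollenSeries]:
    """Read a ``date,concentration`` CSV into per-year pollen series.

    Days absent from the file are marked missing (NaN); a negative
    concentration raises :class:`ValidationError` naming the row.
    """
    df = _read_dated_csv(path)
    if "concentration" not in df.columns:
        raise ValidationError(f"{path}: missing 'concentration' column")
    neg = df.index[pd.to_numeric(df["concentration"], errors="coerce") < 0]
    if len(neg):
        raise ValidationError(
            f"{path}: negative concentration at row {int(neg[0]) + 2} "
            f"(date {df.loc[neg[0], 'date'].date()})"
        )
    out: dict[int, DailyPollenSeries] = {}
    for year, grp in df.groupby(df["date"].dt.year):
        doy = grp["date"].dt.dayofyear
        values = pd.Series(
            grp["concentration"].astype(float).to_numpy(), index=doy.to_numpy()
        )
        out[int(year)] = DailyPollenSeries(int(year), values)
    if not out:
        logger.warning("%s: empty pollen file", path)
    return out


def read_met_csv(path, trace_as_zero: bool = False) -> dict[int, DailyMetSeries]:
    """Read a daily meteorological CSV into per-year series.

    Rows with rainfall exactly 0.01 are flagged as trace rain and keep
    the numeric value 0.01.
    """
    df = _read_dated_csv(path)
    missing_cols = [c for c in MET_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    out: dict[int, DailyMetSeries] = {}
    for year, grp in df.groupby(df["date"].dt.year):
        doy = grp["date"].dt.dayofyear.to_numpy()
        frame = grp[MET_COLUMNS].astype(float)
        frame.index = pd.Index(doy, name="doy")
        out[int(year)] = DailyMetSeries(int(year), frame, trace_as_zero=trace_as_zero)
    if not out:
        logger.warning("%s: empty meteorological file", path)
    return out


def _dates_for_year(year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")


def write_pollen_csv(path, series: dict[int, DailyPollenSeries]) -> None:
    """Write per-year pollen series back to the ``date,concentration`` dialect.

    Missing days are omitted from the file, so a round trip reproduces
    the stored values and the missing-day set exactly.
    """
    parts = []
    for year in sorted(series):
        s = series[year]
        dates = _dates_for_year(year)
        df = pd.DataFrame(
            {"date": dates.strftime("%Y-%m-%d"), "concentration": s.values.to_numpy()}
        )
        parts.append(df.dropna(subset=["concentration"]))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_met_csv(path, series: dict[int, DailyMetSeries]) -> None:
    parts = []
    for year in sorted(series):
        s = series[year]
        dates = _dates_for_year(year)
        df = s.frame[MET_COLUMNS].copy()
        df.insert(0, "date", dates.strftime("%Y-%m-%d"))
        parts.append(df.dropna(how="all", subset=MET_COLUMNS))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
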