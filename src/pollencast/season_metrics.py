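"""Percentage-method pollen-season delimitation and season statistics.

A percentage method delimits the season as the span holding a central
fraction of the annual pollen sum.  The registry covers the common
variants:

======== =============== =============
method   start fraction  end fraction
======== =============== =============
98       1 %             99 %
95       2.5 %           97.5 %
90       5 %             95 %
98/95    1 %             97.5 %
======== =============== =============

The season starts on the first day whose cumulative sum reaches the
start fraction of the annual total, and ends on the first day whose
cumulative sum reaches the end fraction (">=" attainment, so a
point-mass year is well defined and a season never ends on a zero day
after the mass has been reached).  The seasonal pollen index (SPI) is
the concentration sum over the delimited season; the peak day is the
day of the maximum daily concentration within the season, earliest on
ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from pollencast.io_core import DailyPollenSeries, ValidationError

logger = logging.getLogger(__name__)


class NoSeasonError(ValidationError):
    """Raised when the annual total is zero and no season can be delimited."""


@dataclass(frozen=True)
class SeasonDefinition:
    """Cumulative-fraction thresholds of one percentage method."""

    name: str
    start_fraction: float
    end_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.start_fraction < self.end_fraction < 1.0:
            raise ValidationError(
                f"method {self.name}: need 0 < start < end < 1, got "
                f"({self.start_fraction}, {self.end_fraction})"
            )


METHODS: dict[str, SeasonDefinition] = {
    "98": SeasonDefinition("98", 0.01, 0.99),
    "95": SeasonDefinition("95", 0.025, 0.975),
    "90": SeasonDefinition("90", 0.05, 0.95),
    "98/95": SeasonDefinition("98/95", 0.01, 0.975),
}


@dataclass(frozen=True)
class SeasonSummary:
    year: int
    method: str
    start: int  # day-of-year (SS)
    end: int  # day-of-year (SE)
    duration: int  # end - start + 1
    spi: float  # seasonal pollen index, PG/m3
    peak_day: int  # day-of-year (PD)
    peak_concentration: float  # PG/m3 (PC)


def _season_values(series: DailyPollenSeries, strict: bool) -> pd.Series:
    values = series.values
    if values.isna().any():
        if strict:
            raise ValidationError(
                f"year {series.year}: {len(series.missing_days)} missing days "
                "(strict mode)"
            )
        logger.warning(
            "year %d: %d missing days treated as zero for season delimitation",
            series.year,
            len(series.missing_days),
        )
        values = values.fillna(0.0)
    return values


def season_bounds(
    series: DailyPollenSeries,
    definition: SeasonDefinition,
    strict_missing: bool = False,
) -> tuple[int, int]:
    """First days whose cumulative sums reach the start/end fractions."""
    values = _season_values(series, strict_missing)
    total = float(values.sum())
    if total <= 0.0:
        raise NoSeasonError(f"year {series.year}: annual total is zero")
    cum = values.cumsum()
    start = int(cum.index[np.searchsorted(cum.to_numpy(), definition.start_fraction * total)])
    end = int(cum.index[np.searchsorted(cum.to_numpy(), definition.end_fraction * total)])
    return start, end


def season_summary(
    series: DailyPollenSeries,
    definition: SeasonDefinition,
    strict_missing: bool = False,
    peak_within_season: bool = True,
) -> SeasonSummary:
    """Season bounds plus SPI, duration and peak statistics for one year."""
    start, end = season_bounds(series, definition, strict_missing)
    values = _season_values(series, strict_missing)
    window = values.loc[start:end]
    search = window if peak_within_season else values
    peak_day = int(search.idxmax())  # idxmax returns the earliest tie
    return SeasonSummary(
        year=series.year,
        method=definition.name,
        start=start,
        end=end,
        duration=end - start + 1,
        spi=float(window.sum()),
        peak_day=peak_day,
        peak_concentration=float(search.max()),
    )


def season_table(
    series: Mapping[int, DailyPollenSeries],
    definition: SeasonDefinition,
    strict_missing: bool = False,
) -> pd.DataFrame:
    """One summary row per year: start, end, duration, SPI, peak day/conc."""
    rows = []
    for year in sorted(series):
        s = season_summary(series[year], definition, strict_missing)
        rows.append(
            {
                "year": year,
                "method": s.method,
                "start": s.start,
                "end": s.end,
                "duration": s.duration,
                "spi": s.spi,
                "peak_day": s.peak_day,
                "peak_concentration": s.peak_concentration,
            }
        )
    return pd.DataFrame(rows).set_index("year")


def coefficient_of_variation(values: Iterable[float]) -> float:
    """V% = 100 * sample SD (n-1) / mean; undefined for mean 0 or n < 2."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValidationError("coefficient of variation needs n >= 2")
    mean = arr.mean()
    if mean == 0.0:
        raise ValidationError("coefficient of variation undefined for mean 0")
    return float(100.0 * arr.std(ddof=1) / mean)


def compare_methods(
    series: Mapping[int, DailyPollenSeries],
    methods: Iterable[SeasonDefinition] = tuple(METHODS.values()),
) -> pd.DataFrame:
    """V% of each season characteristic per percentage method.

    Rows are the methods plus the method-independent peak-day and
    peak-concentration rows (computed with the widest season so the
    peak is inside it for every method in practice).
    """
    series = dict(series)
    if len(series) < 2:
        raise ValidationError("method comparison needs at least 2 years")
    rows = {}
    for definition in methods:
        table = season_table(series, definition)
        rows[f"{definition.name} % method"] = {
            "season_start": coefficient_of_variation(table["start"]),
            "season_end": coefficient_of_variation(table["end"]),
            "season_duration": coefficient_of_variation(table["duration"]),
            "spi": coefficient_of_variation(table["spi"]),
        }
    widest = season_table(series, METHODS["98"])
    out = pd.DataFrame(rows).T
    out.loc["peak_day", "v_pct"] = coefficient_of_variation(widest["peak_day"])
    out.loc["peak_concentration", "v_pct"] = coefficient_of_variation(
        widest["peak_concentration"]
    )
    return out
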