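"""Temporal classification and yearly frequency tables.

Each record is assigned to the study's temporal categories:

* illumination, at coarse (LR3: NI night / DL daylight / TW twilight) and
  fine (LR5: NbD night before dawn / DA dawn / DL daylight / DU dusk /
  NaD night after dusk) resolution, from the date's sunrise/sunset and the
  configured twilight window.  All windows are half-open and left-closed:
  a record at exactly sunrise is daylight, at exactly sunset is dusk.
* moon day 1..30 from the mean-synodic lunar age (day 30, a partial day,
  is dropped before smoothing when configured);
* season, month, ISO weekday, day of year (Feb 29 merged into day 59 so
  the cyclic axis has fixed period 365).

The descriptive surface is the :class:`FrequencyTable`: per-year counts and
within-year proportions per category, with the cross-year mean and sample
standard deviation (n-1 denominator over years) of the proportions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .config import StudyConfig
from .ephemeris import (
    SeasonTable,
    SolarDay,
    lunar_state,
    season_of,
    season_table,
    solar_events,
)
from .records import AccidentRecord

__all__ = [
    "LR5_CATEGORIES",
    "LR3_CATEGORIES",
    "LR5_TO_LR3",
    "FrequencyTable",
    "classify_illumination",
    "assign_moon_day",
    "annotate_records",
    "frequency_table",
    "report_rate",
    "MONTH_LABELS",
    "WEEKDAY_LABELS",
    "SEASON_LABELS",
]

LR5_CATEGORIES = ("NbD", "DA", "DL", "DU", "NaD")
LR3_CATEGORIES = ("NI", "DL", "TW")
LR5_TO_LR3 = {"NbD": "NI", "DA": "TW", "DL": "DL", "DU": "TW", "NaD": "NI"}

SEASON_LABELS = ("spring", "summer", "autumn", "winter")
MONTH_LABELS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
WEEKDAY_LABELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def classify_illumination(
    record: AccidentRecord, solar: SolarDay, config: StudyConfig
) -> tuple[str, str] | None:
    """(lr5, lr3) labels for a record, or ``None`` when the time is missing.

    ``solar`` must describe the record's date.  Windows, in local civil
    time:  NbD = [00:00, sunrise-tw), DA = [sunrise-tw, sunrise),
    DL = [sunrise, sunset), DU = [sunset, sunset+tw), NaD = [sunset+tw, 24:00).
    """
    if record.date != solar.date:
        raise ValueError("solar day does not match the record's date")
    if record.time is None:
        return None
    t = dt.datetime.combine(record.date, record.time, tzinfo=config.tzinfo)
    if t < solar.dawn_start:
        lr5 = "NbD"
    elif t < solar.sunrise:
        lr5 = "DA"
    elif t < solar.sunset:
        lr5 = "DL"
    elif t < solar.dusk_end:
        lr5 = "DU"
    else:
        lr5 = "NaD"
    return lr5, LR5_TO_LR3[lr5]


def assign_moon_day(record: AccidentRecord, config: StudyConfig) -> int | None:
    """Moon day 1..30 of a record, or ``None`` when day 30 is dropped.

    Records without a clock time use local noon: lunar age changes by less
    than 0.04 d across a day, negligible at day resolution.
    """
    time = record.time if record.time is not None else dt.time(12, 0)
    moon_day = lunar_state(dt.datetime.combine(record.date, time), config).moon_day
    if moon_day == 30 and config.drop_moon_day_30:
        return None
    return moon_day


def _merged_day_of_year(date: dt.date) -> int:
    """Day of year on a fixed 1..365 axis; Feb 29 is merged into day 59."""
    doy = date.timetuple().tm_yday
    if _is_leap(date.year) and doy >= 60:  # Feb 29 (doy 60) -> 59, later days shift back
        return doy - 1
    return doy


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def annotate_records(
    records: list[AccidentRecord],
    config: StudyConfig,
    seasons: SeasonTable | None = None,
) -> pd.DataFrame:
    """Annotate records with every temporal category in one pass.

    Returns a DataFrame with one row per record and columns: date, time,
    year, month, weekday, day_of_year, season, sunrise, sunset, lr5, lr3
    (empty strings when the time is missing), moon_age, moon_day
    (<NA> when day 30 is dropped).
    """
    if seasons is None:
        years = sorted({r.date.year for r in records} or set(config.study_years))
        seasons = season_table(years, config)

    @lru_cache(maxsize=None)
    def solar_for(date: dt.date) -> SolarDay:
        return solar_events(date, config)

    rows = []
    for rec in records:
        solar = solar_for(rec.date)
        illum = classify_illumination(rec, solar, config)
        time = rec.time if rec.time is not None else dt.time(12, 0)
        moon = lunar_state(dt.datetime.combine(rec.date, time), config)
        moon_day = moon.moon_day
        if moon_day == 30 and config.drop_moon_day_30:
            moon_day = None
        rows.append(
            {
                "date": rec.date,
                "time": rec.time.strftime("%H:%M") if rec.time else "",
                "year": rec.date.year,
                "month": MONTH_LABELS[rec.date.month - 1],
                "weekday": WEEKDAY_LABELS[rec.date.weekday()],
                "day_of_year": _merged_day_of_year(rec.date),
                "season": season_of(rec.date, seasons),
                "sunrise": solar.sunrise.strftime("%H:%M"),
                "sunset": solar.sunset.strftime("%H:%M"),
                "lr5": illum[0] if illum else "",
                "lr3": illum[1] if illum else "",
                "moon_age": moon.age_days,
                "moon_day": moon_day,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["moon_day"] = frame["moon_day"].astype("Int64")
    return frame


@dataclass(frozen=True)
class FrequencyTable:
    """Category x year counts with within-year proportions.

    ``counts`` is a categories-by-years DataFrame; ``proportions`` its
    column-normalized form (each year sums to 1); ``mean`` and ``sd`` the
    cross-year mean and sample SD of each category's proportions.
    ``excluded`` counts records that carried no label (e.g. missing time in
    illumination tables, dropped moon day 30).
    """

    counts: pd.DataFrame
    excluded: int = 0

    @property
    def categories(self) -> tuple: return tuple(self.counts.index)

    @property
    def years(self) -> tuple: return tuple(self.counts.columns)

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    @property
    def mean(self) -> pd.Series:
        return self.proportions.mean(axis=1)

    @property
    def sd(self) -> pd.Series:
        return self.proportions.std(axis=1, ddof=1)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def long_form(self) -> pd.DataFrame:
        """Tidy (category, year, count, proportion, mean, sd) table."""
        props = self.proportions
        rows = [
            {
                "category": cat,
                "year": year,
                "count": int(self.counts.loc[cat, year]),
                "proportion": props.loc[cat, year],
                "mean": self.mean[cat],
                "sd": self.sd[cat],
            }
            for cat in self.counts.index
            for year in self.counts.columns
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Per-category mean ± SD of yearly percentage shares."""
        return pd.DataFrame(
            {
                "mean_pct": (100 * self.mean).round(1),
                "sd_pct": (100 * self.sd).round(1),
                "total_count": self.counts.sum(axis=1).astype(int),
            }
        )


def frequency_table(
    annotated: pd.DataFrame,
    by: str,
    categories: tuple | None = None,
    year_col: str = "year",
) -> FrequencyTable:
    """Build the category-by-year frequency table for one labelling rule.

    ``by`` names an annotation column (season, month, weekday, lr3, lr5,
    moon_day, day_of_year).  Rows with a null/empty label are counted as
    excluded.  Raises if any year in the data has zero labelled records
    (its proportions would be undefined).
    """
    if by not in annotated.columns:
        raise KeyError(f"no annotation column {by!r}")
    labels = annotated[by]
    valid = labels.notna() & (labels.astype(str) != "")
    sub = annotated.loc[valid, [year_col, by]]
    if categories is None:
        categories = _default_categories(by, sub[by])
    years = sorted(annotated[year_col].unique())
    counts = (
        sub.groupby([by, year_col], observed=True).size().unstack(year_col, fill_value=0)
    )
    counts = counts.reindex(index=list(categories), columns=years, fill_value=0)
    counts.index.name = by
    empty_years = [y for y in years if counts[y].sum() == 0]
    if empty_years:
        raise ValueError(f"no labelled records in year(s) {empty_years}; proportions undefined")
    return FrequencyTable(counts=counts, excluded=int((~valid).sum()))


def _default_categories(by: str, observed: pd.Series) -> tuple:
    fixed = {
        "season": SEASON_LABELS,
        "month": MONTH_LABELS,
        "weekday": WEEKDAY_LABELS,
        "lr3": LR3_CATEGORIES,
        "lr5": LR5_CATEGORIES,
    }
    if by in fixed:
        return fixed[by]
    return tuple(sorted(observed.unique()))


def report_rate(
    police_counts: dict[int, int], hunting_counts: dict[int, int]
) -> pd.DataFrame:
    """Report rates: police records as a percentage of hunting-bag losses.

    Hunting statistics (carcass removals per year) are taken as the 100%
    reference; the rate is 100 * police / hunting per year, plus a pooled
    row from the summed counts.  Rates are rounded to 2 decimals for
    presentation.  Raises on a zero or missing hunting count.
    """
    years = sorted(police_counts)
    if sorted(hunting_counts) != years:
        raise ValueError("police and hunting counts must cover the same years")
    rows = []
    for year in years:
        h = hunting_counts[year]
        if h <= 0:
            raise ValueError(f"hunting count for {year} must be positive")
        rows.append(
            {
                "year": str(year),
                "hunting": h,
                "police": police_counts[year],
                "rate_pct": round(100.0 * police_counts[year] / h, 2),
            }
        )
    tot_p, tot_h = sum(police_counts.values()), sum(hunting_counts.values())
    rows.append(
        {"year": "total", "hunting": tot_h, "police": tot_p,
         "rate_pct": round(100.0 * tot_p / tot_h, 2)}
    )
    return pd.DataFrame(rows)
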