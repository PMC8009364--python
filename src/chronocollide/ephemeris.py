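"""Solar and lunar ephemeris at the reference point.

The study annotated every accident with sunrise/sunset, astronomical season
and lunar "moon day" using interactive calculators; this module is that
layer as code.  Three computations live here:

* ``solar_events`` -- sunrise and sunset for a date, via the standard
  solar-position formulation (fractional year -> equation of time and solar
  declination -> hour angle at zenith 90.833 deg), evaluated in UTC and
  converted to the configured civil timezone including DST.  Accuracy is in
  the one-minute class, matching the online calculators the protocol used.
* ``lunar_state`` -- lunar age under the mean-synodic model: age is the time
  since a fixed anchor new moon (2000-01-06 18:14 UTC) modulo the synodic
  month (29.53 d); ``moon_day = floor(age) + 1`` so that the full-moon
  center (age = synodic/2 = 14.765 d) falls inside moon day 15.
* ``season_table`` / ``season_of`` -- astronomical seasons bounded by the
  actual equinox and solstice instants of each year, computed with the
  classical mean-phenomena polynomial plus its 24-term periodic correction.
  Boundary days belong to the season that begins (half-open intervals at
  day resolution in local time).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from zoneinfo import ZoneInfo

from .config import StudyConfig

__all__ = [
    "SolarDay",
    "LunarState",
    "SeasonTable",
    "solar_events",
    "lunar_state",
    "season_table",
    "season_of",
    "equinox_solstice",
    "NEW_MOON_ANCHOR",
]

UTC = dt.timezone.utc

#: Anchor new moon of the mean-synodic lunar model (a widely used epoch).
NEW_MOON_ANCHOR = dt.datetime(2000, 1, 6, 18, 14, tzinfo=UTC)

#: Supported era for lunar-age computation.
_LUNAR_ERA = (dt.datetime(1990, 1, 1, tzinfo=UTC), dt.datetime(2050, 12, 31, tzinfo=UTC))

#: Zenith for sunrise/sunset: 90 deg + 34' refraction + 16' solar semidiameter.
_SUN_ZENITH_DEG = 90.833

SEASONS = ("spring", "summer", "autumn", "winter")


@dataclass(frozen=True)
class SolarDay:
    """Sunrise/sunset for one date, with the derived twilight windows.

    All four instants are timezone-aware datetimes in the configured civil
    zone.  ``dawn_window`` is [sunrise - twilight, sunrise) and
    ``dusk_window`` is [sunset, sunset + twilight); both are half-open.
    """

    date: dt.date
    sunrise: dt.datetime
    sunset: dt.datetime
    dawn_start: dt.datetime
    dusk_end: dt.datetime

    @property
    def dawn_window(self) -> tuple[dt.datetime, dt.datetime]:
        return (self.dawn_start, self.sunrise)

    @property
    def dusk_window(self) -> tuple[dt.datetime, dt.datetime]:
        return (self.sunset, self.dusk_end)

    @property
    def day_length(self) -> dt.timedelta:
        return self.sunset - self.sunrise


@dataclass(frozen=True)
class LunarState:
    """Lunar age (days since new moon) and the derived moon day (1..30)."""

    timestamp: dt.datetime
    age_days: float
    moon_day: int


def _fractional_year(when_utc: dt.datetime) -> float:
    """Fractional year angle (radians) at a UTC instant."""
    year_days = 366.0 if _is_leap(when_utc.year) else 365.0
    doy = when_utc.timetuple().tm_yday
    hour = when_utc.hour + when_utc.minute / 60.0 + when_utc.second / 3600.0
    return 2.0 * math.pi / year_days * (doy - 1 + (hour - 12.0) / 24.0)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _equation_of_time_min(gamma: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )


def _solar_declination(gamma: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )


def _hour_angle_deg(latitude: float, decl: float) -> float:
    lat = math.radians(latitude)
    cos_ha = math.cos(math.radians(_SUN_ZENITH_DEG)) / (
        math.cos(lat) * math.cos(decl)
    ) - math.tan(lat) * math.tan(decl)
    if not -1.0 < cos_ha < 1.0:
        raise ValueError(
            "sun does not rise/set on this date at this latitude; "
            "polar day/night is unsupported"
        )
    return math.degrees(math.acos(cos_ha))


def _event_utc_minutes(date: dt.date, config: StudyConfig, rise: bool) -> float:
    """UTC minutes-of-day of sunrise (rise=True) or sunset, iterated twice."""
    minutes = 720.0 - 4.0 * config.longitude  # first guess: local solar noon
    for _ in range(2):
        when = dt.datetime(date.year, date.month, date.day, tzinfo=UTC) + dt.timedelta(
            minutes=minutes
        )
        gamma = _fractional_year(when)
        eqtime = _equation_of_time_min(gamma)
        decl = _solar_declination(gamma)
        ha = _hour_angle_deg(config.latitude, decl)
        if rise:
            minutes = 720.0 - 4.0 * (config.longitude + ha) - eqtime
        else:
            minutes = 720.0 - 4.0 * (config.longitude - ha) - eqtime
    return minutes


def solar_events(date: dt.date, config: StudyConfig) -> SolarDay:
    """Sunrise/sunset and twilight windows for ``date`` at the reference point.

    Deterministic for fixed inputs; raises ``ValueError`` at latitudes where
    the sun does not rise or set.
    """
    midnight_utc = dt.datetime(date.year, date.month, date.day, tzinfo=UTC)
    tz = config.tzinfo
    sunrise = (midnight_utc + dt.timedelta(minutes=_event_utc_minutes(date, config, True))).astimezone(tz)
    sunset = (midnight_utc + dt.timedelta(minutes=_event_utc_minutes(date, config, False))).astimezone(tz)
    twilight = dt.timedelta(minutes=config.twilight_minutes)
    return SolarDay(
        date=date,
        sunrise=sunrise,
        sunset=sunset,
        dawn_start=sunrise - twilight,
        dusk_end=sunset + twilight,
    )


def lunar_state(timestamp: dt.datetime, config: StudyConfig) -> LunarState:
    """Lunar age and moon day for a local civil timestamp.

    Naive timestamps are interpreted in the configured zone.  Age is the
    elapsed time since the anchor new moon, modulo the synodic month; moon
    day 15 therefore contains the mean full-moon instant.
    """
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=config.tzinfo)
    t_utc = timestamp.astimezone(UTC)
    if not _LUNAR_ERA[0] <= t_utc <= _LUNAR_ERA[1]:
        raise ValueError(f"timestamp {timestamp} outside the supported era 1990-2050")
    elapsed = (t_utc - NEW_MOON_ANCHOR).total_seconds() / 86400.0
    age = elapsed % config.synodic_days
    return LunarState(timestamp=timestamp, age_days=age, moon_day=int(math.floor(age)) + 1)


# ---------------------------------------------------------------------------
# Equinoxes and solstices
#
# Mean-phenomena polynomials (valid 1000-3000 CE) plus the standard 24-term
# periodic correction; the result is good to about a minute, far below the
# day resolution at which seasons are assigned.

_MEAN_JDE = {
    "march_equinox": (2451623.80984, 365242.37404, 0.05169, -0.00411, -0.00057),
    "june_solstice": (2451716.56767, 365241.62603, 0.00325, 0.00888, -0.00030),
    "september_equinox": (2451810.21715, 365242.01767, -0.11575, 0.00337, 0.00078),
    "december_solstice": (2451900.05952, 365242.74049, -0.06223, -0.00823, 0.00032),
}

# (amplitude, phase deg, rate deg per Julian century)
_PERIODIC_TERMS = (
    (485, 324.96, 1934.136), (203, 337.23, 32964.467), (199, 342.08, 20.186),
    (182, 27.85, 445267.112), (156, 73.14, 45036.886), (136, 171.52, 22518.443),
    (77, 222.54, 65928.934), (74, 296.72, 3034.906), (70, 243.58, 9037.513),
    (58, 119.81, 33718.147), (52, 297.17, 150.678), (50, 21.02, 2281.226),
    (45, 247.54, 29929.562), (44, 325.15, 31555.956), (29, 60.93, 4443.417),
    (18, 155.12, 67555.328), (17, 288.79, 4562.452), (16, 198.04, 62894.029),
    (14, 199.76, 31436.921), (12, 95.39, 14577.848), (12, 287.11, 31931.756),
    (12, 320.81, 34777.259), (9, 227.73, 1222.114), (8, 15.45, 16859.074),
)


def _jde_to_datetime(jde: float) -> dt.datetime:
    """Julian ephemeris day to UTC datetime (TT-UT difference is ~1 min,
    negligible at the day resolution seasons are used at)."""
    days = jde - 2440587.5  # JD of the Unix epoch
    return dt.datetime(1970, 1, 1, tzinfo=UTC) + dt.timedelta(days=days)


def equinox_solstice(year: int, event: str) -> dt.datetime:
    """UTC instant of one of the four season boundaries of ``year``.

    ``event`` is one of ``march_equinox``, ``june_solstice``,
    ``september_equinox``, ``december_solstice``.
    """
    if event not in _MEAN_JDE:
        raise ValueError(f"unknown event {event!r}")
    if not 1000 <= year <= 3000:
        raise ValueError("season computation valid for years 1000-3000")
    a0, a1, a2, a3, a4 = _MEAN_JDE[event]
    y = (year - 2000) / 1000.0
    jde0 = a0 + a1 * y + a2 * y**2 + a3 * y**3 + a4 * y**4
    t = (jde0 - 2451545.0) / 36525.0
    w = math.radians(35999.373 * t - 2.47)
    dlam = 1.0 + 0.0334 * math.cos(w) + 0.0007 * math.cos(2 * w)
    s = sum(a * math.cos(math.radians(b + c * t)) for a, b, c in _PERIODIC_TERMS)
    return _jde_to_datetime(jde0 + 0.00001 * s / dlam)


@dataclass(frozen=True)
class SeasonTable:
    """Local season-boundary dates for a set of years.

    ``boundaries[year]`` maps each of the four events to its local calendar
    date at the reference point; lookups cover the configured years plus the
    winter wrap into the first configured year.
    """

    boundaries: dict
    timezone: str

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.boundaries))


def season_table(years, config: StudyConfig) -> SeasonTable:
    """Compute season-boundary local dates for ``years`` (plus the preceding
    year, so winter wrapping the year boundary resolves)."""
    tz = config.tzinfo
    all_years = sorted(set(years) | {min(years) - 1})
    boundaries = {}
    for year in all_years:
        boundaries[year] = {
            event: equinox_solstice(year, event).astimezone(tz).date()
            for event in _MEAN_JDE
        }
    return SeasonTable(boundaries=boundaries, timezone=config.timezone)


def season_of(date: dt.date, seasons: SeasonTable) -> str:
    """Astronomical season of a local calendar date.

    Half-open intervals: the boundary date belongs to the season that
    begins on it.  Raises ``KeyError`` for years the table does not cover.
    """
    if date.year not in seasons.boundaries:
        raise KeyError(f"year {date.year} not covered by the season table")
    b = seasons.boundaries[date.year]
    if date < b["march_equinox"]:
        return "winter"
    if date < b["june_solstice"]:
        return "spring"
    if date < b["september_equinox"]:
        return "summer"
    if date < b["december_solstice"]:
        return "autumn"
    return "winter"
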