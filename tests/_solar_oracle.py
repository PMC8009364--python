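"""Independent sunrise/sunset oracle for the ephemeris tests.

Classical ecliptic-longitude solar position (mean longitude and anomaly ->
equation of center -> apparent longitude -> right ascension/declination),
combined with Greenwich sidereal time to get the sun's altitude on a
minute grid; rise and set are the interpolated crossings of altitude
-0.833 deg.  This is a different algorithmic path from the package's
equation-of-time/hour-angle formulation, so agreement is a genuine
cross-check, not a tautology.  Accuracy is well under a minute at
mid-latitudes.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

_UTC = dt.timezone.utc
_ALT_EVENT_DEG = -0.833  # refraction + solar semidiameter


def _julian_day(when: dt.datetime) -> float:
    return when.timestamp() / 86400.0 + 2440587.5


def _sun_radec(jd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apparent right ascension and declination (radians) of the sun."""
    t = (jd - 2451545.0) / 36525.0
    l0 = np.deg2rad(np.mod(280.46646 + 36000.76983 * t + 0.0003032 * t**2, 360.0))
    m = np.deg2rad(np.mod(357.52911 + 35999.05029 * t - 0.0001537 * t**2, 360.0))
    c = (
        (1.914602 - 0.004817 * t - 0.000014 * t**2) * np.sin(m)
        + (0.019993 - 0.000101 * t) * np.sin(2 * m)
        + 0.000289 * np.sin(3 * m)
    )
    true_lon = l0 + np.deg2rad(c)
    omega = np.deg2rad(125.04 - 1934.136 * t)
    app_lon = true_lon - np.deg2rad(0.00569 + 0.00478 * np.sin(omega))
    eps = np.deg2rad(
        23.4392911 - 0.0130042 * t - 1.64e-7 * t**2 + 0.00256 * np.cos(omega)
    )
    ra = np.arctan2(np.cos(eps) * np.sin(app_lon), np.cos(app_lon))
    dec = np.arcsin(np.sin(eps) * np.sin(app_lon))
    return ra, dec


def _sun_altitude_deg(jd: np.ndarray, latitude: float, longitude: float) -> np.ndarray:
    ra, dec = _sun_radec(jd)
    t = (jd - 2451545.0) / 36525.0
    gmst = np.mod(
        280.46061837 + 360.98564736629 * (jd - 2451545.0) + 0.000387933 * t**2, 360.0
    )
    hour_angle = np.deg2rad(gmst + longitude) - ra
    lat = np.deg2rad(latitude)
    alt = np.arcsin(
        np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(hour_angle)
    )
    return np.rad2deg(alt)


def sun_events_utc(
    date: dt.date, latitude: float, longitude: float
) -> tuple[dt.datetime, dt.datetime]:
    """(sunrise, sunset) as UTC datetimes, by altitude-crossing search."""
    start = dt.datetime(date.year, date.month, date.day, tzinfo=_UTC)
    jd0 = _julian_day(start)
    minutes = np.arange(0.0, 1441.0)
    alt = _sun_altitude_deg(jd0 + minutes / 1440.0, latitude, longitude)
    above = alt > _ALT_EVENT_DEG
    crossings_up = np.flatnonzero(~above[:-1] & above[1:])
    crossings_down = np.flatnonzero(above[:-1] & ~above[1:])
    if len(crossings_up) != 1 or len(crossings_down) != 1:
        raise ValueError(f"no unique sunrise/sunset on {date} at {latitude}N")

    def _interp(i: int) -> dt.datetime:
        frac = (_ALT_EVENT_DEG - alt[i]) / (alt[i + 1] - alt[i])
        return start + dt.timedelta(minutes=float(i + frac))

    return _interp(int(crossings_up[0])), _interp(int(crossings_down[0]))


def max_event_error_minutes(dates, solar_days, latitude: float, longitude: float) -> float:
    """Largest |package event - oracle event| in minutes over ``dates``."""
    worst = 0.0
    for date, solar in zip(dates, solar_days):
        rise_ref, set_ref = sun_events_utc(date, latitude, longitude)
        for ours, ref in ((solar.sunrise, rise_ref), (solar.sunset, set_ref)):
            err = abs((ours.astimezone(_UTC) - ref).total_seconds()) / 60.0
            worst = max(worst, err)
    return worst
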