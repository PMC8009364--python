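"""Study configuration.

All temporal computations in the package are anchored to a single reference
point (a latitude/longitude and an IANA timezone).  The defaults describe the
original study setting: Eisenstadt, the capital of Burgenland (Austria),
with police-reported local civil time (CET/CEST), a 40-minute operational
civil-twilight window, and the 29.53-day mean synodic month.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from zoneinfo import ZoneInfo

__all__ = ["StudyConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class StudyConfig:
    """Run configuration shared by every analysis stage.

    Parameters
    ----------
    latitude, longitude : float
        Reference point in degrees (north/east positive).  Latitudes beyond
        |66| deg are rejected: sunrise and sunset must exist on every date.
    timezone : str
        IANA zone of the clock the accident times were recorded in.
    twilight_minutes : int
        Length of the operational dawn and dusk windows, minutes before
        sunrise and after sunset respectively.
    synodic_days : float
        Mean synodic month used for the moon-day classification.
    study_years : tuple[int, ...]
        Calendar years covered; records outside are rejected at ingest.
    target_species : str
        Species label retained at ingest (case-insensitive exact match).
    drop_moon_day_30 : bool
        Remove the partial moon day 30 (the synodic month is shorter than
        30 days) before smoothing, as the study protocol prescribes.
    rng_seed : int
        Seed for any randomized step configured from this object.
    """

    latitude: float = 47.85
    longitude: float = 16.52
    timezone: str = "Europe/Vienna"
    twilight_minutes: int = 40
    synodic_days: float = 29.53
    study_years: tuple[int, ...] = (2002, 2003, 2004, 2005, 2006)
    target_species: str = "roe deer"
    drop_moon_day_30: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not -66.0 < self.latitude < 66.0:
            raise ValueError(
                f"latitude {self.latitude} outside (-66, 66): sunrise/sunset "
                "must exist on every date; polar latitudes are unsupported"
            )
        if self.twilight_minutes <= 0:
            raise ValueError("twilight_minutes must be positive")
        if not 29.0 < self.synodic_days < 30.0:
            raise ValueError("synodic_days must lie in (29, 30)")
        if not self.study_years:
            raise ValueError("study_years must be non-empty")
        ZoneInfo(self.timezone)  # raises for unknown zone ids

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)

    def replace(self, **kwargs) -> "StudyConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = StudyConfig()
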