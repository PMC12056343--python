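"""Sunrise/sunset computation and diel analysis windows.

Sunrise and sunset are computed with the NOAA solar-position equations
(Meeus-style truncated series as used in the NOAA solar calculator), at the
standard zenith of 90.833 deg (atmospheric refraction plus the solar radius),
which matches common civil sunrise/sunset tables.  Accuracy for mid-latitude
sites is well under a minute against reference ephemerides, which is ample
for 3-min telemetry grids.

All windows are built in the site's civil local time (DST-aware); the
underlying instants are absolute, so slicing a UTC-spaced 3-min grid with
these windows is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "SolarDay",
    "AnalysisWindows",
    "UnsupportedLatitudeError",
    "solar_times",
    "build_windows",
    "relative_time",
    "solar_table",
]

#: Zenith angle (degrees) defining sunrise/sunset: 90 deg + refraction (34')
#: + solar semi-diameter (16').
SUNRISE_ZENITH_DEG = 90.833

#: Latitude bound beyond which polar day/night can occur for this zenith.
MAX_ABS_LATITUDE_DEG = 66.5


class UnsupportedLatitudeError(ValueError):
    """Raised for latitudes where polar day/night would occur."""


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset for one site and calendar date (local time)."""

    site_id: str
    date: _date
    sunrise: pd.Timestamp
    sunset: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.sunrise < self.sunset:
            raise ValueError("sunrise must precede sunset")


@dataclass(frozen=True)
class AnalysisWindows:
    """The four half-open analysis windows [start, end) for one site-date.

    onset_window    : [sunrise - 4 h, sunrise + 2 h)   (6 h)
    end_window      : [sunset - 4 h, sunset + 4 h)     (8 h)
    diurnal_window  : [10:00, 16:00) local clock       (6 h)
    nocturnal_window: [22:00 on d, 02:00 on d+1) local (4 h), keyed to date d
    """

    onset_window: tuple[pd.Timestamp, pd.Timestamp]
    end_window: tuple[pd.Timestamp, pd.Timestamp]
    diurnal_window: tuple[pd.Timestamp, pd.Timestamp]
    nocturnal_window: tuple[pd.Timestamp, pd.Timestamp]


def _julian_day(ts: pd.Timestamp) -> float:
    """Julian day number (UT) for a timezone-aware or UTC timestamp."""
    ts = ts.tz_convert("UTC") if ts.tzinfo is not None else ts.tz_localize("UTC")
    # Unix epoch 1970-01-01 00:00 UTC is JD 2440587.5
    return 2440587.5 + ts.value / 1e9 / 86400.0


def _solar_coordinates(jc: float) -> tuple[float, float]:
    """Return (declination deg, equation of time minutes) at Julian century jc."""
    geom_mean_long = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    m = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * math.cos(math.radians(omega))

    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq_corr)) * math.sin(math.radians(app_long)))
    )

    var_y = math.tan(math.radians(obliq_corr / 2.0)) ** 2
    l0 = math.radians(geom_mean_long)
    eot = 4.0 * math.degrees(
        var_y * math.sin(2 * l0)
        - 2.0 * ecc * math.sin(m)
        + 4.0 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y**2 * math.sin(4 * l0)
        - 1.25 * ecc**2 * math.sin(2 * m)
    )
    return decl, eot


def _hour_angle_deg(lat: float, decl: float) -> float:
    cos_ha = (
        math.cos(math.radians(SUNRISE_ZENITH_DEG))
        / (math.cos(math.radians(lat)) * math.cos(math.radians(decl)))
        - math.tan(math.radians(lat)) * math.tan(math.radians(decl))
    )
    if not -1.0 < cos_ha < 1.0:
        raise UnsupportedLatitudeError(
            f"no sunrise/sunset at latitude {lat:.2f} for this date (polar day/night)"
        )
    return math.degrees(math.acos(cos_ha))


def solar_times(
    lat: float, lon: float, date: _date, tz: str, site_id: str = ""
) -> SolarDay:
    """Sunrise and sunset for one site-date, in the site's civil local time.

    Parameters
    ----------
    lat, lon : degrees; longitude positive east.
    date : calendar date in the site's timezone.
    tz : IANA timezone name (e.g. ``"Europe/London"``).

    Raises
    ------
    UnsupportedLatitudeError
        if ``|lat| >= 66.5`` or no sunrise/sunset exists on that date.
    """
    if abs(lat) >= MAX_ABS_LATITUDE_DEG:
        raise UnsupportedLatitudeError(
            f"latitude {lat:.2f} not supported (|lat| >= {MAX_ABS_LATITUDE_DEG})"
        )

    # Iterate: solar noon at the site, then declination/EoT at event times.
    noon_utc_minutes = 720.0 - 4.0 * lon
    base = pd.Timestamp(date).tz_localize("UTC")

    sunrise_min = noon_utc_minutes - 4.0 * 90.0  # initial guess
    sunset_min = noon_utc_minutes + 4.0 * 90.0
    for _ in range(3):
        jc_rise = (_julian_day(base + pd.Timedelta(minutes=sunrise_min)) - 2451545.0) / 36525.0
        decl, eot = _solar_coordinates(jc_rise)
        ha = _hour_angle_deg(lat, decl)
        sunrise_min = 720.0 - 4.0 * (lon + ha) - eot

        jc_set = (_julian_day(base + pd.Timedelta(minutes=sunset_min)) - 2451545.0) / 36525.0
        decl, eot = _solar_coordinates(jc_set)
        ha = _hour_angle_deg(lat, decl)
        sunset_min = 720.0 - 4.0 * (lon - ha) - eot

    sunrise = (base + pd.Timedelta(minutes=sunrise_min)).tz_convert(tz)
    sunset = (base + pd.Timedelta(minutes=sunset_min)).tz_convert(tz)
    return SolarDay(site_id=site_id, date=date, sunrise=sunrise, sunset=sunset)


def _local_clock(date: _date, hour: int, tz: str) -> pd.Timestamp:
    """A local wall-clock instant, resolving DST folds to the first occurrence."""
    ts = pd.Timestamp(date) + pd.Timedelta(hours=hour)
    return ts.tz_localize(tz, ambiguous=True, nonexistent="shift_forward")


def build_windows(solar_day: SolarDay) -> AnalysisWindows:
    """Build the four half-open analysis windows for one site-date."""
    tz = str(solar_day.sunrise.tz)
    d = solar_day.date
    h = pd.Timedelta(hours=1)
    onset = (solar_day.sunrise - 4 * h, solar_day.sunrise + 2 * h)
    end = (solar_day.sunset - 4 * h, solar_day.sunset + 4 * h)
    if onset[1] > end[0]:
        import warnings

        warnings.warn(
            f"onset and end windows overlap on {d} at site {solar_day.site_id!r}; "
            "day length is shorter than 6 h between anchors",
            stacklevel=2,
        )
    diurnal = (_local_clock(d, 10, tz), _local_clock(d, 16, tz))
    nocturnal = (
        _local_clock(d, 22, tz),
        _local_clock(d + pd.Timedelta(days=1), 2, tz),
    )
    return AnalysisWindows(
        onset_window=onset,
        end_window=end,
        diurnal_window=diurnal,
        nocturnal_window=nocturnal,
    )


def relative_time(event: pd.Timestamp, anchor: pd.Timestamp) -> float:
    """(event - anchor) in hours; negative means the event precedes the anchor."""
    return (event - anchor).total_seconds() / 3600.0


def solar_table(sites: pd.DataFrame, dates: "list[_date]") -> pd.DataFrame:
    """Sunrise/sunset for every (site, date) pair.

    ``sites`` needs columns site_id, latitude, longitude, timezone.
    """
    rows = []
    for site in sites.itertuples(index=False):
        for d in dates:
            sd = solar_times(site.latitude, site.longitude, d, site.timezone, site.site_id)
            rows.append(
                {
                    "site_id": site.site_id,
                    "date": d,
                    "sunrise": sd.sunrise,
                    "sunset": sd.sunset,
                }
            )
    return pd.DataFrame(rows)
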