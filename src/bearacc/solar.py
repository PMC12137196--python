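"""Sunrise/sunset from the NOAA solar-position equations.

Implements the standard NOAA spreadsheet algorithm (Meeus-based low-precision
ephemeris): Julian century, solar geometric mean longitude/anomaly, equation
of center, obliquity with nutation correction, declination, equation of time,
and the sunrise hour angle at a configurable zenith (default 90.833°, i.e.
apparent sunrise including refraction and the solar semi-diameter). Accuracy
is on the order of a minute at temperate latitudes, ample for delimiting
daily activity and legal-hour intervals.
"""

from __future__ import annotations

import datetime as dt
import math


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_parameters(jc: float) -> tuple[float, float]:
    """(declination in degrees, equation of time in minutes) at Julian century jc."""
    geom_mean_long = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m_rad = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(m_rad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m_rad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m_rad) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23 + (26 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60) / 60
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )
    var_y = math.tan(math.radians(obliq / 2)) ** 2
    eot = 4 * math.degrees(
        var_y * math.sin(2 * math.radians(geom_mean_long))
        - 2 * ecc * math.sin(m_rad)
        + 4 * ecc * var_y * math.sin(m_rad) * math.cos(2 * math.radians(geom_mean_long))
        - 0.5 * var_y**2 * math.sin(4 * math.radians(geom_mean_long))
        - 1.25 * ecc**2 * math.sin(2 * m_rad)
    )
    return decl, eot


def sunrise_sunset(
    date: dt.date,
    lat: float,
    lon: float,
    utc_offset_h: float,
    zenith: float = 90.833,
) -> tuple[dt.datetime, dt.datetime]:
    """Local (naive) sunrise and sunset datetimes for one calendar date.

    Parameters
    ----------
    date
        Calendar date in the local time zone.
    lat, lon
        Degrees north / east (east positive).
    utc_offset_h
        Fixed local offset from UTC in hours (e.g. +2 for Sweden in summer).
    zenith
        Solar zenith angle defining rise/set; 90.833° is apparent sunrise.

    Raises
    ------
    ValueError
        If the sun never reaches the zenith on that date (polar day/night).
    """
    jd = _julian_day(date) + 0.5 - utc_offset_h / 24.0  # local noon, in UT
    jc = (jd - 2451545.0) / 36525.0
    decl, eot = _solar_parameters(jc)
    lat_r, decl_r = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(zenith)) - math.sin(lat_r) * math.sin(decl_r)
    ) / (math.cos(lat_r) * math.cos(decl_r))
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(
            f"sun does not cross zenith {zenith} deg at lat {lat} on {date} (polar day/night)"
        )
    ha = math.degrees(math.acos(cos_ha))
    solar_noon_min = 720.0 - 4.0 * lon - eot + utc_offset_h * 60.0
    rise_min = solar_noon_min - 4.0 * ha
    set_min = solar_noon_min + 4.0 * ha
    midnight = dt.datetime.combine(date, dt.time())
    return (
        midnight + dt.timedelta(minutes=rise_min),
        midnight + dt.timedelta(minutes=set_min),
    )
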