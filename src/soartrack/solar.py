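"""Sunrise/sunset from the NOAA solar-position algorithm.

Standard civil sunrise/sunset (zenith 90.833°, i.e. including the usual
atmospheric-refraction and solar-radius allowance), computed from
longitude/latitude for a given UTC date.  Accuracy is a couple of minutes,
ample for flagging whether a tracking day covers the full daylight period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_ZENITH_DEG = 90.833


def _solar_params(day: pd.Timestamp):
    # NOAA general solar position calculations, evaluated at solar noon
    jd = day.to_julian_date() + 0.5  # noon of the civil date
    t = (jd - 2451545.0) / 36525.0
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mrad = np.radians(m)
    c = (np.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
         + np.sin(2 * mrad) * (0.019993 - 0.000101 * t)
         + np.sin(3 * mrad) * 0.000289)
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    lam = true_long - 0.00569 - 0.00478 * np.sin(np.radians(omega))
    eps0 = 23 + (26 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60) / 60
    eps = eps0 + 0.00256 * np.cos(np.radians(omega))
    decl = np.degrees(np.arcsin(np.sin(np.radians(eps)) * np.sin(np.radians(lam))))
    y = np.tan(np.radians(eps / 2)) ** 2
    eccent = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    eqtime = 4 * np.degrees(
        y * np.sin(2 * np.radians(l0))
        - 2 * eccent * np.sin(mrad)
        + 4 * eccent * y * np.sin(mrad) * np.cos(2 * np.radians(l0))
        - 0.5 * y * y * np.sin(4 * np.radians(l0))
        - 1.25 * eccent * eccent * np.sin(2 * mrad))
    return decl, eqtime  # degrees, minutes


def sunrise_sunset(day, lon: float, lat: float) -> tuple[pd.Timestamp, pd.Timestamp]:
    """UTC sunrise and sunset for the civil date of ``day`` at (lon, lat).

    Raises ValueError in polar day/night conditions.
    """
    day = pd.Timestamp(day).normalize()
    decl, eqtime = _solar_params(day)
    latr, declr = np.radians(lat), np.radians(decl)
    cos_ha = (np.cos(np.radians(_ZENITH_DEG)) / (np.cos(latr) * np.cos(declr))
              - np.tan(latr) * np.tan(declr))
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("sun does not rise/set at this latitude and date")
    ha = np.degrees(np.arccos(cos_ha))  # degrees
    solar_noon_min = 720.0 - 4.0 * lon - eqtime
    rise = day + pd.Timedelta(minutes=solar_noon_min - 4.0 * ha)
    sett = day + pd.Timedelta(minutes=solar_noon_min + 4.0 * ha)
    return rise.round("s"), sett.round("s")
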