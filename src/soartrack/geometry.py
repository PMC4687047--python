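"""Local planar geometry for short-range trajectory work.

All distances in this package are computed on a local equirectangular
(plate carrée) plane anchored at a reference point, usually the colony.
For a central-place forager whose trips stay within a few tens of
kilometres of the anchor the projection error relative to great-circle
distances is far below GPS noise (< 0.1 % for steps under 5 km at
mid-latitudes), which keeps the geometry dependency-free.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def local_xy(lon, lat, origin_lon: float, origin_lat: float):
    """Project lon/lat (degrees) to planar metres about an origin.

    x points east, y points north.  Valid for points within ~100 km of
    the origin.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    coslat0 = np.cos(np.radians(origin_lat))
    x = EARTH_RADIUS_M * coslat0 * np.radians(lon - origin_lon)
    y = EARTH_RADIUS_M * np.radians(lat - origin_lat)
    return x, y


def inverse_local_xy(x, y, origin_lon: float, origin_lat: float):
    """Inverse of :func:`local_xy`: planar metres back to lon/lat degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coslat0 = np.cos(np.radians(origin_lat))
    lon = origin_lon + np.degrees(x / (EARTH_RADIUS_M * coslat0))
    lat = origin_lat + np.degrees(y / EARTH_RADIUS_M)
    return lon, lat


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres (used as an independent check)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def heading_deg(dx, dy):
    """Compass heading of a displacement: degrees clockwise from north, [0, 360)."""
    h = np.degrees(np.arctan2(np.asarray(dx, float), np.asarray(dy, float)))
    return np.mod(h, 360.0)


def wrap_angle_deg(a):
    """Wrap angle differences into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = np.mod(a, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 to +180 so the interval is half-open on the left
    return np.where(wrapped == -180.0, 180.0, wrapped)


def circular_moving_average_deg(headings, half_window: int):
    """Smooth a heading series (degrees) with a centred circular moving average.

    Averaging is done on the unit circle so that e.g. 350° and 10° average
    to 0° rather than 180°.  ``half_window`` is in samples; 0 disables.
    """
    h = np.radians(np.asarray(headings, dtype=float))
    if half_window <= 0 or h.size < 3:
        return np.degrees(h) % 360.0
    w = 2 * half_window + 1
    kernel = np.ones(w) / w
    # pad with edge values so endpoints keep their local direction
    s = np.pad(np.sin(h), half_window, mode="edge")
    c = np.pad(np.cos(h), half_window, mode="edge")
    sm = np.convolve(s, kernel, mode="valid")
    cm = np.convolve(c, kernel, mode="valid")
    return np.degrees(np.arctan2(sm, cm)) % 360.0
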