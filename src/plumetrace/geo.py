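"""Spherical-Earth geodesy helpers shared by the track and dispersion code.

All distances are in meters on a sphere of radius 6,371 km; bearings are
degrees clockwise from geographic North in [0, 360).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
#: meters per degree of latitude (2*pi*R/360, rounded to the value used
#: throughout the meter<->degree conversions of the dispersion stepper)
M_PER_DEG_LAT = 111_195.0


def wrap360(angle_deg):
    """Map angles to [0, 360)."""
    return np.mod(angle_deg, 360.0)


def wrap_signed(angle_deg):
    """Map angles to the signed branch (-180, 180]."""
    a = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) - 180.0
    # mod maps exact +180 to -180; put it back on the +180 side
    a = np.where(a == -180.0, 180.0, a)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return float(a)
    return a


def gc_distance(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in meters (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def bearing(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360).

    Raises ``ValueError`` for coincident points (bearing undefined).
    """
    if np.ndim(lon1) == 0 and lon1 == lon2 and lat1 == lat2:
        raise ValueError("bearing undefined for coincident points")
    lon1r, lat1r, lon2r, lat2r = (np.radians(np.asarray(x, dtype=float))
                                  for x in (lon1, lat1, lon2, lat2))
    dlon = lon2r - lon1r
    y = np.sin(dlon) * np.cos(lat2r)
    x = np.cos(lat1r) * np.sin(lat2r) - np.sin(lat1r) * np.cos(lat2r) * np.cos(dlon)
    b = wrap360(np.degrees(np.arctan2(y, x)))
    if np.ndim(b) == 0:
        return float(b)
    return b


def destination(lon, lat, bearing_deg, distance_m):
    """Great-circle destination point from (lon, lat) along a bearing."""
    delta = distance_m / EARTH_RADIUS_M
    theta = np.radians(bearing_deg)
    lat1 = np.radians(lat)
    lon1 = np.radians(lon)
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta) +
                     np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    lon2d = wrap_signed(np.degrees(lon2))
    return lon2d, float(np.degrees(lat2)) if np.ndim(lat2) == 0 else np.degrees(lat2)


def circular_mean_deg(angles_deg, weights=None):
    """Mean direction (deg in [0,360)) and resultant length r of a sample of angles."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if weights is None:
        c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        c, s = np.sum(w * np.cos(a)), np.sum(w * np.sin(a))
    r = float(np.hypot(c, s))
    mean = float(wrap360(np.degrees(np.arctan2(s, c))))
    return mean, r
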