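"""Spherical geometry helpers for GPS tracks.

All coordinates are WGS84 decimal degrees; distances are great-circle
(haversine) on a sphere of radius 6371.0088 km, which is accurate to ~0.5%
— far below any threshold used in track classification.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km. Accepts scalars or numpy arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_interpolate(lat1: float, lon1: float, lat2: float, lon2: float, fracs):
    """Points along the great circle from (lat1,lon1) to (lat2,lon2).

    ``fracs`` are fractions of the arc in [0, 1]. Returns (lats, lons) arrays.
    Uses spherical linear interpolation on unit vectors.
    """
    fracs = np.asarray(fracs, dtype=float)

    def to_xyz(lat, lon):
        la, lo = np.radians(lat), np.radians(lon)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])

    p1, p2 = to_xyz(lat1, lon1), to_xyz(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(p1, p2), -1.0, 1.0))
    if omega < 1e-12:
        lats = np.full_like(fracs, lat1)
        lons = np.full_like(fracs, lon1)
        return lats, lons
    s = np.sin(omega)
    pts = (np.sin((1 - fracs)[:, None] * omega) * p1[None, :] + np.sin(fracs[:, None] * omega) * p2[None, :]) / s
    lats = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lons = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    return lats, lons


def offset_point(lat: float, lon: float, dx_m, dy_m):
    """Displace a point by metres east (dx) and north (dy).

    Local equirectangular approximation — valid for the sub-km offsets used
    for GPS noise and foraging excursions.
    """
    dlat = np.asarray(dy_m, dtype=float) / 111_194.9
    dlon = np.asarray(dx_m, dtype=float) / (111_194.9 * max(np.cos(np.radians(lat)), 1e-6))
    return lat + dlat, lon + dlon
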