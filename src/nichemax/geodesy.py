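"""Spherical-earth geometry shared across the package.

All distances use a single authoritative sphere radius (the IUGG mean
radius, 6371.0088 km) so that thinning distances, cell areas and centroid
migration are mutually consistent.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM: float = 6371.0088
"""Mean earth radius in km, used by every great-circle computation."""

KM_PER_DEGREE_LAT: float = 2.0 * np.pi * EARTH_RADIUS_KM / 360.0
"""Arc length of one degree of latitude (≈ 111.195 km)."""


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between (lon, lat) points in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal / coincident points
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def initial_bearing_deg(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Initial great-circle bearing from point 1 to point 2, in [0, 360).

    0° = north, 90° = east.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlon = np.radians(lon2 - lon1)
    y = np.sin(dlon) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlon)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def band_area_km2(lat_bottom_deg, lat_top_deg, dlon_deg) -> np.ndarray | float:
    """Area in km² of a lon/lat rectangle on the sphere.

    A = R² · Δλ · (sin φ_top − sin φ_bottom); depends on latitude only
    through the sine difference, so equal-latitude cells have equal area.
    """
    dlam = np.radians(np.asarray(dlon_deg, dtype=float))
    s = np.sin(np.radians(np.asarray(lat_top_deg, dtype=float))) - np.sin(
        np.radians(np.asarray(lat_bottom_deg, dtype=float)))
    a = EARTH_RADIUS_KM ** 2 * dlam * s
    return a if np.ndim(a) else float(a)
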