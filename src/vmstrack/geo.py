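"""Spherical-earth geometry helpers shared across the package.

All distances are great-circle distances on a sphere of mean radius
R = 6371.0088 km; positions are WGS84 decimal degrees, speeds are knots
(1 kn = 1.852 km/h).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0  # length of one degree of arc
KNOT_KMH = 1.852  # international nautical mile per hour, in km/h


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (vectorised).

    Accepts scalars or numpy arrays in decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def knots_to_deg_per_s(speed_kn: float, heading_deg: float, lat_deg: float) -> tuple[float, float]:
    """Convert a (speed, heading) velocity to (dlon/dt, dlat/dt) in degrees/second.

    The east component is scaled by cos(latitude) so that the implied ground
    speed matches the reported speed at that latitude.
    """
    v_km_s = speed_kn * KNOT_KMH / 3600.0
    h = np.radians(heading_deg)
    dlat = v_km_s * np.cos(h) / KM_PER_DEG
    coslat = np.cos(np.radians(lat_deg))
    dlon = v_km_s * np.sin(h) / (KM_PER_DEG * coslat) if coslat > 1e-12 else 0.0
    return dlon, dlat


def deg_per_s_to_knots(dlon_dt: float, dlat_dt: float, lat_deg: float) -> tuple[float, float]:
    """Inverse of :func:`knots_to_deg_per_s`: velocity in degree space -> (knots, heading)."""
    ve = dlon_dt * KM_PER_DEG * np.cos(np.radians(lat_deg))  # km/s east
    vn = dlat_dt * KM_PER_DEG  # km/s north
    speed_kn = float(np.hypot(ve, vn) * 3600.0 / KNOT_KMH)
    heading = float(np.degrees(np.arctan2(ve, vn)) % 360.0)
    return speed_kn, heading
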