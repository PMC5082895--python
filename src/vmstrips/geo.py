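"""Great-circle geometry on a spherical Earth.

All distances are in nautical miles (nmi), speeds in knots, angles in
decimal degrees.  The sphere radius is fixed at 6371 km, the conventional
mean Earth radius; at subarctic latitudes the difference from a geodesic
computation is well below half a percent, which is far smaller than the
positional noise of 30-minute vessel fixes.  The whole package pins this
one convention so that distances computed in different modules agree
exactly.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_NMI = 1.852

_R_NMI = EARTH_RADIUS_KM / KM_PER_NMI  # sphere radius in nautical miles


def nmi_to_km(nmi):
    """Convert nautical miles to kilometres (1 nmi = 1.852 km)."""
    return np.asarray(nmi, dtype=float) * KM_PER_NMI


def knots_to_kph(knots):
    """Convert knots (nmi/h) to kilometres per hour."""
    return np.asarray(knots, dtype=float) * KM_PER_NMI


def haversine_nmi(lat1, lon1, lat2, lon2):
    """Great-circle distance between points, in nautical miles.

    Inputs may be scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return _R_NMI * 2.0 * np.arcsin(np.sqrt(a))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination(lat, lon, bearing_deg, dist_nmi):
    """Dead-reckoned destination along a great circle.

    Returns (lat, lon) in decimal degrees after travelling ``dist_nmi``
    from (lat, lon) on the given initial bearing.
    """
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(dist_nmi, dtype=float) / _R_NMI
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    lon2 = (lon2 + np.pi) % (2.0 * np.pi) - np.pi
    return np.degrees(lat2), np.degrees(lon2)


def gc_interpolate(lat1, lon1, lat2, lon2, fracs):
    """Points along the great circle from point 1 to point 2.

    ``fracs`` is an array of fractions in [0, 1] of the total arc; the
    interpolation is a spherical linear interpolation (slerp), so every
    returned point lies exactly on the connecting great circle.
    """
    fracs = np.asarray(fracs, dtype=float)
    p1 = _to_unit(lat1, lon1)
    p2 = _to_unit(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(p1, p2), -1.0, 1.0))
    if omega < 1e-12:
        lat = np.full_like(fracs, float(lat1))
        lon = np.full_like(fracs, float(lon1))
        return lat, lon
    s = np.sin(omega)
    a = np.sin((1.0 - fracs) * omega) / s
    b = np.sin(fracs * omega) / s
    v = a[:, None] * p1[None, :] + b[:, None] * p2[None, :]
    return _from_unit(v)


def polyline_nmi(lats, lons):
    """Total length of the polyline through the given vertices, in nmi."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2:
        return 0.0
    return float(np.sum(haversine_nmi(lats[:-1], lons[:-1], lats[1:], lons[1:])))


def _to_unit(lat, lon):
    lat = np.radians(float(lat))
    lon = np.radians(float(lon))
    return np.array([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)])


def _from_unit(v):
    lat = np.degrees(np.arcsin(np.clip(v[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return lat, lon
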