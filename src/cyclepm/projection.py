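"""Transforms between WGS84 geographic and Dutch RD New (EPSG:28992) planar
coordinates.

The analysis grids are metric, so geographic positions must be projected to a
planar system in metres.  For the Dutch study area the national
Rijksdriehoek ("RD New") grid is the natural choice.  The implementation uses
the well-known polynomial approximation of the official RDNAPTRANS
transformation (Schreutelkamp & Strang van Hees, 2001), which is accurate to
a few decimetres within the Netherlands -- far below the 25 m analysis cell
size.  Both directions are provided so synthetic campaigns generated in
planar metres can be written as lat/lon and re-projected on ingest.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rd_to_wgs84", "wgs84_to_rd", "haversine_m", "EARTH_RADIUS_M"]

EARTH_RADIUS_M = 6_371_000.0

# Base point: Onze Lieve Vrouwetoren, Amersfoort.
_X0 = 155_000.0
_Y0 = 463_000.0
_PHI0 = 52.15517440  # degrees north
_LAM0 = 5.38720621   # degrees east

# RD -> WGS84: (p, q, coefficient); terms are coeff * dX**p * dY**q, result
# in seconds of arc relative to the base point.
_K_PHI = [
    (0, 1, 3235.65389), (2, 0, -32.58297), (0, 2, -0.24750),
    (2, 1, -0.84978), (0, 3, -0.06550), (2, 2, -0.01709),
    (1, 0, -0.00738), (4, 0, 0.00530), (2, 3, -0.00039),
    (4, 1, 0.00033), (1, 1, -0.00012),
]
_L_LAM = [
    (1, 0, 5260.52916), (1, 1, 105.94684), (1, 2, 2.45656),
    (3, 0, -0.81885), (1, 3, 0.05594), (3, 1, -0.05607),
    (0, 1, 0.01199), (3, 2, -0.00256), (1, 4, 0.00128),
    (0, 2, 0.00022), (2, 0, -0.00022), (5, 0, 0.00026),
]

# WGS84 -> RD: terms are coeff * dphi**p * dlam**q, result in metres.
_R_X = [
    (0, 1, 190094.945), (1, 1, -11832.228), (2, 1, -114.221),
    (0, 3, -32.391), (1, 0, -0.705), (3, 1, -2.340),
    (1, 3, -0.608), (0, 2, -0.008), (2, 3, 0.148),
]
_S_Y = [
    (1, 0, 309056.544), (0, 2, 3638.893), (2, 0, 73.077),
    (1, 2, -157.984), (3, 0, 59.788), (0, 1, 0.433),
    (2, 2, -6.439), (1, 1, -0.032), (0, 4, 0.092), (1, 4, -0.054),
]


def _poly(terms, u, v):
    out = np.zeros(np.broadcast(u, v).shape)
    for p, q, c in terms:
        out += c * u**p * v**q
    return out


def rd_to_wgs84(x, y):
    """Convert RD New easting/northing (metres) to WGS84 (lat, lon) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = (x - _X0) * 1e-5
    dy = (y - _Y0) * 1e-5
    lat = _PHI0 + _poly(_K_PHI, dx, dy) / 3600.0
    lon = _LAM0 + _poly(_L_LAM, dx, dy) / 3600.0
    return lat, lon


def wgs84_to_rd(lat, lon):
    """Convert WGS84 (lat, lon) degrees to RD New easting/northing (metres)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dphi = 0.36 * (lat - _PHI0)
    dlam = 0.36 * (lon - _LAM0)
    x = _X0 + _poly(_R_X, dphi, dlam)
    y = _Y0 + _poly(_S_Y, dphi, dlam)
    return x, y


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between WGS84 points (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
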