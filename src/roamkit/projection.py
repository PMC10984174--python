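"""Transverse Mercator (UTM/WGS84) forward and inverse projection.

Every distance threshold in the pipeline is metric, so geographic input is
projected once, at ingestion, into a single UTM zone. The implementation
follows the classic ellipsoidal series (Snyder's working-manual formulas),
which are accurate to well under a centimetre within a UTM zone — far below
GPS positional error (~5 m).

Only the UTM/WGS84 EPSG codes 326xx (north) and 327xx (south) are supported;
the loader requires an explicit code rather than guessing a datum.
"""

from __future__ import annotations

import math

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_S = 10_000_000.0

# meridian-arc series coefficients
_M0 = 1.0 - _E2 / 4.0 - 3.0 * _E2**2 / 64.0 - 5.0 * _E2**3 / 256.0
_M2 = 3.0 * _E2 / 8.0 + 3.0 * _E2**2 / 32.0 + 45.0 * _E2**3 / 1024.0
_M4 = 15.0 * _E2**2 / 256.0 + 45.0 * _E2**3 / 1024.0
_M6 = 35.0 * _E2**3 / 3072.0


def utm_zone_params(epsg: int) -> tuple[float, bool]:
    """Central meridian (degrees) and southern-hemisphere flag for a UTM EPSG code."""
    if 32601 <= epsg <= 32660:
        zone, south = epsg - 32600, False
    elif 32701 <= epsg <= 32760:
        zone, south = epsg - 32700, True
    else:
        raise ValueError(
            f"EPSG {epsg} is not a UTM/WGS84 code (expected 326xx or 327xx)"
        )
    return -183.0 + 6.0 * zone, south


def _meridian_arc(phi: np.ndarray) -> np.ndarray:
    return _A * (
        _M0 * phi
        - _M2 * np.sin(2 * phi)
        + _M4 * np.sin(4 * phi)
        - _M6 * np.sin(6 * phi)
    )


def lonlat_to_xy(lon, lat, epsg: int):
    """Project geographic WGS84 coordinates (degrees) to UTM metres."""
    lon0_deg, south = utm_zone_params(epsg)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    dlam = np.radians(lon - lon0_deg)

    sin_phi, cos_phi, tan_phi = np.sin(phi), np.cos(phi), np.tan(phi)
    n = _A / np.sqrt(1.0 - _E2 * sin_phi**2)
    t = tan_phi**2
    c = _EP2 * cos_phi**2
    a_ = dlam * cos_phi
    m = _meridian_arc(phi)

    x = _K0 * n * (
        a_
        + (1 - t + c) * a_**3 / 6.0
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a_**5 / 120.0
    ) + _FALSE_EASTING
    y = _K0 * (
        m
        + n * tan_phi * (
            a_**2 / 2.0
            + (5 - t + 9 * c + 4 * c**2) * a_**4 / 24.0
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a_**6 / 720.0
        )
    )
    if south:
        y = y + _FALSE_NORTHING_S
    return x, y


def xy_to_lonlat(x, y, epsg: int):
    """Inverse projection: UTM metres back to WGS84 degrees."""
    lon0_deg, south = utm_zone_params(epsg)
    x = np.asarray(x, dtype=float) - _FALSE_EASTING
    y = np.asarray(y, dtype=float)
    if south:
        y = y - _FALSE_NORTHING_S

    m = y / _K0
    mu = m / (_A * _M0)
    e1 = (1 - math.sqrt(1 - _E2)) / (1 + math.sqrt(1 - _E2))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )

    sin1, cos1, tan1 = np.sin(phi1), np.cos(phi1), np.tan(phi1)
    c1 = _EP2 * cos1**2
    t1 = tan1**2
    n1 = _A / np.sqrt(1 - _E2 * sin1**2)
    r1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
    d = x / (n1 * _K0)

    phi = phi1 - (n1 * tan1 / r1) * (
        d**2 / 2.0
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24.0
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
        * d**6 / 720.0
    )
    dlam = (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6.0
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2) * d**5 / 120.0
    ) / cos1
    return lon0_deg + np.degrees(dlam), np.degrees(phi)
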