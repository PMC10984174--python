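"""Independent transverse-Mercator forward projection (test oracle).

Karney/Krüger exponential-series formulation — a different derivation from
the package's Snyder-style series, so agreement between the two is a
genuine cross-implementation check rather than a reimplementation of the
same polynomial.
"""

import math

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_N = _F / (2.0 - _F)

# rectifying radius
_A_BAR = _A / (1 + _N) * (1 + _N**2 / 4 + _N**4 / 64 + _N**6 / 256)

# Krüger alpha coefficients (to n^4)
_ALPHA = (
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440,
    61 * _N**3 / 240 - 103 * _N**4 / 140,
    49561 * _N**4 / 161280,
)


def forward(lon_deg: float, lat_deg: float, lon0_deg: float
            ) -> tuple[float, float]:
    """UTM easting/northing (northern hemisphere convention)."""
    phi = math.radians(lat_deg)
    lam = math.radians(lon_deg - lon0_deg)
    e = math.sqrt(_F * (2 - _F))

    # conformal latitude
    t = math.sinh(
        math.atanh(math.sin(phi))
        - e * math.atanh(e * math.sin(phi))
    )
    xi_p = math.atan2(t, math.cos(lam))
    eta_p = math.asinh(math.sin(lam) / math.hypot(t, math.cos(lam)))

    xi = xi_p
    eta = eta_p
    for j, a in enumerate(_ALPHA, start=1):
        xi += a * math.sin(2 * j * xi_p) * math.cosh(2 * j * eta_p)
        eta += a * math.cos(2 * j * xi_p) * math.sinh(2 * j * eta_p)

    easting = 500_000.0 + _K0 * _A_BAR * eta
    northing = _K0 * _A_BAR * xi
    return easting, northing
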