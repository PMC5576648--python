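"""WGS-84 geodesic distances.

Distances between telemetry fixes follow Vincenty's inverse formula on the
WGS-84 ellipsoid, the conventional choice for Argos track analysis.  A
vectorized implementation keeps section-building fast.  For the rare
near-antipodal pairs where Vincenty's iteration fails to converge, we fall
back to the haversine great-circle distance on the mean Earth radius (logged);
such pairs are thousands of kilometres beyond any plausible daily movement,
so the ~0.5 % spherical error there is immaterial.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
MEAN_RADIUS = (2.0 * WGS84_A + WGS84_B) / 3.0

_MAX_ITER = 200
_TOL = 1e-12


def vincenty_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Geodesic distance in metres between points on the WGS-84 ellipsoid.

    Accepts scalars or broadcastable arrays of degrees.  Returns metres with
    the broadcast shape (a float for all-scalar input).  Symmetric, and zero
    iff the two points coincide.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    )
    scalar = lat1.ndim == 0
    phi1 = np.atleast_1d(np.radians(lat1))
    phi2 = np.atleast_1d(np.radians(lat2))
    dlon = np.atleast_1d(np.radians(lon2 - lon1))
    # wrap to [-pi, pi): shortest rotation between meridians
    dlon = (dlon + np.pi) % (2.0 * np.pi) - np.pi

    U1 = np.arctan((1.0 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = dlon.copy()
    active = np.ones(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(_MAX_ITER):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        sin_sigma_new = np.hypot(t1, t2)
        cos_sigma_new = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma_new = np.arctan2(sin_sigma_new, cos_sigma_new)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(
                sin_sigma_new > 0, cosU1 * cosU2 * sin_lam / sin_sigma_new, 0.0
            )
        csa = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2sm = np.where(
                csa > 0, cos_sigma_new - 2.0 * sinU1 * sinU2 / np.where(csa > 0, csa, 1.0), 0.0
            )
        C = WGS84_F / 16.0 * csa * (4.0 + WGS84_F * (4.0 - 3.0 * csa))
        lam_new = dlon + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma_new
            + C * sin_sigma_new * (c2sm + C * cos_sigma_new * (-1.0 + 2.0 * c2sm**2))
        )
        upd = active
        sin_sigma = np.where(upd, sin_sigma_new, sin_sigma)
        cos_sigma = np.where(upd, cos_sigma_new, cos_sigma)
        sigma = np.where(upd, sigma_new, sigma)
        cos_sq_alpha = np.where(upd, csa, cos_sq_alpha)
        cos2sm = np.where(upd, c2sm, cos2sm)
        converged = np.abs(lam_new - lam) < _TOL
        lam = np.where(upd, lam_new, lam)
        active = active & ~converged
        if not active.any():
            break

    u_sq = cos_sq_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos2sm
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos2sm**2)
                - B
                / 6.0
                * cos2sm
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos2sm**2)
            )
        )
    )
    dist = WGS84_B * A * (sigma - delta_sigma)

    if active.any():
        # non-convergent (near-antipodal) pairs: great-circle fallback
        log.warning(
            "Vincenty failed to converge for %d near-antipodal pair(s); "
            "using great-circle fallback",
            int(active.sum()),
        )
        hav = _haversine(
            np.atleast_1d(phi1), np.atleast_1d(phi2), np.atleast_1d(dlon)
        )
        dist = np.where(active, hav, dist)

    # identical points short-circuit (sigma==0 already gives 0, keep exact)
    same = (np.atleast_1d(phi1) == np.atleast_1d(phi2)) & (np.abs(np.atleast_1d(dlon)) == 0)
    dist = np.where(same, 0.0, dist)
    return float(dist[0]) if scalar else dist.reshape(lat1.shape)


def _haversine(phi1, phi2, dlon):
    a = np.sin((phi2 - phi1) / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * MEAN_RADIUS * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Scalar WGS-84 distance in metres (Vincenty; see module docstring)."""
    return float(vincenty_distance(lat1, lon1, lat2, lon2))


# -- meridian arc -----------------------------------------------------------
# Closed-form series for arc length along a meridian from the equator; exact
# (to machine precision) for the meridional distances used when building
# synthetic fields and section distance axes, and much cheaper than the
# iterative inverse problem.

_E2 = WGS84_F * (2.0 - WGS84_F)
_N = WGS84_F / (2.0 - WGS84_F)
_MERID_COEF = (
    1.0 + _N**2 / 4.0 + _N**4 / 64.0,
    -3.0 / 2.0 * (_N - _N**3 / 8.0),
    15.0 / 16.0 * (_N**2 - _N**4 / 4.0),
    -35.0 / 48.0 * _N**3,
    315.0 / 512.0 * _N**4,
)


def meridian_arc(lat) -> np.ndarray | float:
    """Distance in metres along the meridian from the equator to ``lat``."""
    phi = np.radians(np.asarray(lat, dtype=float))
    a0, a2, a4, a6, a8 = _MERID_COEF
    r = WGS84_A / (1.0 + _N)
    m = r * (
        a0 * phi
        + a2 * np.sin(2.0 * phi)
        + a4 * np.sin(4.0 * phi)
        + a6 * np.sin(6.0 * phi)
        + a8 * np.sin(8.0 * phi)
    )
    return float(m) if np.ndim(lat) == 0 else m


def meridional_distance_km(lat_from, lat_to) -> np.ndarray | float:
    """Signed meridional distance in km, positive when ``lat_to`` is north."""
    return (meridian_arc(lat_to) - meridian_arc(lat_from)) / 1000.0


def latitude_at_meridional_offset(lat_from, offset_km):
    """Latitude ``offset_km`` north (signed) of ``lat_from`` along the meridian.

    Inverts the meridian-arc series with two Newton steps (the arc is nearly
    linear in latitude, so this is accurate to well under a metre).
    """
    lat = np.asarray(lat_from, dtype=float) + np.asarray(offset_km, dtype=float) / 111.0
    target = meridian_arc(lat_from) + np.asarray(offset_km, dtype=float) * 1000.0
    for _ in range(2):
        # dM/dphi = a(1-e^2)/(1-e^2 sin^2 phi)^{3/2}
        phi = np.radians(lat)
        dm = WGS84_A * (1.0 - _E2) / (1.0 - _E2 * np.sin(phi) ** 2) ** 1.5
        lat = lat - np.degrees((meridian_arc(lat) - target) / dm)
    return lat


def zonal_distance_km(lat: float, lon_from, lon_to) -> np.ndarray | float:
    """Signed east-west geodesic distance in km between two longitudes.

    Measured between points at the shared latitude ``lat``; positive when
    ``lon_to`` lies east of ``lon_from`` after wrapping across the antimeridian.
    """
    dlon = (np.asarray(lon_to, dtype=float) - np.asarray(lon_from, dtype=float) + 180.0) % 360.0 - 180.0
    dist = vincenty_distance(lat, 0.0, lat, dlon) / 1000.0
    return np.sign(dlon) * dist
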