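"""Coordinate reference systems, map projections, and ellipsoidal geodesics.

Grid datasets arrive in heterogeneous native projections (regular lon/lat,
the MODIS sinusoidal grid, Lambert conformal conic for regional reanalyses,
Albers equal area for some land-cover products).  Track fixes are WGS84
longitude/latitude.  This module provides the forward/inverse transforms
between them, plus geodesic distance and initial bearing on the WGS84
ellipsoid, which the interpolation and derived-variable code build on.

Projection formulas follow Snyder, *Map Projections — A Working Manual*
(USGS PP 1395).  Geodesics use Vincenty's inverse/direct algorithms on the
WGS84 ellipsoid; a spherical haversine alternative is provided because the
distinction matters below the 0.6 % level only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ProjectionDomainError, UndefinedBearingError, ValidationError

# WGS84 ellipsoid
WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)
WGS84_E = math.sqrt(WGS84_E2)

#: Authalic sphere radius of the MODIS sinusoidal grid (meters).
MODIS_SPHERE_RADIUS = 6371007.181

#: Mean Earth radius used by the spherical haversine option (meters).
SPHERE_RADIUS = 6371000.0

_KNOWN_CRS = {
    "wgs84_lonlat",
    "plate_carree",
    "sinusoidal",
    "lambert_conformal_conic",
    "albers_equal_area",
}


@dataclass(frozen=True)
class CRS:
    """A named coordinate reference system with projection parameters.

    ``wgs84_lonlat`` coordinates are degrees; all projected systems are
    meters.  The ellipsoid is WGS84 except for the sinusoidal projection,
    which uses the MODIS authalic sphere by convention.
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _KNOWN_CRS:
            raise ValidationError(f"unknown CRS {self.name!r}")
        if self.name == "lambert_conformal_conic":
            missing = {"lat_1", "lat_2", "lat_0", "lon_0"} - set(self.params)
            if missing:
                raise ValidationError(f"lambert_conformal_conic missing {sorted(missing)}")
        if self.name == "albers_equal_area":
            missing = {"lat_1", "lat_2", "lat_0", "lon_0"} - set(self.params)
            if missing:
                raise ValidationError(f"albers_equal_area missing {sorted(missing)}")

    # -- constructors -------------------------------------------------
    @staticmethod
    def wgs84():
        return CRS("wgs84_lonlat")

    @staticmethod
    def plate_carree(radius: float = WGS84_A):
        return CRS("plate_carree", {"radius": radius})

    @staticmethod
    def sinusoidal(radius: float = MODIS_SPHERE_RADIUS, lon_0: float = 0.0):
        return CRS("sinusoidal", {"radius": radius, "lon_0": lon_0})

    @staticmethod
    def lambert_conformal_conic(lat_1, lat_2, lat_0=0.0, lon_0=0.0,
                                false_easting=0.0, false_northing=0.0):
        return CRS("lambert_conformal_conic",
                   {"lat_1": lat_1, "lat_2": lat_2, "lat_0": lat_0,
                    "lon_0": lon_0, "false_easting": false_easting,
                    "false_northing": false_northing})

    @staticmethod
    def albers_equal_area(lat_1, lat_2, lat_0=0.0, lon_0=0.0,
                          false_easting=0.0, false_northing=0.0):
        return CRS("albers_equal_area",
                   {"lat_1": lat_1, "lat_2": lat_2, "lat_0": lat_0,
                    "lon_0": lon_0, "false_easting": false_easting,
                    "false_northing": false_northing})

    @property
    def is_lonlat(self) -> bool:
        return self.name == "wgs84_lonlat"

    # frozen dataclass with a dict field: hash by name + sorted params
    def __hash__(self):
        return hash((self.name, tuple(sorted(self.params.items()))))


def normalize_lon(lon):
    """Wrap longitude(s) into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# Projection cores (scalar lon/lat in degrees -> x, y in meters)
# ---------------------------------------------------------------------------

def _sinusoidal_fwd(lon, lat, p):
    R = p.get("radius", MODIS_SPHERE_RADIUS)
    lon0 = p.get("lon_0", 0.0)
    lam = math.radians(float(normalize_lon(lon - lon0)))
    phi = math.radians(lat)
    return R * lam * math.cos(phi), R * phi


def _sinusoidal_inv(x, y, p):
    R = p.get("radius", MODIS_SPHERE_RADIUS)
    lon0 = p.get("lon_0", 0.0)
    phi = y / R
    if abs(phi) > math.pi / 2 + 1e-12:
        raise ProjectionDomainError(f"sinusoidal y={y} outside the globe")
    c = math.cos(phi)
    if abs(c) < 1e-12:
        lam = 0.0
    else:
        lam = x / (R * c)
    return float(normalize_lon(math.degrees(lam) + lon0)), math.degrees(phi)


def _plate_carree_fwd(lon, lat, p):
    R = p.get("radius", WGS84_A)
    return R * math.radians(lon), R * math.radians(lat)


def _plate_carree_inv(x, y, p):
    R = p.get("radius", WGS84_A)
    return math.degrees(x / R), math.degrees(y / R)


def _lcc_m(phi, e):
    return math.cos(phi) / math.sqrt(1.0 - (e * math.sin(phi)) ** 2)


def _lcc_t(phi, e):
    s = math.sin(phi)
    return math.tan(math.pi / 4 - phi / 2) / ((1 - e * s) / (1 + e * s)) ** (e / 2)


def _lcc_constants(p):
    e = WGS84_E
    phi1 = math.radians(p["lat_1"])
    phi2 = math.radians(p["lat_2"])
    phi0 = math.radians(p["lat_0"])
    m1, m2 = _lcc_m(phi1, e), _lcc_m(phi2, e)
    t0, t1, t2 = _lcc_t(phi0, e), _lcc_t(phi1, e), _lcc_t(phi2, e)
    if abs(phi1 - phi2) > 1e-12:
        n = (math.log(m1) - math.log(m2)) / (math.log(t1) - math.log(t2))
    else:
        n = math.sin(phi1)
    F = m1 / (n * t1 ** n)
    rho0 = WGS84_A * F * t0 ** n
    return e, n, F, rho0


def _lcc_fwd(lon, lat, p):
    e, n, F, rho0 = _lcc_constants(p)
    phi = math.radians(lat)
    # the pole opposite the cone's apex is not representable
    if n > 0 and lat <= -89.999 or n < 0 and lat >= 89.999:
        raise ProjectionDomainError(
            f"latitude {lat} outside the Lambert conformal conic domain")
    t = _lcc_t(phi, e)
    rho = WGS84_A * F * t ** n
    theta = n * math.radians(float(normalize_lon(lon - p["lon_0"])))
    x = rho * math.sin(theta) + p.get("false_easting", 0.0)
    y = rho0 - rho * math.cos(theta) + p.get("false_northing", 0.0)
    return x, y


def _phi_from_t(t, e):
    phi = math.pi / 2 - 2 * math.atan(t)
    for _ in range(25):
        s = math.sin(phi)
        phi_new = math.pi / 2 - 2 * math.atan(t * ((1 - e * s) / (1 + e * s)) ** (e / 2))
        if abs(phi_new - phi) < 1e-13:
            return phi_new
        phi = phi_new
    return phi


def _lcc_inv(x, y, p):
    e, n, F, rho0 = _lcc_constants(p)
    x = x - p.get("false_easting", 0.0)
    y = y - p.get("false_northing", 0.0)
    rho = math.copysign(math.hypot(x, rho0 - y), n)
    if n >= 0:
        theta = math.atan2(x, rho0 - y)
    else:
        theta = math.atan2(-x, y - rho0)
    if rho == 0.0:
        phi = math.copysign(math.pi / 2, n)
    else:
        t = (rho / (WGS84_A * F)) ** (1.0 / n)
        phi = _phi_from_t(t, e)
    lon = math.degrees(theta / n) + p["lon_0"]
    return float(normalize_lon(lon)), math.degrees(phi)


def _aea_q(phi, e):
    s = math.sin(phi)
    return (1 - e * e) * (s / (1 - e * e * s * s)
                          - (1 / (2 * e)) * math.log((1 - e * s) / (1 + e * s)))


def _aea_constants(p):
    e = WGS84_E
    phi1 = math.radians(p["lat_1"])
    phi2 = math.radians(p["lat_2"])
    phi0 = math.radians(p["lat_0"])
    m1, m2 = _lcc_m(phi1, e), _lcc_m(phi2, e)
    q0, q1, q2 = _aea_q(phi0, e), _aea_q(phi1, e), _aea_q(phi2, e)
    if abs(phi1 - phi2) > 1e-12:
        n = (m1 * m1 - m2 * m2) / (q2 - q1)
    else:
        n = math.sin(phi1)
    C = m1 * m1 + n * q1
    rho0 = WGS84_A * math.sqrt(C - n * q0) / n
    return e, n, C, rho0


def _aea_fwd(lon, lat, p):
    e, n, C, rho0 = _aea_constants(p)
    q = _aea_q(math.radians(lat), e)
    under = C - n * q
    if under < 0:
        raise ProjectionDomainError(
            f"latitude {lat} outside the Albers equal-area domain")
    rho = WGS84_A * math.sqrt(under) / n
    theta = n * math.radians(float(normalize_lon(lon - p["lon_0"])))
    x = rho * math.sin(theta) + p.get("false_easting", 0.0)
    y = rho0 - rho * math.cos(theta) + p.get("false_northing", 0.0)
    return x, y


def _aea_inv(x, y, p):
    e, n, C, rho0 = _aea_constants(p)
    x = x - p.get("false_easting", 0.0)
    y = y - p.get("false_northing", 0.0)
    rho = math.hypot(x, rho0 - y)
    if n >= 0:
        theta = math.atan2(x, rho0 - y)
    else:
        theta = math.atan2(-x, y - rho0)
    q = (C - (rho * n / WGS84_A) ** 2) / n
    # iterate for phi (Snyder 3-16)
    arg = q / 2
    arg = max(-1.0, min(1.0, arg))
    phi = math.asin(arg)
    for _ in range(25):
        s = math.sin(phi)
        denom = 1 - e * e * s * s
        corr = (denom ** 2 / (2 * math.cos(phi))) * (
            q / (1 - e * e) - s / denom
            + (1 / (2 * e)) * math.log((1 - e * s) / (1 + e * s)))
        phi_new = phi + corr
        if abs(phi_new - phi) < 1e-13:
            phi = phi_new
            break
        phi = phi_new
    lon = math.degrees(theta / n) + p["lon_0"]
    return float(normalize_lon(lon)), math.degrees(phi)


_FWD = {
    "sinusoidal": _sinusoidal_fwd,
    "plate_carree": _plate_carree_fwd,
    "lambert_conformal_conic": _lcc_fwd,
    "albers_equal_area": _aea_fwd,
}
_INV = {
    "sinusoidal": _sinusoidal_inv,
    "plate_carree": _plate_carree_inv,
    "lambert_conformal_conic": _lcc_inv,
    "albers_equal_area": _aea_inv,
}


def project(lon: float, lat: float, crs: CRS):
    """Forward-project WGS84 lon/lat (degrees) into ``crs`` native coords."""
    if abs(lat) > 90.0:
        raise ProjectionDomainError(f"latitude {lat} outside [-90, 90]")
    if crs.is_lonlat:
        return float(normalize_lon(lon)), float(lat)
    return _FWD[crs.name](lon, lat, crs.params)


def unproject(x: float, y: float, crs: CRS):
    """Inverse-project native coordinates back to WGS84 lon/lat degrees."""
    if crs.is_lonlat:
        return float(normalize_lon(x)), float(y)
    return _INV[crs.name](x, y, crs.params)


def transform_point(point, from_crs: CRS, to_crs: CRS):
    """Transform a point between any two supported CRSs (via lon/lat)."""
    lon, lat = unproject(point[0], point[1], from_crs)
    return project(lon, lat, to_crs)


# ---------------------------------------------------------------------------
# Geodesics
# ---------------------------------------------------------------------------

def _vincenty_inverse(lon1, lat1, lon2, lat2):
    """Vincenty inverse on WGS84: (distance m, initial azimuth deg, converged)."""
    a, b, f = WGS84_A, WGS84_B, WGS84_F
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(float(normalize_lon(lon2 - lon1)))
    U1 = math.atan((1 - f) * math.tan(phi1))
    U2 = math.atan((1 - f) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0, None, True  # coincident points
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha
        C = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        # nearly antipodal: Vincenty may not converge; spherical fallback
        d = haversine_distance(lon1, lat1, lon2, lat2)
        brg = _spherical_bearing(lon1, lat1, lon2, lat2)
        return d, brg, False

    u2 = cos2_alpha * (a * a - b * b) / (b * b)
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)
            - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma ** 2)
            * (-3 + 4 * cos_2sigma_m ** 2)))
    s = b * A * (sigma - delta_sigma)
    alpha1 = math.atan2(cosU2 * math.sin(lam),
                        cosU1 * sinU2 - sinU1 * cosU2 * math.cos(lam))
    return s, math.degrees(alpha1) % 360.0, True


def _vincenty_direct(lon1, lat1, azimuth_deg, distance_m):
    """Vincenty direct: destination lon/lat from start, bearing, distance."""
    a, b, f = WGS84_A, WGS84_B, WGS84_F
    alpha1 = math.radians(azimuth_deg)
    phi1 = math.radians(lat1)
    U1 = math.atan((1 - f) * math.tan(phi1))
    sigma1 = math.atan2(math.tan(U1), math.cos(alpha1))
    sin_alpha = math.cos(U1) * math.sin(alpha1)
    cos2_alpha = 1 - sin_alpha ** 2
    u2 = cos2_alpha * (a * a - b * b) / (b * b)
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    sigma = distance_m / (b * A)
    for _ in range(200):
        cos_2sigma_m = math.cos(2 * sigma1 + sigma)
        sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
        delta_sigma = B * sin_sigma * (
            cos_2sigma_m + B / 4 * (
                cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)
                - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma ** 2)
                * (-3 + 4 * cos_2sigma_m ** 2)))
        sigma_new = distance_m / (b * A) + delta_sigma
        if abs(sigma_new - sigma) < 1e-12:
            sigma = sigma_new
            break
        sigma = sigma_new
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
    cos_2sigma_m = math.cos(2 * sigma1 + sigma)
    phi2 = math.atan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * math.cos(alpha1),
        (1 - f) * math.hypot(sin_alpha,
                             sinU1 * sin_sigma - cosU1 * cos_sigma * math.cos(alpha1)))
    lam = math.atan2(sin_sigma * math.sin(alpha1),
                     cosU1 * cos_sigma - sinU1 * sin_sigma * math.cos(alpha1))
    C = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
    L = lam - (1 - C) * f * sin_alpha * (
        sigma + C * sin_sigma * (
            cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)))
    lon2 = float(normalize_lon(lon1 + math.degrees(L)))
    return lon2, math.degrees(phi2)


def _spherical_bearing(lon1, lat1, lon2, lat2):
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dlam = math.radians(float(normalize_lon(lon2 - lon1)))
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return math.degrees(math.atan2(y, x)) % 360.0


def haversine_distance(lon1, lat1, lon2, lat2, radius: float = SPHERE_RADIUS):
    """Great-circle distance on a sphere (meters)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(float(normalize_lon(lon2 - lon1)))
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius * math.asin(min(1.0, math.sqrt(h)))


def geodesic_distance(lon1, lat1, lon2, lat2, method: str = "ellipsoidal"):
    """Distance between two WGS84 lon/lat points in meters.

    ``method`` is ``"ellipsoidal"`` (Vincenty on WGS84, the default) or
    ``"spherical"`` (haversine on a 6371 km sphere).
    """
    if method == "spherical":
        return haversine_distance(lon1, lat1, lon2, lat2)
    if method != "ellipsoidal":
        raise ValidationError(f"unknown distance method {method!r}")
    d, _, _ = _vincenty_inverse(lon1, lat1, lon2, lat2)
    return d


def initial_bearing(lon1, lat1, lon2, lat2):
    """Initial azimuth of the geodesic p1 -> p2, degrees clockwise from north.

    Raises :class:`UndefinedBearingError` for coincident points.
    """
    d, brg, _ = _vincenty_inverse(lon1, lat1, lon2, lat2)
    if brg is None or d == 0.0:
        raise UndefinedBearingError(
            f"bearing undefined between coincident points ({lon1}, {lat1})")
    return brg % 360.0


def destination_point(lon, lat, bearing_deg, distance_m):
    """Destination reached from (lon, lat) along an initial bearing (Vincenty direct)."""
    if distance_m == 0.0:
        return float(normalize_lon(lon)), float(lat)
    return _vincenty_direct(lon, lat, bearing_deg, distance_m)
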