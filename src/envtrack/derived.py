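"""Derived movement covariates: wind decomposition, uplift, and terrain.

Wind conventions
----------------
Reanalysis wind comes as u (eastward) and v (northward) components in m/s.
The direction computed here is the azimuth TOWARD which the air moves
(degrees clockwise from true north), which is what the tailwind
decomposition needs; meteorological "direction the wind blows FROM" differs
by 180 degrees and a converter is provided.

For an animal moving on heading theta (degrees from north),

    tailwind  = u sin(theta) + v cos(theta)
    crosswind = u cos(theta) - v sin(theta)

so tailwind > 0 is flow assistance, tailwind < 0 a head wind, and
crosswind > 0 means wind arriving from the animal's left (flip with
``cross_from_right=True``).  The decomposition is a rotation, hence
tailwind^2 + crosswind^2 = u^2 + v^2.

Terrain operators use the Horn 3x3 kernel for slope/aspect (exact for
planes) and the population standard deviation of a window for rugosity.
Orographic uplift is the vertical wind induced on a windward slope,
|w| tan(slope) cos(wind_to - upslope); thermal uplift is the convective
velocity scale w* = [ (g z_i / T) * H / (rho c_p) ]^(1/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedBearingError, ValidationError

GRAVITY = 9.80665  # m/s^2
AIR_DENSITY = 1.225  # kg/m^3 at sea level, 15 C
SPECIFIC_HEAT_AIR = 1005.0  # J/kg/K


@dataclass(frozen=True)
class TerrainCell:
    """Slope (radians), downslope aspect (degrees from north, NaN when
    flat), and rugosity (elevation units) of one DEM cell."""

    slope: float
    aspect: float
    rugosity: float = float("nan")

    @property
    def is_flat(self) -> bool:
        return self.slope == 0.0


def wind_speed_direction(u: float, v: float):
    """(speed m/s, direction degrees from north TOWARD which air moves).

    Calm air (u = v = 0) has speed 0 and undefined (NaN) direction.
    """
    if not (np.isfinite(u) and np.isfinite(v)):
        return float("nan"), float("nan")
    speed = math.hypot(u, v)
    if speed == 0.0:
        return 0.0, float("nan")
    return speed, math.degrees(math.atan2(u, v)) % 360.0


def direction_to_from(direction: float) -> float:
    """Convert between 'blowing toward' and 'blowing from' azimuths (+-180)."""
    return (direction + 180.0) % 360.0


def wind_support(u: float, v: float, heading: float, cross_from_right: bool = False):
    """(tailwind, crosswind) of wind (u, v) for travel on ``heading`` degrees.

    Raises :class:`UndefinedBearingError` when the heading is undefined
    (NaN), e.g. at stationary fixes.
    """
    if heading is None or not np.isfinite(heading):
        raise UndefinedBearingError("wind support needs a defined flight heading")
    th = math.radians(heading)
    tail = u * math.sin(th) + v * math.cos(th)
    cross = u * math.cos(th) - v * math.sin(th)
    if cross_from_right:
        cross = -cross
    return tail, cross


def slope_aspect(dem_window, cell_size_x: float, cell_size_y: float) -> TerrainCell:
    """Horn slope and aspect from a 3x3 elevation window.

    The window rows run north to south, columns west to east; cell sizes are
    meters.  Aspect is the downslope azimuth (270 = slope faces west); it is
    NaN for flat cells.  Any missing cell makes the result missing.
    """
    w = np.asarray(dem_window, dtype=float)
    if w.shape != (3, 3):
        raise ValidationError(f"slope_aspect needs a 3x3 window, got {w.shape}")
    if not np.isfinite(w).all():
        return TerrainCell(float("nan"), float("nan"))
    (a, b, c), (d, _, f), (g, h, i) = w
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size_x)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cell_size_y)  # northward
    slope = math.atan(math.hypot(dzdx, dzdy))
    if slope == 0.0:
        return TerrainCell(0.0, float("nan"))
    aspect = math.degrees(math.atan2(-dzdx, -dzdy)) % 360.0
    return TerrainCell(slope, aspect)


def rugosity(dem_window) -> float:
    """Population standard deviation of a k x k elevation window.

    Needs at least 4 finite cells; all-missing windows return NaN.
    """
    w = np.asarray(dem_window, dtype=float).ravel()
    good = np.isfinite(w)
    if not good.any():
        return float("nan")
    if good.sum() < 4:
        raise ValidationError("rugosity needs >= 4 finite cells")
    return float(np.std(w[good]))


def orographic_uplift(u: float, v: float, cell: TerrainCell,
                      clamp_zero: bool = False) -> float:
    """Vertical air speed (m/s) from horizontal wind meeting sloped terrain.

    w_oro = |w| tan(slope) cos(wind_to - upslope); positive on windward
    slopes, negative downslope flow (clamped at 0 with ``clamp_zero``).
    Flat cells give 0 regardless of wind.
    """
    if cell.is_flat:
        return 0.0
    if not np.isfinite(cell.slope) or not np.isfinite(cell.aspect):
        return float("nan")
    speed, direction = wind_speed_direction(u, v)
    if speed == 0.0:
        return 0.0
    upslope = (cell.aspect + 180.0) % 360.0
    w = speed * math.tan(cell.slope) * math.cos(math.radians(direction - upslope))
    if clamp_zero:
        w = max(0.0, w)
    return w


def thermal_uplift(H: float, z_i: float, T: float,
                   rho: float = AIR_DENSITY, c_p: float = SPECIFIC_HEAT_AIR) -> float:
    """Convective velocity scale w* (m/s) of a heated boundary layer.

    w* = [ (g z_i / T) * H / (rho c_p) ]^(1/3) for positive surface sensible
    heat flux H (W/m^2); 0 for H <= 0.  ``z_i`` is boundary-layer height (m)
    and T surface air temperature in kelvin (values below 200 are taken as
    Celsius and converted).
    """
    if T < 200.0:
        T = T + 273.15
    if T <= 0 or z_i <= 0 or rho <= 0 or c_p <= 0:
        raise ValidationError("thermal_uplift: T, z_i, rho, c_p must be positive")
    if not np.isfinite(H):
        return float("nan")
    if H <= 0:
        return 0.0
    return ((GRAVITY * z_i / T) * H / (rho * c_p)) ** (1.0 / 3.0)


def terrain_at_node(dem, iy: int, ix: int) -> TerrainCell:
    """Slope/aspect/rugosity of a DEM grid node from its 3x3 neighborhood.

    ``dem`` is a GridVariable whose x/y axes are degrees (lon/lat) or
    meters; degree spacings are converted to meters at the node's latitude.
    Edge nodes (no full 3x3 window) give a missing cell.
    """
    ax_x, ax_y = dem.axis("x"), dem.axis("y")
    ny, nx = len(ax_y), len(ax_x)
    if not (1 <= iy <= ny - 2 and 1 <= ix <= nx - 2):
        return TerrainCell(float("nan"), float("nan"))
    sel = []
    for ax in dem.axes:
        if ax.name == "y":
            sel.append(slice(iy - 1, iy + 2))
        elif ax.name == "x":
            sel.append(slice(ix - 1, ix + 2))
        else:
            sel.append(0)
    win = dem.clean(dem.values[tuple(sel)])
    # rows must run north->south for the Horn kernel
    if ax_y.coordinates[1] > ax_y.coordinates[0]:
        win = win[::-1, :]
    dx = abs(ax_x.spacing if ax_x.is_regular else np.diff(ax_x.coordinates).mean())
    dy = abs(ax_y.spacing if ax_y.is_regular else np.diff(ax_y.coordinates).mean())
    if dem.crs.is_lonlat:
        lat = float(ax_y.coordinates[iy])
        m_per_deg = 111319.49079327358  # WGS84 equatorial degree
        dx = dx * m_per_deg * math.cos(math.radians(lat))
        dy = dy * m_per_deg
    cell = slope_aspect(win, dx, dy)
    return TerrainCell(cell.slope, cell.aspect, rugosity(win))
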