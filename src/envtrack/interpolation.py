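"""Space-then-time interpolation of gridded values to a track point.

For a trajectory point p(x, y, t), the bracketing grid nodes are located at
the two scene timestamps around t; the node values are first interpolated in
space at each timestamp, and the two spatial values are then interpolated in
time to t.

Spatial methods: nearest_neighbour, bilinear (regular grids; extended
per-cell to irregular ones via fractional coordinates), and
inverse-distance-weighted (IDW, Shepard weights d^-p on geodesic distances).
Temporal methods: nearest_neighbour and IDW with power 1, which for the two
bracketing samples reduces to linear interpolation.

Categorical variables only ever use nearest neighbour, so every annotated
category is a code actually present in the neighborhood.

Missing nodes are dropped and the remaining weights renormalized; a value is
missing (NaN) only when every node is.  All methods yield convex
combinations of the contributing nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import OutOfDomainError, ValidationError
from .geo import geodesic_distance, project
from .grid import CellNeighborhood, GridVariable, locate_neighborhood

SPATIAL_METHODS = ("nearest_neighbour", "bilinear", "inverse_distance_weighted")
TEMPORAL_METHODS = ("nearest_neighbour", "inverse_distance_weighted")

#: distance below which a query is an exact node hit (meters)
EXACT_HIT_M = 1.0


@dataclass(frozen=True)
class InterpMethod:
    """Interpolation method choice for one variable.

    ``idw_power_space`` defaults to 2 (classic Shepard); ``idw_power_time``
    defaults to 1 so two-sample time IDW equals linear interpolation.
    ``idw_k`` is the neighbour count for spatial IDW (4 = the bracketing
    cell; more requests a wider ring).
    """

    spatial: str = "bilinear"
    temporal: str = "inverse_distance_weighted"
    idw_power_space: float = 2.0
    idw_power_time: float = 1.0
    idw_k: int = 4

    def __post_init__(self):
        if self.spatial not in SPATIAL_METHODS:
            raise ValidationError(f"unknown spatial method {self.spatial!r}")
        if self.temporal not in TEMPORAL_METHODS:
            raise ValidationError(f"unknown temporal method {self.temporal!r}")
        if self.idw_power_space <= 0 or self.idw_power_time <= 0:
            raise ValidationError("IDW powers must be positive")
        if self.idw_k < 1:
            raise ValidationError("idw_k must be >= 1")

    @property
    def ring(self) -> int:
        """Neighborhood ring radius needed for this method."""
        if self.spatial == "inverse_distance_weighted" and self.idw_k > 4:
            return max(1, math.ceil(math.sqrt(self.idw_k) / 2))
        return 1

    @property
    def column_tag(self) -> str:
        short = {"nearest_neighbour": "nearest", "bilinear": "bilinear",
                 "inverse_distance_weighted": "idw"}
        return f"{short[self.spatial]}-{short[self.temporal]}"


NEAREST = InterpMethod(spatial="nearest_neighbour", temporal="nearest_neighbour")
BILINEAR_LINEAR = InterpMethod(spatial="bilinear", temporal="inverse_distance_weighted")


def _node_distances(nb: CellNeighborhood) -> np.ndarray:
    """Geodesic distance (m) from the query point to every neighborhood node."""
    d = np.empty(nb.values_before.shape, dtype=float)
    for (r, c) in np.ndindex(d.shape):
        d[r, c] = geodesic_distance(nb.query_lon, nb.query_lat,
                                    float(nb.node_lon[r, c]), float(nb.node_lat[r, c]))
    return d


def _bilinear(nb: CellNeighborhood, values: np.ndarray) -> float:
    fx, fy = nb.frac
    r, c = nb.core_row, nb.core_col
    ny, nx = values.shape
    # degenerate axes collapse to linear / point lookup
    r2 = min(r + 1, ny - 1)
    c2 = min(c + 1, nx - 1)
    v = np.array([[values[r, c], values[r, c2]],
                  [values[r2, c], values[r2, c2]]])
    w = np.array([[(1 - fx) * (1 - fy), fx * (1 - fy)],
                  [(1 - fx) * fy, fx * fy]])
    good = np.isfinite(v)
    if not good.any():
        return float("nan")
    ws = w[good].sum()
    if ws <= 0:
        # query sits exactly on (all-)missing corner(s); fall back to mean
        return float(np.nanmean(v))
    return float((w[good] * v[good]).sum() / ws)


def interp_spatial(nb: CellNeighborhood, values: np.ndarray,
                   method: InterpMethod) -> float:
    """Interpolate one timestamp's node values to the query location.

    ``values`` is the (ny, nx) node block (``nb.values_before`` or
    ``nb.values_after``).  Returns NaN when every node is missing.
    """
    values = np.asarray(values, dtype=float)
    good = np.isfinite(values)
    if not good.any():
        return float("nan")

    if method.spatial == "bilinear":
        return _bilinear(nb, values)

    d = _node_distances(nb)

    if method.spatial == "nearest_neighbour":
        dd = np.where(good, d, np.inf)
        r, c = np.unravel_index(int(np.argmin(dd)), dd.shape)
        return float(values[r, c])

    # inverse distance weighting
    hit = (d < EXACT_HIT_M) & good
    if hit.any():
        dd = np.where(hit, d, np.inf)
        r, c = np.unravel_index(int(np.argmin(dd)), dd.shape)
        return float(values[r, c])
    dflat = d[good]
    vflat = values[good]
    k = min(method.idw_k, dflat.size)
    if k == 1:  # single-neighbour IDW is exactly nearest neighbour
        return float(vflat[int(np.argmin(dflat))])
    sel = np.argsort(dflat, kind="stable")[:k]
    w = dflat[sel] ** (-method.idw_power_space)
    return float((w * vflat[sel]).sum() / w.sum())


def interp_temporal(v_before: float, v_after: float, t_before, t_after, t,
                    method: InterpMethod) -> float:
    """Interpolate the two spatially-interpolated values to the query time.

    Nearest-neighbour ties at the exact midpoint resolve to the *before*
    scene.  IDW weights are |t - t_k|^-p with p=1 by default, i.e. linear
    interpolation between the two scenes.  A missing side falls through to
    the other.
    """
    if t_before is None or t_after is None or t_before == t_after:
        if np.isfinite(v_before):
            return float(v_before)
        return float(v_after)
    if not (t_before <= t <= t_after):
        raise ValidationError(f"time {t} outside bracket [{t_before}, {t_after}]")
    vb_ok, va_ok = np.isfinite(v_before), np.isfinite(v_after)
    if not vb_ok and not va_ok:
        return float("nan")
    if not vb_ok:
        return float(v_after)
    if not va_ok:
        return float(v_before)
    if t == t_before:
        return float(v_before)
    if t == t_after:
        return float(v_after)
    if method.temporal == "nearest_neighbour":
        return float(v_before) if (t - t_before) <= (t_after - t) else float(v_after)
    wb = (t - t_before) ** (-method.idw_power_time)
    wa = (t_after - t) ** (-method.idw_power_time)
    return float((wb * v_before + wa * v_after) / (wb + wa))


def effective_method(var: GridVariable, method: InterpMethod) -> InterpMethod:
    """Categorical variables force nearest neighbour in both space and time."""
    if var.kind == "categorical":
        return NEAREST
    return method


def annotate_point(var: GridVariable, lon: float, lat: float, t=None,
                   method: InterpMethod = BILINEAR_LINEAR, z=None) -> float:
    """Annotate one WGS84 track point with ``var`` (space then time).

    The point is transformed into the variable's native CRS, its
    neighborhood located, interpolated spatially at the two bracketing
    scenes, then temporally to t.  Out-of-domain points yield NaN (the
    caller flags them); they never silently produce a value.
    """
    method = effective_method(var, method)
    x, y = project(lon, lat, var.crs)
    nb = locate_neighborhood(var, x, y, t, z=z, ring=method.ring)
    vb = interp_spatial(nb, nb.values_before, method)
    if nb.t_indices[0] == nb.t_indices[1]:
        va = vb
    else:
        va = interp_spatial(nb, nb.values_after, method)
    return interp_temporal(vb, va, nb.t_before, nb.t_after, nb.t_query, method)


def annotate_point_or_missing(var, lon, lat, t=None, method=BILINEAR_LINEAR, z=None):
    """Like :func:`annotate_point` but returns (value, ok) instead of raising
    for out-of-domain points."""
    try:
        return annotate_point(var, lon, lat, t, method, z), True
    except OutOfDomainError:
        return float("nan"), False
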