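"""Data model for n-dimensional gridded environmental variables.

A :class:`GridVariable` is an array over 1-4 named axes drawn from
``{x, y, z, t}``, in a declared CRS, with a missing-value convention and a
tile layout.  Grid coordinates are CELL CENTERS (the convention of
reanalysis and remote-sensing products), so a query point generally falls
between four centers; :func:`locate_neighborhood` finds those bracketing
nodes at the two scene timestamps around the query time, which is exactly
what the space-then-time interpolation consumes.

Tiles: the spatial plane is cut into ``tile_shape`` blocks; one block at one
timestamp is a *scene*, the unit of caching and fetching.
:func:`scenes_required` maps a batch of query points to the ordered,
de-duplicated list of scene keys they touch, so that I/O can be planned and
points processed in file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import OutOfDomainError, ValidationError
from .geo import CRS, normalize_lon, unproject

_AXIS_NAMES = ("t", "z", "y", "x")  # canonical dim order for stored values


@dataclass
class GridAxis:
    """One axis of a grid: a strictly monotone coordinate vector.

    ``spacing`` is the constant step for regular axes and ``None`` for
    irregular ones; when given it must match the successive differences to
    1e-9 relative tolerance.
    """

    name: str
    coordinates: np.ndarray
    spacing: Optional[float] = None

    def __post_init__(self):
        if self.name not in _AXIS_NAMES:
            raise ValidationError(f"axis name must be one of {_AXIS_NAMES}, got {self.name!r}")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 1 or self.coordinates.size == 0:
            raise ValidationError(f"axis {self.name!r}: coordinates must be a non-empty vector")
        d = np.diff(self.coordinates)
        if self.coordinates.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError(f"axis {self.name!r}: coordinates must be strictly monotone")
        if np.any(d < 0):
            raise ValidationError(
                f"axis {self.name!r}: decreasing axes must be flipped before construction")
        if self.spacing is not None:
            if self.coordinates.size > 1:
                scale = max(abs(self.spacing), 1.0)
                if np.max(np.abs(d - self.spacing)) > 1e-9 * scale:
                    raise ValidationError(
                        f"axis {self.name!r}: spacing {self.spacing} does not match coordinates")
            self.spacing = float(self.spacing)
        elif self.coordinates.size > 1:
            # auto-detect regular spacing
            step = float(d[0])
            if np.max(np.abs(d - step)) <= 1e-9 * max(abs(step), 1.0):
                self.spacing = step

    @property
    def is_regular(self) -> bool:
        return self.spacing is not None

    def __len__(self):
        return self.coordinates.size


def _sorted_axes(axes: Sequence[GridAxis]):
    order = {n: i for i, n in enumerate(_AXIS_NAMES)}
    return sorted(axes, key=lambda ax: order[ax.name])


@dataclass
class GridVariable:
    """An environmental variable on a 1-4 dimensional grid.

    ``values`` dims follow the canonical (t, z, y, x) order restricted to the
    axes present.  ``kind`` is ``"continuous"`` or ``"categorical"``;
    categorical variables carry the set of legal integer codes and only admit
    nearest-neighbour interpolation.  ``missing_value`` is a sentinel mapped
    to NaN on access (NaN itself always counts as missing).
    """

    id: str
    axes: list
    values: np.ndarray
    crs: CRS
    kind: str = "continuous"
    units: str = ""
    missing_value: Optional[float] = None
    tile_shape: Optional[tuple] = None  # (tile_ny, tile_nx)
    codes: Optional[frozenset] = None

    def __post_init__(self):
        if not 1 <= len(self.axes) <= 4:
            raise ValidationError(f"{self.id}: need 1-4 axes, got {len(self.axes)}")
        names = [ax.name for ax in self.axes]
        if len(set(names)) != len(names):
            raise ValidationError(f"{self.id}: duplicate axis names {names}")
        self.axes = _sorted_axes(self.axes)
        self.values = np.asarray(self.values)
        expected = tuple(len(ax) for ax in self.axes)
        if self.values.shape != expected:
            raise ValidationError(
                f"{self.id}: values shape {self.values.shape} != axes shape {expected}")
        if self.kind not in ("continuous", "categorical"):
            raise ValidationError(f"{self.id}: kind must be continuous|categorical")
        if self.kind == "categorical":
            if self.codes is None:
                present = self.values[np.isfinite(self.values)] if \
                    np.issubdtype(self.values.dtype, np.floating) else self.values
                self.codes = frozenset(int(c) for c in np.unique(present))
            else:
                self.codes = frozenset(int(c) for c in self.codes)
        ny = len(self.axis("y")) if self.axis("y") is not None else 1
        nx = len(self.axis("x")) if self.axis("x") is not None else 1
        if self.tile_shape is None:
            self.tile_shape = (ny, nx)
        else:
            ty, tx = self.tile_shape
            if ty <= 0 or tx <= 0:
                raise ValidationError(f"{self.id}: tile_shape must be positive")
            self.tile_shape = (int(ty), int(tx))

    # -- axis helpers -------------------------------------------------
    def axis(self, name: str) -> Optional[GridAxis]:
        for ax in self.axes:
            if ax.name == name:
                return ax
        return None

    @property
    def axis_names(self):
        return [ax.name for ax in self.axes]

    @property
    def n_nodes(self) -> int:
        return int(self.values.size)

    @property
    def x_is_circular(self) -> bool:
        """True for global regular longitude axes that wrap at the antimeridian."""
        ax = self.axis("x")
        if ax is None or not ax.is_regular or not self.crs.is_lonlat:
            return False
        return abs(len(ax) * ax.spacing - 360.0) <= 1e-6 * 360.0

    def node_value(self, **idx):
        """Value at integer node indices given per axis name (missing -> NaN)."""
        key = tuple(idx[ax.name] for ax in self.axes)
        v = self.values[key]
        return self._clean_scalar(v)

    def _clean_scalar(self, v):
        v = float(v)
        if self.missing_value is not None and v == self.missing_value:
            return float("nan")
        return v

    def clean(self, arr):
        """Array copy with the missing-value sentinel replaced by NaN."""
        out = np.asarray(arr, dtype=float)
        if self.missing_value is not None:
            out = np.where(out == self.missing_value, np.nan, out)
        return out

    # -- tiles and scenes ---------------------------------------------
    @property
    def n_tiles(self) -> tuple:
        ny = len(self.axis("y")) if self.axis("y") is not None else 1
        nx = len(self.axis("x")) if self.axis("x") is not None else 1
        ty, tx = self.tile_shape
        return (-(-ny // ty), -(-nx // tx))

    def tile_of_node(self, iy: int, ix: int) -> tuple:
        return (iy // self.tile_shape[0], ix // self.tile_shape[1])

    def scene_key(self, t_index: int, tile_index: tuple) -> tuple:
        return (self.id, int(t_index), tuple(tile_index))

    def scene_payload(self, t_index: int, tile_index: tuple) -> np.ndarray:
        """Extract the raw value block of one scene (edge tiles may be smaller)."""
        ty, tx = self.tile_shape
        jy, jx = tile_index
        ys = slice(jy * ty, (jy + 1) * ty)
        xs = slice(jx * tx, (jx + 1) * tx)
        sel = []
        for ax in self.axes:
            if ax.name == "t":
                sel.append(t_index)
            elif ax.name == "y":
                sel.append(ys)
            elif ax.name == "x":
                sel.append(xs)
            else:  # z: whole column rides along in the scene
                sel.append(slice(None))
        return self.values[tuple(sel)].copy()


@dataclass
class Scene:
    """One cached raster block: (variable, tile, timestamp) plus its payload."""

    key: tuple
    payload: np.ndarray
    access_count: int = 0
    last_access: float = 0.0


@dataclass
class CellNeighborhood:
    """The grid nodes bracketing a query point at two bracketing timestamps.

    ``values_before``/``values_after`` are (ny, nx) blocks over ``iy`` x
    ``ix``; the core 2x2 bracketing cell starts at (``core_row``,
    ``core_col``) and ``frac`` is the query's fractional position inside it.
    ``node_lon``/``node_lat`` give each node's WGS84 position for geodesic
    distance weighting.
    """

    ix: np.ndarray
    iy: np.ndarray
    node_x: np.ndarray
    node_y: np.ndarray
    node_lon: np.ndarray  # (ny, nx)
    node_lat: np.ndarray
    values_before: np.ndarray
    values_after: np.ndarray
    t_before: Optional[float]
    t_after: Optional[float]
    t_query: Optional[float]
    frac: tuple
    core_row: int
    core_col: int
    query_lon: float
    query_lat: float
    t_indices: tuple = (0, 0)

    @property
    def n_nodes(self) -> int:
        return self.values_before.size


def build_grid_variable(axes, values, crs=None, kind="continuous", tile_shape=None,
                        var_id="var", units="", missing_value=None, codes=None) -> GridVariable:
    """Validate and assemble a :class:`GridVariable`.

    ``axes`` may be :class:`GridAxis` objects or ``(name, coordinates)``
    pairs.  Raises :class:`ValidationError` on non-monotone axes, a shape
    mismatch, or an axis count outside 1-4.
    """
    built = []
    for ax in axes:
        if isinstance(ax, GridAxis):
            built.append(ax)
        else:
            name, coords = ax[0], ax[1]
            built.append(GridAxis(name, np.asarray(coords, dtype=float)))
    if crs is None:
        crs = CRS.wgs84()
    return GridVariable(id=var_id, axes=built, values=np.asarray(values),
                        crs=crs, kind=kind, tile_shape=tile_shape, units=units,
                        missing_value=missing_value,
                        codes=frozenset(codes) if codes is not None else None)


# ---------------------------------------------------------------------------
# Neighborhood location
# ---------------------------------------------------------------------------

def _bracket_index(axis: GridAxis, v: float, circular: bool):
    """Return (i0, frac, wrapped) so the cell is [i0, i0+1] (or the seam cell)."""
    c = axis.coordinates
    n = c.size
    if n == 1:
        if abs(v - c[0]) > 1e-9 * max(1.0, abs(c[0])):
            raise OutOfDomainError(f"coordinate {v} off the single-node axis {axis.name!r}")
        return 0, 0.0, False
    if v < c[0] or v > c[-1]:
        if circular:
            # the seam cell spans c[-1] .. c[0]+360
            span = (v - c[-1]) % 360.0
            if span <= axis.spacing + 1e-9:
                return n - 1, span / axis.spacing, True
        raise OutOfDomainError(
            f"coordinate {v} outside axis {axis.name!r} domain [{c[0]}, {c[-1]}]")
    i = int(np.searchsorted(c, v, side="right")) - 1
    if i >= n - 1:  # exactly the last node
        return n - 2, 1.0, False
    frac = (v - c[i]) / (c[i + 1] - c[i])
    return i, float(frac), False


def _bracket_time(var: GridVariable, t: Optional[float]):
    """Bracketing (t_before_idx, t_after_idx, t_before, t_after); clamps one
    scene interval past the edges with a warning, errors beyond that."""
    ax = var.axis("t")
    if ax is None:
        return 0, 0, None, None
    if t is None:
        raise ValidationError(f"{var.id}: variable has a time axis but no query time given")
    c = ax.coordinates
    if c.size == 1:
        interval = np.inf
    else:
        interval = float(np.median(np.diff(c)))
    if t < c[0]:
        if c[0] - t <= interval:
            warnings.warn(f"{var.id}: time {t} before first scene; clamped", stacklevel=3)
            return 0, 0, float(c[0]), float(c[0])
        raise OutOfDomainError(f"{var.id}: time {t} more than one scene interval before domain")
    if t > c[-1]:
        if t - c[-1] <= interval:
            warnings.warn(f"{var.id}: time {t} after last scene; clamped", stacklevel=3)
            k = c.size - 1
            return k, k, float(c[-1]), float(c[-1])
        raise OutOfDomainError(f"{var.id}: time {t} more than one scene interval after domain")
    i = int(np.searchsorted(c, t, side="left"))
    if i < c.size and c[i] == t:
        return i, i, float(c[i]), float(c[i])
    return i - 1, i, float(c[i - 1]), float(c[i])


def _nearest_index(axis: GridAxis, v: float) -> int:
    i0, frac, wrapped = _bracket_index(axis, v, False)
    return i0 if frac <= 0.5 else i0 + 1


def locate_neighborhood(var: GridVariable, x: float, y: float, t=None, z=None,
                        ring: int = 1) -> CellNeighborhood:
    """Locate the grid nodes around a native-coordinate query point.

    ``ring=1`` gives the 4 bracketing nodes (2x2); larger rings expand the
    block symmetrically (clipped at grid edges, wrapped on circular longitude
    axes) for inverse-distance weighting with more than 4 neighbours.  The
    vertical axis, when present, is resolved to the nearest level.
    """
    ax_x, ax_y = var.axis("x"), var.axis("y")
    if ax_x is None:
        raise ValidationError(f"{var.id}: variable has no x axis")
    circ = var.x_is_circular
    if var.crs.is_lonlat:
        x = float(normalize_lon(x))
    ix0, fx, wrapped = _bracket_index(ax_x, x, circ)
    nx_axis = len(ax_x)

    if ax_y is not None:
        iy0, fy, _ = _bracket_index(ax_y, y, False)
        ny_axis = len(ax_y)
    else:
        iy0, fy, ny_axis = 0, 0.0, 1

    kb, ka, t_before, t_after = _bracket_time(var, t)

    z_idx = None
    ax_z = var.axis("z")
    if ax_z is not None:
        z_idx = _nearest_index(ax_z, float(z) if z is not None else float(ax_z.coordinates[0]))

    # assemble ring index lists around the core cell
    def ring_indices(i0, n, wrap):
        lo, hi = i0 - (ring - 1), i0 + ring
        if n == 1:
            return np.array([0]), 0
        if wrap:
            idx = np.arange(lo, hi + 1) % n
            core = ring - 1
        else:
            lo_c, hi_c = max(0, lo), min(n - 1, hi)
            idx = np.arange(lo_c, hi_c + 1)
            core = i0 - lo_c
        return idx, core

    ix, core_col = ring_indices(ix0, nx_axis, circ)
    iy, core_row = ring_indices(iy0, ny_axis, False) if ax_y is not None else (np.array([0]), 0)

    # native node coordinates (seam cells get +360 continuity for display only)
    node_x = ax_x.coordinates[ix]
    node_y = ax_y.coordinates[iy] if ax_y is not None else np.array([y], dtype=float)

    def block(t_idx):
        sel = []
        for ax in var.axes:
            if ax.name == "t":
                sel.append(t_idx)
            elif ax.name == "z":
                sel.append(z_idx)
            elif ax.name == "y":
                sel.append(iy[:, None])
            elif ax.name == "x":
                sel.append(ix[None, :] if ax_y is not None else ix)
        out = np.atleast_2d(var.values[tuple(sel)])
        return var.clean(out)

    vb = block(kb)
    va = block(ka) if ka != kb else vb.copy()

    # WGS84 positions of nodes, for geodesic distance weighting
    XX, YY = np.meshgrid(node_x, node_y)
    if var.crs.is_lonlat:
        lon_grid, lat_grid = normalize_lon(XX), YY
        q_lon, q_lat = float(normalize_lon(x)), float(y)
    else:
        lon_grid = np.empty_like(XX)
        lat_grid = np.empty_like(YY)
        for (r, cidx), xv in np.ndenumerate(XX):
            lo, la = unproject(float(xv), float(YY[r, cidx]), var.crs)
            lon_grid[r, cidx], lat_grid[r, cidx] = lo, la
        q_lon, q_lat = unproject(float(x), float(y), var.crs)

    return CellNeighborhood(
        ix=ix, iy=iy, node_x=node_x, node_y=node_y,
        node_lon=lon_grid, node_lat=lat_grid,
        values_before=vb, values_after=va,
        t_before=t_before, t_after=t_after,
        t_query=float(t) if t is not None else None,
        frac=(fx, fy), core_row=core_row, core_col=core_col,
        query_lon=q_lon, query_lat=q_lat,
        t_indices=(kb, ka))


def scenes_required(points, var: GridVariable, ring: int = 1):
    """Ordered, de-duplicated scene keys needed to annotate ``points``.

    ``points`` are (x, y, t) triples in the variable's native CRS (``t`` may
    be ``None`` for static variables).  Keys sort by (variable, timestamp
    index, tile index), the file order used for batched reads.
    """
    if len(points) == 0:
        raise ValidationError("scenes_required: empty point list")
    keys = set()
    for pt in points:
        x, y = pt[0], pt[1]
        t = pt[2] if len(pt) > 2 else None
        nb = locate_neighborhood(var, x, y, t, ring=ring)
        for t_idx in set(nb.t_indices):
            for yi in nb.iy:
                for xi in nb.ix:
                    keys.add(var.scene_key(t_idx, var.tile_of_node(int(yi), int(xi))))
    return sorted(keys, key=lambda k: (k[0], k[1], k[2]))
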