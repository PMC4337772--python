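"""End-to-end track and area annotation.

Tracks are pandas DataFrames with Movebank-style columns
(``individual-local-identifier``, ``timestamp``, ``location-long``,
``location-lat``); annotation appends one value column per requested
(variable, method) pair, named ``<dataset>.<variable>.<spatial>-<temporal>``,
leaving every input column and the row order untouched.  Missing
annotations (out-of-domain points, all-missing neighborhoods) are NaN and
counted in the run log — never a silent zero.

Internally points are processed in scene-sorted order (the file order of
the underlying archive) and values are read through the scene cache when
one is supplied; both are invisible in the output, which is a pure function
of (track, request, datasets).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from . import derived as dv
from .cache import SceneCache, variable_provider
from .errors import OutOfDomainError, RequestError, ValidationError
from .geo import CRS, geodesic_distance, initial_bearing, project, unproject
from .grid import GridVariable, locate_neighborhood, scenes_required
from .interpolation import (InterpMethod, NEAREST, annotate_point,
                            effective_method, interp_spatial, interp_temporal)
from .request import AnnotationRequest, AreaSpec, DerivedRequest, VariableRequest
from .times import parse_timestamp

logger = logging.getLogger("envtrack")

IND_COL = "individual-local-identifier"
TIME_COL = "timestamp"
LON_COL = "location-long"
LAT_COL = "location-lat"

#: Case-study segmentation defaults: transit = speed > 5 m/s between 90 W
#: and 82.5 W; coastal foraging between 82.5 W and 75 W.
SPEED_THRESHOLD_MPS = 5.0
TRANSIT_LON_BAND = (-90.0, -82.5)
COASTAL_LON_BAND = (-82.5, -75.0)


def _require_track_columns(track: pd.DataFrame):
    missing = [c for c in (IND_COL, TIME_COL, LON_COL, LAT_COL) if c not in track.columns]
    if missing:
        raise ValidationError(f"track is missing columns {missing}")
    if (track[LAT_COL].abs() > 90).any():
        raise ValidationError("track has |latitude| > 90")


def track_epochs(track: pd.DataFrame) -> np.ndarray:
    """Timestamps of a track as UTC epoch seconds."""
    return np.array([parse_timestamp(t) for t in track[TIME_COL]], dtype=float)


def compute_heading_speed(track: pd.DataFrame) -> pd.DataFrame:
    """Per-fix ground speed and flight heading from consecutive fixes.

    Forward differences: speed_i and heading_i describe the segment from
    fix i to fix i+1; the last fix of each individual inherits the previous
    heading (its speed is NaN).  Stationary segments have speed 0 and NaN
    heading.  Duplicate timestamps within an individual are an error.
    """
    _require_track_columns(track)
    out = track.copy()
    out["ground-speed"] = np.nan
    out["heading"] = np.nan
    epochs = track_epochs(track)
    for ind, idx in track.groupby(IND_COL, sort=False).groups.items():
        idx = np.asarray(idx)
        t = epochs[[track.index.get_loc(i) for i in idx]]
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"individual {ind!r}: timestamps not strictly increasing")
        lons = track.loc[idx, LON_COL].to_numpy(dtype=float)
        lats = track.loc[idx, LAT_COL].to_numpy(dtype=float)
        headings = np.full(idx.size, np.nan)
        speeds = np.full(idx.size, np.nan)
        for k in range(idx.size - 1):
            d = geodesic_distance(lons[k], lats[k], lons[k + 1], lats[k + 1])
            speeds[k] = d / (t[k + 1] - t[k])
            if d > 0:
                headings[k] = initial_bearing(lons[k], lats[k], lons[k + 1], lats[k + 1])
        if idx.size >= 2:
            headings[-1] = headings[-2]  # last fix inherits
        out.loc[idx, "ground-speed"] = speeds
        out.loc[idx, "heading"] = headings
    return out


def segment_track(track: pd.DataFrame,
                  speed_threshold: float = SPEED_THRESHOLD_MPS,
                  transit_lon=TRANSIT_LON_BAND,
                  coastal_lon=COASTAL_LON_BAND) -> pd.DataFrame:
    """Label each fix transit / coastal_foraging / other.

    Transit: ground speed strictly above the threshold AND longitude in the
    transit band; coastal_foraging: longitude in the coastal band (any
    speed); everything else: other.  Bands are half-open [west, east), so
    the shared boundary belongs to the coastal band.
    """
    if "ground-speed" not in track.columns:
        track = compute_heading_speed(track)
    out = track.copy()
    lon = out[LON_COL].to_numpy(dtype=float)
    speed = out["ground-speed"].to_numpy(dtype=float)
    in_transit_band = (lon >= transit_lon[0]) & (lon < transit_lon[1])
    in_coastal_band = (lon >= coastal_lon[0]) & (lon < coastal_lon[1])
    labels = np.where(in_coastal_band, "coastal_foraging",
                      np.where(in_transit_band & (speed > speed_threshold),
                               "transit", "other"))
    out["segment"] = labels
    return out


def label_direction(track: pd.DataFrame) -> pd.DataFrame:
    """Label each fix outbound/return/hold by its longitude trend
    (eastbound toward the coast = outbound for the case-study geometry)."""
    out = track.copy()
    labels = []
    for _, g in out.groupby(IND_COL, sort=False):
        dlon = np.diff(g[LON_COL].to_numpy(dtype=float), append=np.nan)
        lab = np.where(dlon > 0, "outbound", np.where(dlon < 0, "return", "hold"))
        if len(lab) >= 2:
            lab[-1] = lab[-2]
        labels.extend(lab)
    out["direction"] = labels
    return out


# ---------------------------------------------------------------------------
# Cached neighborhood reads
# ---------------------------------------------------------------------------

def _value_from_scenes(var: GridVariable, cache: SceneCache, provider,
                       t_idx: int, iy: int, ix: int) -> float:
    key = var.scene_key(t_idx, var.tile_of_node(iy, ix))
    sc = cache.get_scene(key, provider)
    ty, tx = var.tile_shape
    off_y, off_x = iy - key[2][0] * ty, ix - key[2][1] * tx
    payload = sc.payload
    if payload.ndim == 1:  # x-only variable
        return var._clean_scalar(payload[off_x])
    return var._clean_scalar(payload[..., off_y, off_x] if payload.ndim > 2
                             else payload[off_y, off_x])


def _annotate_point_cached(var, lon, lat, t, method, cache, provider):
    method = effective_method(var, method)
    x, y = project(lon, lat, var.crs)
    nb = locate_neighborhood(var, x, y, t, ring=method.ring)
    for which, t_idx in (("values_before", nb.t_indices[0]),
                         ("values_after", nb.t_indices[1])):
        block = np.empty((nb.iy.size, nb.ix.size))
        for r, iy in enumerate(nb.iy):
            for c, ix in enumerate(nb.ix):
                block[r, c] = _value_from_scenes(var, cache, provider,
                                                 int(t_idx), int(iy), int(ix))
        setattr(nb, which, block)
    vb = interp_spatial(nb, nb.values_before, method)
    va = vb if nb.t_indices[0] == nb.t_indices[1] else \
        interp_spatial(nb, nb.values_after, method)
    return interp_temporal(vb, va, nb.t_before, nb.t_after, nb.t_query, method)


# ---------------------------------------------------------------------------
# Track annotation
# ---------------------------------------------------------------------------

def _validate_request(request: AnnotationRequest, datasets: dict):
    failures = []
    for item in request.variables:
        if isinstance(item, VariableRequest):
            var = datasets.get(item.var_id)
            if var is None:
                failures.append(f"unknown variable {item.var_id!r}")
                continue
            if var.kind == "categorical" and (
                    item.method.spatial != "nearest_neighbour"
                    or item.method.temporal != "nearest_neighbour"):
                failures.append(
                    f"{item.var_id!r} is categorical: only the nearest neighbor "
                    f"interpolation can be applied (got {item.method.spatial}/"
                    f"{item.method.temporal})")
        elif isinstance(item, DerivedRequest):
            for role, vid in item.inputs.items():
                if vid not in datasets:
                    failures.append(
                        f"derived {item.kind!r}: unknown input variable {vid!r} "
                        f"for role {role!r}")
        else:
            failures.append(f"unrecognized request item {item!r}")
    if failures:
        raise RequestError(failures)


def _annotate_variable_column(track, epochs, var, method, cache):
    """One variable annotated at every fix, scene-sorted internally."""
    lons = track[LON_COL].to_numpy(dtype=float)
    lats = track[LAT_COL].to_numpy(dtype=float)
    n = len(track)
    values = np.full(n, np.nan)
    missing = 0

    # order points by the scenes they need (timestamp bracket, then tile)
    order_keys = []
    for i in range(n):
        try:
            x, y = project(lons[i], lats[i], var.crs)
            nb = locate_neighborhood(var, x, y,
                                     epochs[i] if var.axis("t") is not None else None)
            core = (int(nb.t_indices[0]),
                    var.tile_of_node(int(nb.iy[nb.core_row]), int(nb.ix[nb.core_col])))
        except (OutOfDomainError, ValidationError):
            core = (np.iinfo(np.int32).max, (0, 0))
        order_keys.append(core)
    order = sorted(range(n), key=lambda i: (order_keys[i], i))

    provider = variable_provider(var) if cache is not None else None
    t_needed = var.axis("t") is not None
    for i in order:
        t = epochs[i] if t_needed else None
        try:
            if cache is not None:
                v = _annotate_point_cached(var, lons[i], lats[i], t, method,
                                           cache, provider)
            else:
                v = annotate_point(var, lons[i], lats[i], t, method)
        except OutOfDomainError as exc:
            logger.warning("point %d outside domain of %s: %s", i, var.id, exc)
            v = np.nan
        if not np.isfinite(v):
            missing += 1
        values[i] = v
    return values, missing


def _scene_count(track, epochs, var):
    lons = track[LON_COL].to_numpy(dtype=float)
    lats = track[LAT_COL].to_numpy(dtype=float)
    pts = []
    for i in range(len(track)):
        try:
            x, y = project(lons[i], lats[i], var.crs)
            locate_neighborhood(var, x, y, epochs[i] if var.axis("t") is not None else None)
            pts.append((x, y, epochs[i] if var.axis("t") is not None else None))
        except (OutOfDomainError, ValidationError):
            continue
    if not pts:
        return 0
    return len(scenes_required(pts, var))


def annotate_track(track: pd.DataFrame, request: AnnotationRequest,
                   datasets: dict, cache: Optional[SceneCache] = None):
    """Annotate every fix of ``track`` with the requested variables.

    Returns ``(annotated DataFrame, run log dict)``.  The output has the
    input's rows in the input's order plus one column per request item;
    the log reports per-column scene counts, cache statistics, and missing
    annotation counts.
    """
    _require_track_columns(track)
    _validate_request(request, datasets)
    epochs = track_epochs(track)
    out = track.copy()
    log = {"columns": {}, "cache": None}

    needs_heading = any(isinstance(it, DerivedRequest) and it.needs_heading
                        for it in request.variables)
    hs = compute_heading_speed(track) if needs_heading else None

    annotated = {}

    def column_for(var_id, method):
        key = (var_id, method)
        if key not in annotated:
            var = datasets[var_id]
            vals, miss = _annotate_variable_column(out, epochs, var,
                                                   effective_method(var, method), cache)
            annotated[key] = (vals, miss)
        return annotated[key]

    for item in request.variables:
        if isinstance(item, VariableRequest):
            vals, miss = column_for(item.var_id, item.method)
            out[item.column] = vals
            log["columns"][item.column] = {
                "scenes_required": _scene_count(out, epochs, datasets[item.var_id]),
                "missing": int(miss)}
        else:
            out[item.column] = _derived_column(item, out, epochs, datasets,
                                               column_for, hs)
            log["columns"][item.column] = {
                "missing": int(np.sum(~np.isfinite(out[item.column].to_numpy())))}
    if cache is not None:
        log["cache"] = cache.stats()
    return out, log


def _derived_column(item: DerivedRequest, track, epochs, datasets, column_for, hs):
    n = len(track)
    vals = np.full(n, np.nan)
    if item.kind in ("wind_speed", "wind_direction", "tailwind", "crosswind"):
        u, _ = column_for(item.inputs["u"], item.method)
        v, _ = column_for(item.inputs["v"], item.method)
        for i in range(n):
            if not (np.isfinite(u[i]) and np.isfinite(v[i])):
                continue
            if item.kind in ("wind_speed", "wind_direction"):
                spd, dirn = dv.wind_speed_direction(u[i], v[i])
                vals[i] = spd if item.kind == "wind_speed" else dirn
            else:
                heading = hs["heading"].to_numpy(dtype=float)[i]
                if not np.isfinite(heading):
                    continue
                tail, cross = dv.wind_support(u[i], v[i], heading,
                                              cross_from_right=item.cross_from_right)
                vals[i] = tail if item.kind == "tailwind" else cross
        return vals
    if item.kind == "thermal_uplift":
        H, _ = column_for(item.inputs["H"], item.method)
        zi, _ = column_for(item.inputs["z_i"], item.method)
        T, _ = column_for(item.inputs["T"], item.method)
        for i in range(n):
            if np.isfinite(H[i]) and np.isfinite(zi[i]) and np.isfinite(T[i]):
                vals[i] = dv.thermal_uplift(H[i], zi[i], T[i])
        return vals
    # orographic uplift: wind at the fix + terrain of the nearest DEM cell
    u, _ = column_for(item.inputs["u"], item.method)
    v, _ = column_for(item.inputs["v"], item.method)
    dem = datasets[item.inputs["dem"]]
    lons = track[LON_COL].to_numpy(dtype=float)
    lats = track[LAT_COL].to_numpy(dtype=float)
    for i in range(n):
        if not (np.isfinite(u[i]) and np.isfinite(v[i])):
            continue
        try:
            x, y = project(lons[i], lats[i], dem.crs)
            nb = locate_neighborhood(dem, x, y)
        except OutOfDomainError:
            continue
        fx, fy = nb.frac
        r = min(nb.core_row + (1 if fy > 0.5 else 0), nb.iy.size - 1)
        c = min(nb.core_col + (1 if fx > 0.5 else 0), nb.ix.size - 1)
        iy, ix = int(nb.iy[r]), int(nb.ix[c])
        cell = dv.terrain_at_node(dem, iy, ix)
        vals[i] = dv.orographic_uplift(u[i], v[i], cell, clamp_zero=item.clamp_zero)
    return vals


# ---------------------------------------------------------------------------
# Area annotation
# ---------------------------------------------------------------------------

def annotate_area(request: AnnotationRequest, datasets: dict):
    """Annotate every pixel center of the requested rectangle.

    Returns a list of ``(column_name, timestamp, array, transform)`` rasters,
    one per (variable, timestamp), row 0 at the north edge.  ``transform``
    is the (west, north, dx, dy) edge-registered affine.  Requesting a
    variable's own grid at native resolution with nearest-neighbour
    reproduces the stored scene exactly.
    """
    if request.mode != "area" or request.area is None:
        raise RequestError("annotate_area needs an area-mode request")
    _validate_request(request, datasets)
    area: AreaSpec = request.area
    area_crs = CRS(area.crs_name) if area.crs_name == "wgs84_lonlat" else None
    if area_crs is None:
        raise RequestError(f"area CRS {area.crs_name!r} not supported for requests")
    dx = (area.east - area.west) / area.nx
    dy = (area.north - area.south) / area.ny
    xc = area.west + (np.arange(area.nx) + 0.5) * dx
    yc = area.north - (np.arange(area.ny) + 0.5) * dy  # row 0 = north
    rasters = []
    for item in request.variables:
        if not isinstance(item, VariableRequest):
            raise RequestError(f"area mode supports primary variables only, got {item!r}")
        var = datasets[item.var_id]
        method = effective_method(var, item.method)
        for ts in area.timestamps:
            t = parse_timestamp(ts)
            arr = np.full((area.ny, area.nx), np.nan)
            for r in range(area.ny):
                for c in range(area.nx):
                    try:
                        arr[r, c] = annotate_point(var, float(xc[c]), float(yc[r]),
                                                   t if var.axis("t") is not None else None,
                                                   method)
                    except OutOfDomainError:
                        pass
            rasters.append((item.column, t, arr,
                            {"west": area.west, "north": area.north,
                             "dx": dx, "dy": dy}))
    return rasters
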