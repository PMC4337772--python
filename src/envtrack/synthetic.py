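"""Synthetic gridded fields and tracks with known closed forms.

Every field form here comes with an exact oracle f(lon, lat, t) so that the
whole annotation pipeline can be verified end to end without downloading any
real archive: node values are the oracle evaluated at node centers, and an
annotated value can be compared against the oracle at the query point.

Forms
-----
``affine``            a + b*lon + c*lat + d*t_hours — bilinear space +
                      linear time interpolation reproduce it exactly.
``sinusoidal``        smooth periodic field, for convergence/error checks.
``categorical_mosaic`` seeded integer-code blocks (land-cover stand-in).
``uniform``           constant field (calm wind components, flat DEM).
``banded_wind``       easterly band south of a split latitude, westerly
                      north of it — a crude trade-wind/westerlies pattern so
                      a clockwise loop track sees head wind outbound and
                      tail wind on return, the qualitative signature of the
                      albatross case study.
``dem_plane``         z = z0 + gx*lon + gy*lat (per-degree gradients).
``dem_hill``          Gaussian hill on a flat plain.

Tracks are generated along ellipsoidal geodesics between waypoints at a
constant speed with fixes at a constant interval (default 90 min, a typical
seabird GPS duty cycle), pausing at each waypoint until the next fix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geo import CRS, destination_point, geodesic_distance, initial_bearing, project, unproject
from .grid import GridAxis, GridVariable, build_grid_variable
from .times import format_timestamp

FORMS = ("affine", "sinusoidal", "categorical_mosaic", "uniform",
         "banded_wind", "dem_plane", "dem_hill")


@dataclass
class FieldSpec:
    """Recipe for one synthetic gridded variable.

    Axes are given as (start, step, count) triples in the native CRS units
    (degrees for lon/lat grids, meters for projected ones).  ``times`` are
    scene timestamps in epoch seconds (``None`` for static fields).
    """

    form: str
    params: dict = dc_field(default_factory=dict)
    x: tuple = (0.0, 1.0, 11)
    y: tuple = (0.0, 1.0, 11)
    times: Optional[Sequence[float]] = None
    crs: CRS = dc_field(default_factory=CRS.wgs84)
    tile_shape: Optional[tuple] = None
    missing_fraction: float = 0.0
    seed: int = 0
    var_id: str = "synthetic.var"
    units: str = ""

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValidationError(f"unknown field form {self.form!r}")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must be in [0, 1)")


def _axis_coords(triple):
    start, step, n = triple
    return start + step * np.arange(int(n))


def _oracle(spec: FieldSpec) -> Callable:
    """Closed-form evaluator f(lon, lat, t_epoch) in WGS84 coordinates."""
    p = spec.params
    t0 = float(spec.times[0]) if spec.times is not None else 0.0

    if spec.form == "affine":
        a, b, c, d = p.get("a", 0.0), p.get("b", 0.0), p.get("c", 0.0), p.get("d", 0.0)

        def f(lon, lat, t=None):
            th = 0.0 if t is None else (float(t) - t0) / 3600.0
            return a + b * lon + c * lat + d * th
        return f

    if spec.form == "sinusoidal":
        A = p.get("amplitude", 1.0)
        lx = p.get("wavelength_x", 20.0)
        ly = p.get("wavelength_y", 20.0)
        drift = p.get("drift_per_hour", 0.0)

        def f(lon, lat, t=None):
            th = 0.0 if t is None else (float(t) - t0) / 3600.0
            return (A * math.sin(2 * math.pi * lon / lx)
                    * math.cos(2 * math.pi * lat / ly) + drift * th)
        return f

    if spec.form == "uniform":
        value = p.get("value", 0.0)
        return lambda lon, lat, t=None: float(value)

    if spec.form == "banded_wind":
        u0 = p.get("u0", 8.0)
        lat_split = p.get("lat_split", -5.0)

        def f(lon, lat, t=None):
            return float(u0 if lat >= lat_split else -u0)
        return f

    if spec.form == "dem_plane":
        z0, gx, gy = p.get("z0", 0.0), p.get("gx", 0.0), p.get("gy", 0.0)
        return lambda lon, lat, t=None: z0 + gx * lon + gy * lat

    if spec.form == "dem_hill":
        h = p.get("height", 1000.0)
        lon0, lat0 = p.get("lon0", 0.0), p.get("lat0", 0.0)
        sigma = p.get("sigma", 2.0)

        def f(lon, lat, t=None):
            r2 = (lon - lon0) ** 2 + (lat - lat0) ** 2
            return h * math.exp(-r2 / (2 * sigma * sigma))
        return f

    raise ValidationError(f"no closed form for {spec.form!r}")  # categorical


def make_field(spec: FieldSpec):
    """Build a GridVariable from a spec; returns ``(variable, oracle)``.

    The oracle takes WGS84 ``(lon, lat, t_epoch)`` and equals the stored
    node values at node centers.  Categorical mosaics have no closed form;
    their oracle is a node lookup.
    """
    xc = _axis_coords(spec.x)
    yc = _axis_coords(spec.y)
    axes = [GridAxis("y", yc), GridAxis("x", xc)]
    shape = [yc.size, xc.size]
    if spec.times is not None:
        tc = np.asarray([float(t) for t in spec.times])
        axes.insert(0, GridAxis("t", tc))
        shape.insert(0, tc.size)
    rng = np.random.default_rng(spec.seed)

    if spec.form == "categorical_mosaic":
        codes = list(spec.params.get("codes", [11, 14, 20]))
        block = int(spec.params.get("block_size", 3))
        by = -(-yc.size // block)
        bx = -(-xc.size // block)
        mosaic = rng.choice(codes, size=(by, bx))
        plane = np.repeat(np.repeat(mosaic, block, axis=0), block, axis=1)[:yc.size, :xc.size]
        values = np.broadcast_to(plane, shape).copy() if spec.times is not None else plane
        var = build_grid_variable(axes, values.astype(float), crs=spec.crs,
                                  kind="categorical", tile_shape=spec.tile_shape,
                                  var_id=spec.var_id, codes=codes)

        def oracle(lon, lat, t=None):
            ix = int(round((lon - xc[0]) / (xc[1] - xc[0])))
            iy = int(round((lat - yc[0]) / (yc[1] - yc[0])))
            return float(plane[iy, ix])
        return var, oracle

    f = _oracle(spec)
    # node lon/lat (native grids may be projected)
    if spec.crs.is_lonlat:
        lon_nodes, lat_nodes = np.meshgrid(xc, yc)
    else:
        lon_nodes = np.empty((yc.size, xc.size))
        lat_nodes = np.empty((yc.size, xc.size))
        for (r, c) in np.ndindex(lon_nodes.shape):
            lon_nodes[r, c], lat_nodes[r, c] = unproject(xc[c], yc[r], spec.crs)

    def plane_at(t):
        out = np.empty((yc.size, xc.size))
        for (r, c) in np.ndindex(out.shape):
            out[r, c] = f(lon_nodes[r, c], lat_nodes[r, c], t)
        return out

    if spec.times is not None:
        values = np.stack([plane_at(float(t)) for t in spec.times])
    else:
        values = plane_at(None)

    if spec.missing_fraction > 0:
        mask = rng.random(values.shape) < spec.missing_fraction
        values = np.where(mask, np.nan, values)

    var = build_grid_variable(axes, values, crs=spec.crs, kind="continuous",
                              tile_shape=spec.tile_shape, var_id=spec.var_id,
                              units=spec.units)
    return var, f


def make_wind_pair(u_spec: FieldSpec, v_spec: FieldSpec):
    """Convenience: build (u_var, v_var, u_oracle, v_oracle) wind components."""
    u_var, u_f = make_field(u_spec)
    v_var, v_f = make_field(v_spec)
    return u_var, v_var, u_f, v_f


@dataclass
class TrackSpec:
    """Recipe for a synthetic GPS track along geodesic waypoint legs.

    The default 90-minute fix interval matches a typical seabird GPS duty
    cycle.  ``loop=True`` appends the first waypoint so the track closes.
    """

    waypoints: Sequence[tuple]
    speed_mps: float = 10.0
    fix_interval_s: float = 5400.0
    start_time: float = 0.0
    individual: str = "ind1"
    loop: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.waypoints) < 2 and not self.loop:
            raise ValidationError("need at least two waypoints")
        if self.speed_mps <= 0 or self.fix_interval_s <= 0:
            raise ValidationError("speed and fix interval must be positive")


def make_track(spec: TrackSpec) -> pd.DataFrame:
    """Generate fixes every ``fix_interval_s`` along the waypoint path.

    Movement follows the ellipsoidal geodesic of each leg at constant speed;
    the carrier pauses at each waypoint until the next fix (so waypoints,
    including loop closure, appear exactly in the output).  Returns a
    Movebank-style DataFrame (individual-local-identifier, timestamp,
    location-long, location-lat).
    """
    wps = [(float(lo), float(la)) for lo, la in spec.waypoints]
    if spec.loop and wps[0] != wps[-1]:
        wps.append(wps[0])
    step = spec.speed_mps * spec.fix_interval_s
    fixes = [wps[0]]
    for a, b in zip(wps[:-1], wps[1:]):
        cur = fixes[-1]  # always == a (we clamp at each waypoint)
        leg = geodesic_distance(a[0], a[1], b[0], b[1])
        traveled = 0.0
        while traveled + step < leg - 1e-6:
            traveled += step
            brg = initial_bearing(cur[0], cur[1], b[0], b[1])
            cur = destination_point(cur[0], cur[1], brg, step)
            fixes.append(cur)
        fixes.append(b)
    times = spec.start_time + spec.fix_interval_s * np.arange(len(fixes))
    return pd.DataFrame({
        "individual-local-identifier": spec.individual,
        "timestamp": [format_timestamp(t) for t in times],
        "location-long": [p[0] for p in fixes],
        "location-lat": [p[1] for p in fixes],
    })


def albatross_like_scenario(seed: int = 0):
    """A small study-shaped scenario: banded wind over the eastern Pacific
    and a clockwise island-coast loop track.

    Returns ``(track, datasets, oracles)`` where datasets map variable ids
    to GridVariables (u/v wind at 6-hour scenes) and oracles their closed
    forms.  The loop lies wholly in the easterly (u < 0) band, so the
    eastbound outbound flight meets head winds and the westbound return is
    wind-assisted — the qualitative case-study signature.
    """
    times = [float(k) * 21600.0 for k in range(40)]  # 10 days of 6-hour scenes
    u_spec = FieldSpec(form="banded_wind", params={"u0": 8.0, "lat_split": 5.0},
                       x=(-95.0, 2.5, 11), y=(-15.0, 2.5, 11), times=times,
                       var_id="wind.u", seed=seed, units="m/s")
    v_spec = FieldSpec(form="uniform", params={"value": 0.0},
                       x=(-95.0, 2.5, 11), y=(-15.0, 2.5, 11), times=times,
                       var_id="wind.v", seed=seed, units="m/s")
    u_var, v_var, u_f, v_f = make_wind_pair(u_spec, v_spec)
    track = make_track(TrackSpec(
        waypoints=[(-89.6, -1.4), (-82.0, -2.0), (-78.5, -9.0), (-89.6, -1.4)],
        speed_mps=12.0, fix_interval_s=5400.0, start_time=0.0,
        individual="albatross-like-1"))
    return track, {"wind.u": u_var, "wind.v": v_var}, {"wind.u": u_f, "wind.v": v_f}
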