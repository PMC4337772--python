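"""File formats: Movebank-style track CSV, CF NetCDF, GeoTIFF, YAML
manifests, and a minimal KML ground-overlay writer.

NetCDF goes through xarray's scipy backend (classic NetCDF3) with CF
coordinate variables, time as "seconds since 1970-01-01", and _FillValue
for missing data.  GeoTIFF uses tifffile with the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) for north-up WGS84
rasters, which covers the area-annotation outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from .errors import ValidationError
from .geo import CRS
from .grid import GridAxis, GridVariable, build_grid_variable
from .times import format_timestamp

# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

_TRACK_ALIASES = {
    "individual-local-identifier": ("individual-local-identifier", "individual_id",
                                    "individual", "id"),
    "timestamp": ("timestamp", "time"),
    "location-long": ("location-long", "longitude", "lon"),
    "location-lat": ("location-lat", "latitude", "lat"),
}


def read_track_csv(path) -> pd.DataFrame:
    """Read a track CSV, normalizing common Movebank header variants."""
    df = pd.read_csv(path)
    rename = {}
    for canon, aliases in _TRACK_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                rename[a] = canon
                break
        else:
            raise ValidationError(f"track file {path}: no column for {canon!r}")
    return df.rename(columns=rename)


def write_track_csv(df: pd.DataFrame, path):
    """Write an (annotated) track as RFC 4180 CSV, UTF-8."""
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\r\n")


# ---------------------------------------------------------------------------
# NetCDF
# ---------------------------------------------------------------------------

_CF_NAMES = {"x": "lon", "y": "lat", "z": "level", "t": "time"}
_CF_UNITS = {"x": "degrees_east", "y": "degrees_north", "z": "m",
             "t": "seconds since 1970-01-01 00:00:00"}


def write_netcdf(var: GridVariable, path):
    """Write a GridVariable as a CF-style classic NetCDF file."""
    dims = [_CF_NAMES[ax.name] for ax in var.axes]
    coords = {}
    for ax in var.axes:
        cf = _CF_NAMES[ax.name]
        coords[cf] = (cf, ax.coordinates, {"units": _CF_UNITS[ax.name]})
    attrs = {"units": var.units, "kind": var.kind}
    if var.kind == "categorical":
        attrs["flag_values"] = json.dumps(sorted(var.codes))
    data = var.values.astype(np.float64)
    encoding = {}
    name = var.id.split(".")[-1] or "var"
    fill = var.missing_value if var.missing_value is not None else -9.96921e36
    data = np.where(np.isnan(data), fill, data)
    attrs["_FillValue"] = fill
    ds = xr.Dataset({name: (dims, data, attrs)}, coords=coords,
                    attrs={"envtrack_id": var.id,
                           "crs_name": var.crs.name,
                           "crs_params": json.dumps(var.crs.params),
                           "tile_shape": json.dumps(list(var.tile_shape))})
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path, var_name=None, var_id=None, kind=None, crs=None,
                tile_shape=None) -> GridVariable:
    """Load a GridVariable from a CF NetCDF file.

    CF conventions honored: coordinate variables matched by name
    (lon/longitude, lat/latitude, time, level), decreasing latitude flipped,
    longitudes on [0, 360) re-indexed to [-180, 180), time decoded to epoch
    seconds, _FillValue mapped to NaN.  Metadata absent from the file can be
    supplied via the keyword overrides (normally from the YAML manifest).
    """
    ds = xr.open_dataset(path, engine="scipy", decode_times=False)
    try:
        if var_name is None:
            candidates = [n for n in ds.data_vars]
            if len(candidates) != 1:
                raise ValidationError(
                    f"{path}: specify var_name; file has {candidates}")
            var_name = candidates[0]
        da = ds[var_name]
        dim_roles = {}
        for dim in da.dims:
            d = str(dim).lower()
            if d.startswith(("lon", "x")):
                dim_roles[dim] = "x"
            elif d.startswith(("lat", "y")):
                dim_roles[dim] = "y"
            elif d.startswith(("time", "t")):
                dim_roles[dim] = "t"
            elif d.startswith(("lev", "z", "depth", "height")):
                dim_roles[dim] = "z"
            else:
                raise ValidationError(f"{path}: cannot classify dimension {dim!r}")
        # canonical order t, z, y, x
        order = [d for r in ("t", "z", "y", "x") for d in da.dims if dim_roles[d] == r]
        da = da.transpose(*order)
        values = da.values.astype(float)
        fill = da.attrs.get("_FillValue")
        if fill is not None:
            values = np.where(values == fill, np.nan, values)
        axes = []
        for dim in order:
            role = dim_roles[dim]
            coords = np.asarray(ds[dim].values, dtype=float)
            if role == "t":
                units = str(ds[dim].attrs.get("units", "seconds since 1970-01-01"))
                coords = _decode_time(coords, units)
            axis_slice = [slice(None)] * values.ndim
            pos = order.index(dim)
            if coords.size > 1 and coords[1] < coords[0]:  # flip decreasing axes
                coords = coords[::-1]
                axis_slice[pos] = slice(None, None, -1)
                values = values[tuple(axis_slice)]
            if role == "x" and coords.max() > 180.0:
                shift = np.where(coords >= 180.0, coords - 360.0, coords)
                perm = np.argsort(shift)
                coords = shift[perm]
                axis_slice = [slice(None)] * values.ndim
                axis_slice[pos] = perm
                values = values[tuple(axis_slice)]
            axes.append(GridAxis(role, coords))
        file_kind = kind or da.attrs.get("kind", "continuous")
        codes = None
        if file_kind == "categorical" and "flag_values" in da.attrs:
            codes = json.loads(da.attrs["flag_values"])
        if crs is None:
            crs = CRS(ds.attrs.get("crs_name", "wgs84_lonlat"),
                      json.loads(ds.attrs.get("crs_params", "{}")))
        if tile_shape is None and "tile_shape" in ds.attrs:
            tile_shape = tuple(json.loads(ds.attrs["tile_shape"]))
        return build_grid_variable(
            axes, values, crs=crs, kind=file_kind, tile_shape=tile_shape,
            var_id=var_id or ds.attrs.get("envtrack_id", var_name),
            units=str(da.attrs.get("units", "")), codes=codes)
    finally:
        ds.close()


def _decode_time(coords, units):
    units = units.strip().lower()
    if "since" not in units:
        return coords
    unit, _, epoch = units.partition("since")
    scale = {"seconds": 1.0, "second": 1.0, "hours": 3600.0, "hour": 3600.0,
             "days": 86400.0, "day": 86400.0,
             "minutes": 60.0, "minute": 60.0}.get(unit.strip())
    if scale is None:
        raise ValidationError(f"unsupported time units {units!r}")
    origin = pd.Timestamp(epoch.strip())
    if origin.tz is None:
        origin = origin.tz_localize("UTC")
    return coords * scale + origin.timestamp()


# ---------------------------------------------------------------------------
# GeoTIFF
# ---------------------------------------------------------------------------

_GEOTIFF_KEYS_WGS84 = (
    # KeyDirectoryVersion, KeyRevision, MinorRevision, NumberOfKeys, then keys
    1, 1, 0, 3,
    1024, 0, 1, 2,      # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,      # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,   # GeographicTypeGeoKey = WGS84
)


def write_geotiff(path, array: np.ndarray, west: float, north: float,
                  dx: float, dy: float):
    """Write a north-up WGS84 raster (row 0 = north) as GeoTIFF.

    ``west``/``north`` are the outer EDGES of the top-left pixel; ``dx``,
    ``dy`` are positive pixel sizes in degrees.
    """
    extratags = [
        (33550, "d", 3, (float(dx), float(dy), 0.0)),              # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, float(west), float(north), 0.0)),  # tiepoint
        (34735, "H", len(_GEOTIFF_KEYS_WGS84), _GEOTIFF_KEYS_WGS84),
    ]
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32),
                     extratags=extratags)


def read_geotiff(path):
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns ``(array, transform)`` with transform keys west/north/dx/dy.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        scale = page.tags["ModelPixelScaleTag"].value
        tie = page.tags["ModelTiepointTag"].value
    return arr, {"west": float(tie[3]), "north": float(tie[4]),
                 "dx": float(scale[0]), "dy": float(scale[1])}


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

def load_manifest(path) -> dict:
    """Load a YAML dataset manifest into ``{variable id: GridVariable}``.

    Schema::

        datasets:
          - id: wind.u
            path: wind_u.nc        # relative to the manifest file
            variable: u            # NetCDF variable name
            kind: continuous
            crs: {name: wgs84_lonlat}
            tile_shape: [8, 8]
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "datasets" not in doc:
        raise ValidationError(f"{path}: manifest must have a 'datasets' list")
    out = {}
    for entry in doc["datasets"]:
        crs = None
        if "crs" in entry:
            crs = CRS(entry["crs"]["name"], entry["crs"].get("params", {}))
        tile_shape = tuple(entry["tile_shape"]) if "tile_shape" in entry else None
        var = read_netcdf(path.parent / entry["path"],
                          var_name=entry.get("variable"),
                          var_id=entry["id"], kind=entry.get("kind"),
                          crs=crs, tile_shape=tile_shape)
        out[entry["id"]] = var
    return out


# ---------------------------------------------------------------------------
# KML
# ---------------------------------------------------------------------------

def write_kml_overlay(path, image_href: str, west, south, east, north,
                      name="envtrack overlay"):
    """Write a minimal KML GroundOverlay referencing a raster image."""
    kml = f"""<?xml version="1.0" encoding="UTF-8"?>
<kml xmlns="http://www.opengis.net/kml/2.2">
  <GroundOverlay>
    <name>{name}</name>
    <Icon><href>{image_href}</href></Icon>
    <LatLonBox>
      <north>{north}</north><south>{south}</south>
      <east>{east}</east><west>{west}</west>
    </LatLonBox>
  </GroundOverlay>
</kml>
"""
    Path(path).write_text(kml, encoding="utf-8")
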