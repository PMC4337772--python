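"""YAML request parsing and the machine-readable run manifest.

``parse_request`` validates an entire request document and reports *all*
failures at once (a request with three bad entries produces three named
errors, not one).  Method names accept both British and American spellings
and the short form ``idw``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version

import yaml

from .errors import RequestError
from .interpolation import InterpMethod
from .request import (AnnotationRequest, AreaSpec, DerivedRequest,
                      VariableRequest)
from .times import parse_timestamp

_SPATIAL_ALIASES = {
    "nearest_neighbour": "nearest_neighbour", "nearest_neighbor": "nearest_neighbour",
    "nearest": "nearest_neighbour", "bilinear": "bilinear",
    "inverse_distance_weighted": "inverse_distance_weighted", "idw": "inverse_distance_weighted",
}
_TEMPORAL_ALIASES = {k: v for k, v in _SPATIAL_ALIASES.items() if v != "bilinear"}


def _method_from(entry: dict, failures, where: str) -> InterpMethod:
    spatial = entry.get("spatial", "bilinear")
    temporal = entry.get("temporal", "inverse_distance_weighted")
    sp = _SPATIAL_ALIASES.get(str(spatial).lower())
    tp = _TEMPORAL_ALIASES.get(str(temporal).lower())
    if sp is None:
        failures.append(f"{where}: unknown spatial method {spatial!r}")
    if tp is None:
        failures.append(f"{where}: unknown temporal method {temporal!r}")
    if sp is None or tp is None:
        return InterpMethod()
    try:
        return InterpMethod(
            spatial=sp, temporal=tp,
            idw_power_space=float(entry.get("idw_power_space", 2.0)),
            idw_power_time=float(entry.get("idw_power_time", 1.0)),
            idw_k=int(entry.get("idw_k", 4)))
    except Exception as exc:  # noqa: BLE001
        failures.append(f"{where}: {exc}")
        return InterpMethod()


def _parse_timestamps(value, failures, where):
    if value is None:
        return []
    if isinstance(value, str):
        items = [s for s in (p.strip() for p in value.split(",")) if s]
    else:
        items = list(value)
    out = []
    for item in items:
        try:
            out.append(parse_timestamp(item))
        except Exception as exc:  # noqa: BLE001
            failures.append(f"{where}: {exc}")
    return out


def parse_request(yaml_text: str, datasets: dict | None = None) -> AnnotationRequest:
    """Parse and fully validate a YAML annotation request.

    When ``datasets`` is given, variable existence and the
    categorical-implies-nearest-neighbour constraint are checked here too,
    so a request is rejected before any data is touched.  Raises
    :class:`RequestError` carrying every failure found.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise RequestError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise RequestError("request must be a YAML mapping")

    failures: list = []
    mode = doc.get("mode", "trajectory")
    if mode not in ("trajectory", "area"):
        failures.append(f"unknown mode {mode!r}")
        mode = "trajectory"

    variables = []
    for k, entry in enumerate(doc.get("variables", []) or []):
        where = f"variables[{k}]"
        if not isinstance(entry, dict):
            failures.append(f"{where}: entry must be a mapping")
            continue
        if "derived" in entry:
            try:
                variables.append(DerivedRequest(
                    kind=str(entry["derived"]),
                    inputs=dict(entry.get("inputs", {})),
                    method=_method_from(entry, failures, where),
                    clamp_zero=bool(entry.get("clamp_zero", False)),
                    cross_from_right=bool(entry.get("cross_from_right", False))))
            except RequestError as exc:
                failures.extend(f"{where}: {f}" for f in exc.failures)
            continue
        if "id" not in entry:
            failures.append(f"{where}: missing variable 'id'")
            continue
        method = _method_from(entry, failures, where)
        vr = VariableRequest(var_id=str(entry["id"]), method=method)
        if datasets is not None:
            var = datasets.get(vr.var_id)
            if var is None:
                failures.append(f"{where}: unknown variable {vr.var_id!r}")
            elif var.kind == "categorical" and (
                    method.spatial != "nearest_neighbour"
                    or method.temporal != "nearest_neighbour"):
                failures.append(
                    f"{where}: {vr.var_id!r} is categorical — only the nearest "
                    f"neighbor interpolation can be applied")
        variables.append(vr)

    area = None
    if "area" in doc:
        a = doc["area"] or {}
        timestamps = _parse_timestamps(a.get("timestamps"), failures, "area.timestamps")
        try:
            area = AreaSpec(
                west=float(a["west"]), south=float(a["south"]),
                east=float(a["east"]), north=float(a["north"]),
                nx=int(a["nx"]), ny=int(a["ny"]),
                timestamps=timestamps,
                crs_name=str(a.get("crs", "wgs84_lonlat")))
        except KeyError as exc:
            failures.append(f"area: missing field {exc}")
        except RequestError as exc:
            failures.extend(f"area: {f}" for f in exc.failures)
    if mode == "area" and area is None and not failures:
        failures.append("area mode requires an 'area' section")

    if failures:
        raise RequestError(failures)
    try:
        return AnnotationRequest(mode=mode, variables=variables, area=area)
    except RequestError:
        raise


@dataclass
class RunManifest:
    """Machine-readable record of one annotation run."""

    tool_version: str = ""
    request: dict = field(default_factory=dict)
    columns: dict = field(default_factory=dict)
    cache: dict | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if not self.tool_version:
            try:
                self.tool_version = version("envtrack")
            except PackageNotFoundError:
                self.tool_version = "unknown"

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    def write(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
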