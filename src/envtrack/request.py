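"""Annotation request model: which variables, which methods, which target.

A request is either *trajectory* mode (annotate every fix of a track; the
output resolution is the track's own) or *area* mode (annotate every pixel
center of a rectangle at requested timestamps).  Each requested variable
carries its own interpolation method; derived variables instead name the
primary variables they are computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import RequestError
from .interpolation import BILINEAR_LINEAR, InterpMethod

DERIVED_KINDS = ("wind_speed", "wind_direction", "tailwind", "crosswind",
                 "orographic_uplift", "thermal_uplift")


@dataclass
class VariableRequest:
    """One primary variable with its interpolation method."""

    var_id: str
    method: InterpMethod = field(default_factory=lambda: BILINEAR_LINEAR)

    @property
    def column(self) -> str:
        return f"{self.var_id}.{self.method.column_tag}"


@dataclass
class DerivedRequest:
    """A derived covariate and the primary variables feeding it.

    ``inputs`` maps role names to variable ids; the roles each kind needs:
    wind_speed/wind_direction/tailwind/crosswind -> u, v;
    orographic_uplift -> u, v, dem; thermal_uplift -> H, z_i, T.
    """

    kind: str
    inputs: dict
    method: InterpMethod = field(default_factory=lambda: BILINEAR_LINEAR)
    clamp_zero: bool = False
    cross_from_right: bool = False

    _ROLES = {
        "wind_speed": {"u", "v"}, "wind_direction": {"u", "v"},
        "tailwind": {"u", "v"}, "crosswind": {"u", "v"},
        "orographic_uplift": {"u", "v", "dem"},
        "thermal_uplift": {"H", "z_i", "T"},
    }

    def __post_init__(self):
        if self.kind not in DERIVED_KINDS:
            raise RequestError(f"unknown derived variable kind {self.kind!r}")
        missing = self._ROLES[self.kind] - set(self.inputs)
        if missing:
            raise RequestError(
                f"derived variable {self.kind!r} missing inputs {sorted(missing)}")

    @property
    def column(self) -> str:
        return f"derived.{self.kind}"

    @property
    def needs_heading(self) -> bool:
        return self.kind in ("tailwind", "crosswind")


@dataclass
class AreaSpec:
    """Rectangle of interest: corner coords in ``crs``, pixel counts, timestamps."""

    west: float
    south: float
    east: float
    north: float
    nx: int
    ny: int
    timestamps: Sequence[float] = ()
    crs_name: str = "wgs84_lonlat"

    def __post_init__(self):
        if not (self.east > self.west and self.north > self.south):
            raise RequestError("area rectangle is degenerate (zero width or height)")
        if self.nx <= 0 or self.ny <= 0:
            raise RequestError("area pixel counts must be positive")


@dataclass
class AnnotationRequest:
    """A validated annotation request (trajectory or area mode)."""

    mode: str = "trajectory"
    variables: list = field(default_factory=list)  # VariableRequest | DerivedRequest
    area: Optional[AreaSpec] = None

    def __post_init__(self):
        if self.mode not in ("trajectory", "area"):
            raise RequestError(f"unknown request mode {self.mode!r}")
        if self.mode == "area" and self.area is None:
            raise RequestError("area mode requires an area specification")
        if self.mode == "area" and len(self.area.timestamps) < 1:
            raise RequestError("area mode requires at least one timestamp")
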