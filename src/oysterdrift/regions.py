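"""Named study regions: MPA polygons, transit areas and point sites.

Sinks come in two flavours: polygons (MPAs, the transit gap between them)
and point sites with a radius — restoration sites use a 1-km radius, the
same threshold that defines self-recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry.base import BaseGeometry

from .errors import GeometryError, ValidationError


@dataclass(frozen=True)
class PointSite:
    """A restoration site: a point with a membership/self-recruitment radius."""

    lon: float
    lat: float
    radius_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValidationError("site radius must be positive")


@dataclass
class RegionSet:
    """Uniquely named polygons and point sites.

    ``kinds`` tags each polygon (``mpa`` or ``transit``) for reporting;
    membership semantics do not depend on the tag.
    """

    polygons: dict = field(default_factory=dict)  # name -> shapely geometry
    sites: dict = field(default_factory=dict)  # name -> PointSite
    kinds: dict = field(default_factory=dict)  # polygon name -> kind

    def __post_init__(self) -> None:
        dup = set(self.polygons) & set(self.sites)
        if dup:
            raise ValidationError(f"region names not unique: {sorted(dup)}")
        for name, geom in self.polygons.items():
            if not isinstance(geom, BaseGeometry) or not geom.is_valid:
                raise GeometryError(f"polygon {name!r} is invalid")

    def __contains__(self, name: str) -> bool:
        return name in self.polygons or name in self.sites

    def __getitem__(self, name: str):
        if name in self.polygons:
            return self.polygons[name]
        if name in self.sites:
            return self.sites[name]
        raise KeyError(name)

    @property
    def names(self) -> list:
        return list(self.polygons) + list(self.sites)
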