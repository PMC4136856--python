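"""Vector features: roads, residences, cropland, nature reserves.

Features live in the same planar-meter frame as the rasters.  Residences are
points with a size class (small = fewer than 3 households, large = 3 or
more); roads are polylines classed local (< 2 lanes) or provincial (2+
lanes); cropland and reserves are polygons.  Serialized as GeoJSON
FeatureCollections with a ``kind`` property per feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon, mapping, shape

ROAD_CLASSES = ("local", "provincial")
RESIDENCE_CLASSES = ("small", "large")
RESERVE_LEVELS = ("none", "provincial", "national")
LARGE_RESIDENCE_HOUSEHOLDS = 3  # >= 3 households => "large"


@dataclass
class Road:
    geometry: LineString
    road_class: str = "local"

    def __post_init__(self):
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {self.road_class!r}")


@dataclass
class Residence:
    geometry: Point
    size_class: str = "small"
    households: int | None = None

    def __post_init__(self):
        if self.size_class not in RESIDENCE_CLASSES:
            raise ValueError(f"unknown residence size class {self.size_class!r}")

    @classmethod
    def from_households(cls, geometry: Point, households: int) -> "Residence":
        cls_ = "large" if households >= LARGE_RESIDENCE_HOUSEHOLDS else "small"
        return cls(geometry, cls_, households)


@dataclass
class Cropland:
    geometry: Polygon


@dataclass
class Reserve:
    geometry: Polygon
    level: str = "none"

    def __post_init__(self):
        if self.level not in RESERVE_LEVELS:
            raise ValueError(f"unknown reserve level {self.level!r}")


@dataclass
class FeatureSet:
    """All vector inputs of one landscape."""

    roads: list[Road] = field(default_factory=list)
    residences: list[Residence] = field(default_factory=list)
    cropland: list[Cropland] = field(default_factory=list)
    reserves: list[Reserve] = field(default_factory=list)

    def __post_init__(self):
        for feat in self.roads + self.residences + self.cropland + self.reserves:
            coords = np.asarray(feat.geometry.bounds, dtype=float)
            if not np.all(np.isfinite(coords)):
                raise ValueError("feature coordinates must be finite")

    # -- selection ----------------------------------------------------------
    def road_geometries(self, road_class: str | None = None) -> list[LineString]:
        return [
            r.geometry for r in self.roads
            if road_class is None or r.road_class == road_class
        ]

    def residence_geometries(self, size_class: str | None = None) -> list[Point]:
        return [
            r.geometry for r in self.residences
            if size_class is None or r.size_class == size_class
        ]

    def copy(self) -> "FeatureSet":
        return FeatureSet(
            [Road(LineString(r.geometry), r.road_class) for r in self.roads],
            [Residence(Point(r.geometry), r.size_class, r.households)
             for r in self.residences],
            [Cropland(Polygon(c.geometry)) for c in self.cropland],
            [Reserve(Polygon(r.geometry), r.level) for r in self.reserves],
        )

    # -- GeoJSON ------------------------------------------------------------
    def to_geojson(self, path) -> None:
        feats = []
        for r in self.roads:
            feats.append(_feature(r.geometry, kind="road", road_class=r.road_class))
        for r in self.residences:
            props = {"kind": "residence", "size_class": r.size_class}
            if r.households is not None:
                props["households"] = r.households
            feats.append(_feature(r.geometry, **props))
        for c in self.cropland:
            feats.append(_feature(c.geometry, kind="cropland"))
        for r in self.reserves:
            feats.append(_feature(r.geometry, kind="reserve", level=r.level))
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "FeatureSet":
        with open(path) as fh:
            doc = json.load(fh)
        fs = cls()
        for feat in doc.get("features", []):
            geom = shape(feat["geometry"])
            props = feat.get("properties", {}) or {}
            kind = props.get("kind")
            if kind == "road":
                fs.roads.append(Road(geom, props.get("road_class", "local")))
            elif kind == "residence":
                fs.residences.append(
                    Residence(geom, props.get("size_class", "small"),
                              props.get("households"))
                )
            elif kind == "cropland":
                fs.cropland.append(Cropland(geom))
            elif kind == "reserve":
                fs.reserves.append(Reserve(geom, props.get("level", "none")))
            else:
                raise ValueError(f"feature with unknown kind {kind!r} in {path}")
        return fs


def _feature(geom, **props) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}
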