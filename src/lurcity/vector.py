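"""Typed vector features (points / lines / polygons) with attributes.

A thin container over shapely geometries with GeoJSON round-tripping.
Coordinates are planar metres throughout; there is no CRS handling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

_ALLOWED = {"Point", "MultiPoint", "LineString", "MultiLineString",
            "Polygon", "MultiPolygon"}


@dataclass
class VectorLayer:
    """A list of (geometry, attributes) features."""

    features: list[tuple[BaseGeometry, dict[str, Any]]] = field(
        default_factory=list)

    def __post_init__(self) -> None:
        for geom, attrs in self.features:
            if geom.geom_type not in _ALLOWED:
                raise ValueError(f"unsupported geometry {geom.geom_type}")
            if not geom.is_valid:
                raise ValueError("invalid geometry in layer")
            if not isinstance(attrs, dict):
                raise TypeError("attributes must be a dict")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[tuple[BaseGeometry, dict[str, Any]]]:
        return iter(self.features)

    def add(self, geom: BaseGeometry, **attrs: Any) -> None:
        self.features.append((geom, attrs))

    def filter(self, **attrs: Any) -> "VectorLayer":
        """Features whose attributes match every given key=value."""
        keep = [(g, a) for g, a in self.features
                if all(a.get(k) == v for k, v in attrs.items())]
        return VectorLayer(keep)

    def geometries(self) -> list[BaseGeometry]:
        return [g for g, _ in self.features]

    # --- GeoJSON ------------------------------------------------------
    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": mapping(g), "properties": a}
                for g, a in self.features
            ],
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "VectorLayer":
        feats = [(shape(f["geometry"]), dict(f.get("properties") or {}))
                 for f in obj["features"]]
        return cls(feats)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def read(cls, path) -> "VectorLayer":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))
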