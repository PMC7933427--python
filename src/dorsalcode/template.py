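"""Dorsal-horn tissue templates.

A :class:`TissueTemplate` is the reference geometry every section is mapped
onto: a closed region outline (one half of the dorsal grey matter, medial edge
on the left) plus an ordered, dorsal-to-ventral list of lamina polygons named
I..V. Coordinates are pixels: origin top-left, x to the right, y downwards,
0-based, with positions referring to pixel centers. That convention is used
everywhere in this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, mapping, shape

LAMINA_NAMES = ("I", "II", "III", "IV", "V")

#: dorsal-to-ventral depth fractions of the five laminar bands in the default
#: template (lamina I is a thin superficial sheet, lamina V the deepest band).
DEFAULT_LAMINA_FRACTIONS = (0.09, 0.15, 0.18, 0.24, 0.34)


@dataclass
class TissueTemplate:
    """Region outline plus ordered laminae, in pixel coordinates.

    ``laminae`` is ordered dorsal to ventral; assignment routines rely on that
    order for boundary tie-breaks.
    """

    outline: Polygon
    laminae: list[tuple[str, Polygon]] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.outline, Polygon) or not self.outline.is_valid:
            raise ValueError("outline must be a valid (simple) polygon")
        names = [name for name, _ in self.laminae]
        if len(set(names)) != len(names):
            raise ValueError(f"lamina names must be unique, got {names}")
        hull = self.outline.buffer(1e-6)
        for name, poly in self.laminae:
            if not isinstance(poly, Polygon) or not poly.is_valid:
                raise ValueError(f"lamina {name!r} polygon is not simple/valid")
            if not poly.within(hull):
                raise ValueError(f"lamina {name!r} is not contained in the outline")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def lamina_names(self) -> list[str]:
        return [name for name, _ in self.laminae]

    def lamina(self, name: str) -> Polygon:
        for n, poly in self.laminae:
            if n == name:
                return poly
        raise KeyError(f"no lamina named {name!r}")

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of the smallest image containing the outline."""
        minx, miny, maxx, maxy = self.outline.bounds
        return (int(math.ceil(maxy)) + 1, int(math.ceil(maxx)) + 1)

    # ------------------------------------------------------------------ I/O
    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {"name": "outline", "pixel_size_um": self.pixel_size_um},
                "geometry": mapping(self.outline),
            }
        ]
        for name, poly in self.laminae:
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"name": name},
                    "geometry": mapping(poly),
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "TissueTemplate":
        with open(path) as fh:
            gj = json.load(fh)
        outline = None
        pixel_size = 1.0
        laminae: list[tuple[str, Polygon]] = []
        for feat in gj["features"]:
            name = feat["properties"]["name"]
            geom = shape(feat["geometry"])
            if name == "outline":
                outline = geom
                pixel_size = float(feat["properties"].get("pixel_size_um", 1.0))
            else:
                laminae.append((name, geom))
        if outline is None:
            raise ValueError("GeoJSON template must contain an 'outline' feature")
        return cls(outline=outline, laminae=laminae, pixel_size_um=pixel_size)


def default_template(
    width: float = 400.0,
    depth: float = 500.0,
    pixel_size_um: float = 1.0,
    lamina_fractions: tuple[float, ...] = DEFAULT_LAMINA_FRACTIONS,
) -> TissueTemplate:
    """Half-dorsal-horn outline with five stacked laminar bands.

    The outline is a lens-like shape attached to the midline (x = 0): the
    lateral border bulges out to ``width`` at mid-depth and tapers towards the
    dorsal tip and the ventral end. Laminae are the intersections of the
    outline with horizontal depth bands whose heights follow
    ``lamina_fractions``.
    """
    if abs(sum(lamina_fractions) - 1.0) > 1e-9 or len(lamina_fractions) != 5:
        raise ValueError("lamina_fractions must be 5 values summing to 1")
    t = np.linspace(0.0, 1.0, 81)
    lateral_x = width * np.sin(np.pi * t) ** 0.7
    y = depth * t
    coords = [(0.0, 0.0)]
    coords += [(float(xx), float(yy)) for xx, yy in zip(lateral_x[1:-1], y[1:-1])]
    coords.append((0.0, float(depth)))
    outline = Polygon(coords)

    bounds = np.concatenate([[0.0], np.cumsum(lamina_fractions)]) * depth
    laminae = []
    for name, y0, y1 in zip(LAMINA_NAMES, bounds[:-1], bounds[1:]):
        band = Polygon(
            [(-1.0, y0), (width + 1.0, y0), (width + 1.0, y1), (-1.0, y1)]
        )
        poly = outline.intersection(band)
        if poly.geom_type != "Polygon":  # pragma: no cover - defensive
            poly = max(poly.geoms, key=lambda g: g.area)
        laminae.append((name, poly))
    return TissueTemplate(outline=outline, laminae=laminae, pixel_size_um=pixel_size_um)


def default_landmarks(template: TissueTemplate) -> dict[str, tuple[float, float]]:
    """Named fiducial points used for section-to-template alignment.

    Chosen to be easy to identify on a real section: the dorsomedial and
    ventromedial corners, the lateral apex of the grey matter and the region
    centroid. Four points, never collinear for a non-degenerate outline.
    """
    minx, miny, maxx, maxy = template.outline.bounds
    # lateral apex: outline vertex with the largest x
    apex = max(template.outline.exterior.coords, key=lambda c: c[0])
    c = template.outline.centroid
    return {
        "dorsomedial": (minx, miny),
        "ventromedial": (minx, maxy),
        "lateral_apex": (float(apex[0]), float(apex[1])),
        "centroid": (float(c.x), float(c.y)),
    }
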