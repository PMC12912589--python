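"""Synthetic two-level administrative hierarchies (province > district).

The scoring unit is the district (the survey literature's LGA); the province
("State") is the boundary directly above it.  Districts are produced by a
nested Voronoi construction: province seeds partition the rectangular country
extent, and district seeds drawn inside each province partition the province.
This guarantees the partition invariants (full cover, no overlaps, strict
nesting) by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon, box, mapping, shape
from shapely.ops import voronoi_diagram


@dataclass
class AdminUnit:
    unit_id: str
    geometry: Polygon
    parent_id: str | None = None


@dataclass
class AdminHierarchy:
    country_id: str
    provinces: list[AdminUnit]
    districts: list[AdminUnit]
    extent: tuple[float, float, float, float]  # minx, miny, maxx, maxy
    crs: str = "local-metric"

    @property
    def extent_polygon(self) -> Polygon:
        return box(*self.extent)

    def districts_of(self, province_id: str) -> list[AdminUnit]:
        return [d for d in self.districts if d.parent_id == province_id]

    def district_ids(self) -> list[str]:
        return [d.unit_id for d in self.districts]

    def province_of_district(self) -> dict[str, str]:
        return {d.unit_id: d.parent_id for d in self.districts}

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for level, units in (("province", self.provinces), ("district", self.districts)):
            for u in units:
                features.append({
                    "type": "Feature",
                    "properties": {"id": u.unit_id, "parent_id": u.parent_id, "level": level},
                    "geometry": mapping(u.geometry),
                })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features,
                       "country_id": self.country_id, "crs": self.crs,
                       "extent": list(self.extent)}, fh)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AdminHierarchy":
        with open(path) as fh:
            data = json.load(fh)
        provinces, districts = [], []
        for feat in data["features"]:
            props = feat["properties"]
            unit = AdminUnit(props["id"], shape(feat["geometry"]), props.get("parent_id"))
            (provinces if props["level"] == "province" else districts).append(unit)
        return cls(data["country_id"], provinces, districts,
                   tuple(data["extent"]), data.get("crs", "local-metric"))


def _spread_points(rng: np.random.Generator, region: Polygon, n: int) -> np.ndarray:
    """Sample n well-spread seed points inside a polygon.

    Over-samples candidates in the bounding box, rejects points outside the
    polygon, then greedily keeps the candidate farthest from already kept
    seeds so nearly-coincident seeds (degenerate Voronoi cells) cannot occur.
    """
    minx, miny, maxx, maxy = region.bounds
    pts: list[np.ndarray] = []
    cand = None
    while cand is None or len(cand) < max(50 * n, 200):
        xy = rng.uniform([minx, miny], [maxx, maxy], size=(max(200 * n, 800), 2))
        inside = shapely.contains_xy(region, xy[:, 0], xy[:, 1])
        cand = xy[inside]
    pts.append(cand[0])
    for _ in range(n - 1):
        d = np.min(
            np.linalg.norm(cand[:, None, :] - np.asarray(pts)[None, :, :], axis=2),
            axis=1,
        )
        pts.append(cand[int(np.argmax(d))])
    return np.asarray(pts)


def _voronoi_partition(region: Polygon, seeds: np.ndarray) -> list[Polygon]:
    cells = voronoi_diagram(MultiPoint(seeds.tolist()), envelope=region.buffer(1.0))
    out: list[Polygon] = [None] * len(seeds)
    for cell in cells.geoms:
        clipped = cell.intersection(region)
        if clipped.is_empty:
            continue
        # voronoi_diagram does not preserve seed order; match by containment
        for i, s in enumerate(seeds):
            if out[i] is None and cell.covers(shapely.points(s[0], s[1])):
                out[i] = clipped
                break
    return [p for p in out if p is not None and p.area > 0]


def generate_admin_hierarchy(
    n_provinces: int,
    districts_per_province: int,
    extent_m: tuple[float, float] = (150_000.0, 150_000.0),
    seed: int = 0,
    country_id: str = "SYN",
) -> AdminHierarchy:
    """Generate a nested province->district hierarchy on a rectangular extent.

    Parameters
    ----------
    n_provinces, districts_per_province
        Both must be >= 2 (a province must contain at least two districts for
        state-relative scoring to be meaningful).
    extent_m
        (width, height) of the country rectangle in metres.
    """
    if n_provinces < 2 or districts_per_province < 2:
        raise ValueError("need >=2 provinces and >=2 districts per province")
    width, height = extent_m
    if width <= 0 or height <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    country = box(0.0, 0.0, width, height)

    prov_seeds = _spread_points(rng, country, n_provinces)
    prov_polys = _voronoi_partition(country, prov_seeds)
    provinces, districts = [], []
    for i, poly in enumerate(prov_polys):
        pid = f"{country_id}-P{i + 1:02d}"
        provinces.append(AdminUnit(pid, poly))
        d_seeds = _spread_points(rng, poly, districts_per_province)
        for j, dpoly in enumerate(_voronoi_partition(poly, d_seeds)):
            districts.append(AdminUnit(f"{pid}-D{j + 1:02d}", dpoly, parent_id=pid))
    return AdminHierarchy(country_id, provinces, districts, (0.0, 0.0, width, height))
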