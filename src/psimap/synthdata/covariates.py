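"""Synthetic geocovariate stacks.

Eleven layers emulating the remote-sensing and infrastructure covariates used
for susceptibility surface modelling:

  EVI, NDVI      vegetation indices in [-1, 1]
  LST            land surface temperature (deg C)
  SLOPE          terrain steepness (degrees, >= 0)
  ELEV           elevation (m)
  POPPP          population per pixel (>= 0)
  ACCESS         accessibility index (0..100, higher = better served)
  DMROADS        Euclidean distance to major roads (m)
  DMROADSINT     distance to major road intersections (m)
  DMWATER        distance to water bodies (m)
  NLIGHTS        night-time light intensity (>= 0)

Continuous layers are smoothed Gaussian random fields rescaled into plausible
physical ranges; distance layers are true Euclidean distance transforms to
randomly generated line / point features, so a cell on a road has DMROADS = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

from ..grids import RasterGrid, read_ascii_grid, write_ascii_grid
from .admin import AdminHierarchy

COVARIATE_NAMES = (
    "EVI", "NDVI", "LST", "SLOPE", "ELEV", "POPPP",
    "ACCESS", "DMROADS", "DMROADSINT", "DMWATER", "NLIGHTS",
)


@dataclass
class CovariateStack:
    grid: RasterGrid
    layers: dict[str, np.ndarray]
    nodata: float = np.nan

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def sample(self, name: str, x, y) -> np.ndarray:
        """Layer values at point coordinates (cell-centre lookup)."""
        r, c = self.grid.index_of(x, y)
        return self.layers[name][r, c]

    def standardized(self) -> "CovariateStack":
        """Z-score every layer over the grid (used as the model design scale)."""
        out = {}
        for name, layer in self.layers.items():
            mu = np.nanmean(layer)
            sd = np.nanstd(layer)
            out[name] = (layer - mu) / (sd if sd > 0 else 1.0)
        return CovariateStack(self.grid, out)

    def write(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, layer in self.layers.items():
            write_ascii_grid(directory / f"{prefix}{name}.asc", self.grid, layer)

    @classmethod
    def read(cls, directory: str | Path, names=COVARIATE_NAMES, prefix: str = "") -> "CovariateStack":
        directory = Path(directory)
        layers, grid = {}, None
        for name in names:
            grid, arr = read_ascii_grid(directory / f"{prefix}{name}.asc")
            layers[name] = arr
        return cls(grid, layers)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="wrap")
    sd = f.std()
    return f / (sd if sd > 0 else 1.0)


def _random_roads(rng: np.random.Generator, grid: RasterGrid, n_roads: int) -> list[LineString]:
    """Roads as random chords across the extent with a mild kink."""
    roads = []
    w, h = grid.width, grid.height
    for _ in range(n_roads):
        a = rng.uniform([grid.x0, grid.y0], [grid.x0 + w, grid.y0 + h])
        b = rng.uniform([grid.x0, grid.y0], [grid.x0 + w, grid.y0 + h])
        mid = (a + b) / 2 + rng.normal(scale=0.1 * min(w, h), size=2)
        roads.append(LineString([a, mid, b]))
    return roads


def _distance_raster_from_mask(grid: RasterGrid, feature_mask: np.ndarray) -> np.ndarray:
    if not feature_mask.any():  # no feature: fall back to distance from centre
        feature_mask = feature_mask.copy()
        feature_mask[grid.nrows // 2, grid.ncols // 2] = True
    return ndimage.distance_transform_edt(~feature_mask, sampling=grid.cell)


def _rasterize_lines(grid: RasterGrid, lines: list[LineString]) -> np.ndarray:
    mask = np.zeros((grid.nrows, grid.ncols), dtype=bool)
    for line in lines:
        n = max(int(line.length / (grid.cell * 0.5)), 2)
        pts = [line.interpolate(t, normalized=True) for t in np.linspace(0, 1, n)]
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        r, c = grid.index_of(xs, ys)
        mask[r, c] = True
    return mask


def _rasterize_points(grid: RasterGrid, xy: np.ndarray) -> np.ndarray:
    mask = np.zeros((grid.nrows, grid.ncols), dtype=bool)
    if len(xy):
        r, c = grid.index_of(xy[:, 0], xy[:, 1])
        mask[r, c] = True
    return mask


def generate_covariates(
    hierarchy: AdminHierarchy,
    cell_m: float = 1000.0,
    seed: int = 0,
    smooth_km: float = 10.0,
    n_roads: int = 6,
    n_water: int = 4,
) -> CovariateStack:
    """Generate the 11-layer covariate stack on the hierarchy's extent.

    ``smooth_km`` controls the spatial autocorrelation scale of the continuous
    layers; distance layers derive from ``n_roads`` random road chords (with
    their pairwise intersections as DMROADSINT features) and ``n_water``
    random water features.
    """
    minx, miny, maxx, maxy = hierarchy.extent
    width, height = maxx - minx, maxy - miny
    ncols, nrows = round(width / cell_m), round(height / cell_m)
    if abs(ncols * cell_m - width) > 1e-6 or abs(nrows * cell_m - height) > 1e-6:
        raise ValueError("cell size must divide the extent")
    grid = RasterGrid(minx, miny, cell_m, nrows, ncols)
    rng = np.random.default_rng(seed)
    sig = max(smooth_km * 1000.0 / cell_m, 1.0)
    shp = (nrows, ncols)

    f = {k: _smooth_field(rng, shp, sig) for k in
         ("veg", "veg2", "lst", "terrain", "pop", "access", "lights")}
    ndvi = np.clip(0.35 + 0.25 * f["veg"], -1.0, 1.0)
    evi = np.clip(0.8 * ndvi + 0.1 * f["veg2"], -1.0, 1.0)  # EVI tracks NDVI
    elev = 600.0 + 350.0 * f["terrain"]
    slope_deg = np.abs(8.0 * np.gradient(f["terrain"])[0] * sig + 3.0 * f["veg2"])
    lst = 30.0 - 0.006 * (elev - 600.0) + 2.5 * f["lst"]
    pop = np.exp(3.0 + 1.2 * f["pop"])  # log-normal population density
    lights = np.maximum(0.0, 8.0 * np.tanh(f["pop"] + 0.5 * f["lights"]))

    roads = _random_roads(rng, grid, n_roads)
    road_mask = _rasterize_lines(grid, roads)
    dmroads = _distance_raster_from_mask(grid, road_mask)
    inter = []
    for i in range(len(roads)):
        for j in range(i + 1, len(roads)):
            p = roads[i].intersection(roads[j])
            if p.geom_type == "Point":
                inter.append([p.x, p.y])
            elif p.geom_type == "MultiPoint":
                inter.extend([[q.x, q.y] for q in p.geoms])
    dmroadsint = _distance_raster_from_mask(grid, _rasterize_points(grid, np.asarray(inter)))
    water = _random_roads(rng, grid, n_water)
    dmwater = _distance_raster_from_mask(grid, _rasterize_lines(grid, water))

    # accessibility improves near roads and population centres
    access = np.clip(
        50.0 + 15.0 * f["access"] + 10.0 * np.tanh(f["pop"]) - 25.0 * np.tanh(dmroads / 20_000.0),
        0.0, 100.0,
    )
    layers = {
        "EVI": evi, "NDVI": ndvi, "LST": lst, "SLOPE": slope_deg, "ELEV": elev,
        "POPPP": pop, "ACCESS": access, "DMROADS": dmroads,
        "DMROADSINT": dmroadsint, "DMWATER": dmwater, "NLIGHTS": lights,
    }
    return CovariateStack(grid, layers)


def morans_i(layer: np.ndarray) -> float:
    """Moran's I with rook (4-neighbour) contiguity on a full raster."""
    z = layer - layer.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    w_count = z[:, :-1].size + z[:-1, :].size  # each pair counted once
    return (z.size / (2.0 * w_count)) * (2.0 * num) / (z ** 2).sum()
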