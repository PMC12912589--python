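"""Posterior prediction surfaces on an aggregated covariate grid."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..grids import RasterGrid, block_aggregate, write_ascii_grid
from ..synthdata.covariates import CovariateStack
from .betalik import inv_logit
from .fit import FitResult


@dataclass
class PredictionSurface:
    component_id: str
    grid: RasterGrid
    mean: np.ndarray
    lower: np.ndarray  # 2.5th percentile
    upper: np.ndarray  # 97.5th percentile

    def write(self, directory: str | Path, country: str = "SYN") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for tag, arr in (("mean", self.mean), ("lo", self.lower), ("hi", self.upper)):
            write_ascii_grid(directory / f"{country}_{self.component_id}_{tag}.asc",
                             self.grid, arr)


def predict_surface(
    fit: FitResult,
    covariates: CovariateStack,
    aggregation_factor: int = 10,
) -> PredictionSurface:
    """Posterior mean and 2.5/97.5-percentile response surfaces.

    The covariate stack (on the model scale used at fit time) is block-mean
    aggregated by ``aggregation_factor``; the linear predictor at each cell
    combines the fixed-effect draws with the latent field projected through
    mesh barycentric weights.  Cells outside the mesh hull are nodata (NaN).
    """
    if aggregation_factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    missing = set(fit.covariate_names) - set(covariates.names)
    if missing:
        raise KeyError(f"fit covariates missing from stack: {sorted(missing)}")
    grid = covariates.grid.aggregate(aggregation_factor)
    layers = {n: block_aggregate(covariates.layers[n], aggregation_factor)
              for n in fit.covariate_names}

    gx, gy = grid.cell_centers()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    n_cells = len(pts)
    p = 1 + len(fit.covariate_names)
    X = np.ones((n_cells, p))
    for j, name in enumerate(fit.covariate_names, start=1):
        X[:, j] = layers[name].ravel()

    beta_draws = fit.draws_z[:, fit.n_field:]
    eta = beta_draws @ X.T  # S x cells
    if fit.n_field:
        A = fit.mesh.projector(pts)
        inside = A.sum(axis=1) > 1e-9
        eta = eta + fit.draws_z[:, : fit.n_field] @ A.T
    else:
        inside = np.ones(n_cells, dtype=bool)
    inside &= np.isfinite(X).all(axis=1)

    resp = inv_logit(eta)
    mean = np.full(n_cells, np.nan)
    lo = np.full(n_cells, np.nan)
    hi = np.full(n_cells, np.nan)
    mean[inside] = resp[:, inside].mean(axis=0)
    lo[inside] = np.quantile(resp[:, inside], 0.025, axis=0)
    hi[inside] = np.quantile(resp[:, inside], 0.975, axis=0)
    shape = (grid.nrows, grid.ncols)
    return PredictionSurface(
        fit.component_id, grid,
        mean.reshape(shape), lo.reshape(shape), hi.reshape(shape),
    )
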