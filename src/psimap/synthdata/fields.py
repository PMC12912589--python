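"""Matern (nu = 1) Gaussian random fields on regular grids.

Ground-truth latent susceptibility fields are realised by circulant embedding:
the torus covariance is diagonalised by FFT, eigenvalues are clipped at zero
(the standard fix for marginally non-embeddable ranges) and a complex-normal
spectral draw is transformed back.  The range parameter follows the
rho = sqrt(8 * nu) / kappa convention with nu = 1, so the correlation at
distance rho is about 0.13.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import kv

from ..grids import RasterGrid


def matern_correlation(d: np.ndarray, rho: float, nu: float = 1.0) -> np.ndarray:
    """Matern correlation at distance d for range rho (sqrt(8*nu)/kappa convention)."""
    if rho <= 0:
        raise ValueError("range must be positive")
    kappa = np.sqrt(8.0 * nu) / rho
    x = np.asarray(d, dtype=float) * kappa
    out = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = (2.0 ** (1 - nu) / math.gamma(nu)) * (xp ** nu) * kv(nu, xp)
    return out


@dataclass
class TruthFieldSpec:
    """Configuration of one ground-truth susceptibility component."""

    component_id: str
    direction: str  # "HSLS" or "HSHS"
    beta0: float
    betas: dict[str, float]  # coefficient per (standardized) covariate
    matern_range: float  # metres
    matern_sd: float
    response_type: str = "proportion"  # or "median_count"
    table: str = "households"  # survey table carrying the indicator

    def __post_init__(self):
        if self.direction not in ("HSLS", "HSHS"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.response_type not in ("proportion", "median_count"):
            raise ValueError(f"unknown response_type {self.response_type!r}")
        if self.matern_range <= 0 or self.matern_sd < 0:
            raise ValueError("matern_range must be > 0 and matern_sd >= 0")


@dataclass
class TruthField:
    """A realised component: spec plus the latent raster and true probability."""

    spec: TruthFieldSpec
    latent_raster: np.ndarray  # realised mean-zero Gaussian field
    eta_raster: np.ndarray  # full linear predictor incl. covariates
    p_raster: np.ndarray  # inverse-logit of eta

    @property
    def component_id(self) -> str:
        return self.spec.component_id

    def susceptibility_raster(self) -> np.ndarray:
        """Truth on a susceptibility-increasing scale (flips HSLS components)."""
        return 1.0 - self.p_raster if self.spec.direction == "HSLS" else self.p_raster


def sample_matern_field(
    grid: RasterGrid, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """One mean-zero Matern GRF realisation on the grid via circulant embedding."""
    if sd == 0:
        return np.zeros((grid.nrows, grid.ncols))
    # embed on a doubled torus to kill wrap-around correlation
    m, n = 2 * grid.nrows, 2 * grid.ncols
    rows = np.minimum(np.arange(m), m - np.arange(m))
    cols = np.minimum(np.arange(n), n - np.arange(n))
    d = np.hypot(rows[:, None], cols[None, :]) * grid.cell
    cov = sd ** 2 * matern_correlation(d, rho)
    lam = np.fft.fft2(cov).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative embedding eigenvalues
    noise = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
    sim = np.fft.fft2(np.sqrt(lam / (m * n)) * noise)
    return sim.real[: grid.nrows, : grid.ncols]


def realize_truth(
    spec: TruthFieldSpec,
    std_layers: dict[str, np.ndarray],
    grid: RasterGrid,
    rng: np.random.Generator,
) -> TruthField:
    """Realise latent field + linear predictor for one component spec."""
    unknown = set(spec.betas) - set(std_layers)
    if unknown:
        raise KeyError(f"unknown covariate name(s) in component {spec.component_id}: {sorted(unknown)}")
    latent = sample_matern_field(grid, spec.matern_range, spec.matern_sd, rng)
    latent -= latent.mean()  # domain-mean zero: the intercept/field identifiability split
    eta = spec.beta0 + latent
    for name, b in spec.betas.items():
        eta = eta + b * std_layers[name]
    p = 1.0 / (1.0 + np.exp(-eta))
    return TruthField(spec, latent, eta, p)
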