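"""Finite-element SPDE representation of a Matern (alpha = 2) field.

The Gaussian field with Matern covariance (nu = alpha - d/2 = 1 in 2-D) is the
stationary solution of (kappa^2 - Laplacian) tau x(s) = white noise; on a
triangulation the Galerkin discretisation gives a Gaussian Markov random field
with precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G),

with C the (mass-lumped) mass matrix and G the stiffness matrix.  The range
convention is rho = sqrt(8 nu) / kappa, and tau is set from the target
marginal standard deviation sigma via sigma^2 = 1 / (4 pi kappa^2 tau^2).
A soft mass-weighted sum-to-zero constraint is added for identifiability
against the regression intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, solve_triangular

from .mesh import Mesh

ALPHA = 2  # fixed smoothness order (nu = 1 in two dimensions)


def fem_matrices(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Lumped mass matrix diagonal and stiffness matrix (dense)."""
    nv = mesh.n_vertices
    c_diag = np.zeros(nv)
    G = np.zeros((nv, nv))
    for tri in mesh.triangles:
        p = mesh.vertices[tri]
        e = np.array([p[2] - p[1], p[0] - p[2], p[1] - p[0]])  # edge opposite vertex i
        area = 0.5 * abs(e[0, 0] * e[1, 1] - e[0, 1] * e[1, 0])
        if area <= 0:
            continue
        c_diag[tri] += area / 3.0
        # grad of barycentric basis i is perp(e_i) / (2 area)
        local = (e @ e.T) / (4.0 * area)
        for a in range(3):
            for b in range(3):
                G[tri[a], tri[b]] += local[a, b]
    return c_diag, G


@dataclass
class SpdeModel:
    mesh: Mesh
    rho: float
    sigma: float
    precision: np.ndarray  # constrained precision (dense, SPD)
    constraint: bool = True
    alpha: int = ALPHA

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n field samples (rows) from N(0, Q^-1)."""
        L = np.linalg.cholesky(self.precision)
        z = rng.standard_normal((self.precision.shape[0], n))
        return solve_triangular(L.T, z, lower=False).T

    def logdet(self) -> float:
        sign, ld = np.linalg.slogdet(self.precision)
        if sign <= 0:
            raise np.linalg.LinAlgError("constrained SPDE precision not positive definite")
        return ld


def spde_precision(
    mesh: Mesh,
    rho: float,
    sigma: float,
    constraint: bool = True,
    constraint_weight: float = 1e4,
    fem: tuple[np.ndarray, np.ndarray] | None = None,
) -> SpdeModel:
    """Assemble the (soft-)constrained SPDE precision for given (rho, sigma).

    ``fem`` allows reusing precomputed (C diagonal, G) across hyperparameter
    evaluations on the same mesh.
    """
    if rho <= 0 or sigma <= 0:
        raise ValueError("rho and sigma must be positive")
    c_diag, G = fem_matrices(mesh) if fem is None else fem
    kappa = np.sqrt(8.0) / rho  # nu = 1
    tau2 = 1.0 / (4.0 * np.pi * kappa ** 2 * sigma ** 2)
    GCG = G @ (G / c_diag[:, None])
    Q = tau2 * (kappa ** 4 * np.diag(c_diag) + 2.0 * kappa ** 2 * G + GCG)
    if constraint:
        c = c_diag / c_diag.sum()
        Q = Q + constraint_weight * np.mean(np.diag(Q)) * np.outer(c, c)
    Q = 0.5 * (Q + Q.T)
    model = SpdeModel(mesh, rho, sigma, Q, constraint)
    try:
        cho_factor(Q)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(Q)
        raise np.linalg.LinAlgError(
            f"SPDE precision not positive definite (condition number {cond:.2e})"
        ) from exc
    return model
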