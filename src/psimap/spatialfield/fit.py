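"""Bayesian beta-logit regression with a Matern SPDE latent field.

Model, per cluster i at location s_i with response y_i in (0, 1):

    y_i ~ Beta(mu_i phi, (1 - mu_i) phi)
    logit(mu_i) = beta_0 + x_i' beta + u(s_i)

with u a Matern (alpha = 2) field represented on a mesh through the SPDE
precision.  Inference is a Gaussian (Laplace) approximation over the joint
latent vector (field values, regression coefficients) combined with a small
axis grid over the three hyperparameters (log range, log field sd, log beta
precision), each grid point weighted by its approximate marginal posterior.
This mirrors the empirical-Bayes-plus-CCD strategy of latent-Gaussian
packages while staying self-contained and dense-linear-algebra only.

Priors (configurable): penalised-complexity-style on the field — median-rho0
range prior and P(sigma > sigma_u) = 0.1 — Gamma on phi, and wide normals on
the regression coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .betalik import beta_fisher_eta, beta_loglik, beta_score_eta, inv_logit
from .mesh import Mesh
from .spde import fem_matrices, spde_precision

log = logging.getLogger(__name__)


@dataclass
class Priors:
    """Hyperparameter priors and inference controls."""

    rho0: float | None = None  # prior median range; default 0.3 x domain diameter
    sigma_u: float = 1.0  # P(sigma > sigma_u) = 0.1
    phi_shape: float = 1.0
    phi_rate: float = 0.1
    beta_sd: float = 10.0
    include_field: bool = True
    fixed_hyper: tuple | None = None  # (rho, sigma, phi): skip optimisation
    grid_integration: bool = True  # axis grid around the hyper mode
    n_draws: int = 200
    max_newton: int = 40
    nm_maxfev: int = 300


@dataclass
class FitResult:
    component_id: str
    covariate_names: list[str]
    fixed_effects: pd.DataFrame  # index: intercept + covariates; mean, sd, lo, hi
    phi: dict  # posterior summary of the beta precision
    hyper: dict  # posterior summaries of rho and sigma (None if field off)
    field_mean: np.ndarray
    field_sd: np.ndarray
    dic: float
    waic: float
    pit: np.ndarray
    ppc: pd.DataFrame  # per-observation predictive mean / lo / hi and observed
    mesh: Mesh | None
    draws_z: np.ndarray  # S x (n_field + p): posterior latent draws
    draws_phi: np.ndarray
    n_field: int
    log_marginal: float
    converged: bool = True

    def coefficients(self) -> pd.Series:
        return self.fixed_effects["mean"]

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "covariates": self.covariate_names,
            "fixed_effects": self.fixed_effects.round(6).to_dict(),
            "phi": self.phi,
            "hyper": self.hyper,
            "dic": self.dic,
            "waic": self.waic,
        }


class _Objective:
    """Negative log hyper-posterior with warm-started inner Newton solves."""

    def __init__(self, y, M, n_field, fem, mesh, priors: Priors):
        self.y, self.M, self.n_field = y, M, n_field
        self.fem, self.mesh, self.priors = fem, mesh, priors
        self.p = M.shape[1] - n_field
        self.warm = np.zeros(M.shape[1])
        self.cache: dict[tuple, dict] = {}

    def _prior_matrices(self, rho, sigma):
        nlat = self.M.shape[1]
        P = np.zeros((nlat, nlat))
        if self.n_field:
            spde = spde_precision(self.mesh, rho, sigma, fem=self.fem)
            P[: self.n_field, : self.n_field] = spde.precision
            sign, ld_q = np.linalg.slogdet(spde.precision)
        else:
            ld_q = 0.0
        np.fill_diagonal(P[self.n_field:, self.n_field:],
                         1.0 / self.priors.beta_sd ** 2)
        logdet_p = ld_q + self.p * np.log(1.0 / self.priors.beta_sd ** 2)
        return P, logdet_p

    def _newton(self, P, phi):
        z = self.warm.copy()
        M, y = self.M, self.y
        obj_old = -np.inf
        for _ in range(self.priors.max_newton):
            eta = M @ z
            g = beta_score_eta(y, eta, phi)
            w = beta_fisher_eta(eta, phi)
            H = P + (M.T * w) @ M
            cho = cho_factor(H, lower=True)
            step = cho_solve(cho, M.T @ g - P @ z)
            t = 1.0
            for _ in range(12):
                z_new = z + t * step
                obj = beta_loglik(y, M @ z_new, phi).sum() - 0.5 * z_new @ P @ z_new
                if np.isfinite(obj) and obj >= obj_old - 1e-9:
                    break
                t *= 0.5
            z = z_new
            if abs(obj - obj_old) < 1e-7 * (1 + abs(obj)):
                obj_old = obj
                break
            obj_old = obj
        eta = M @ z
        w = beta_fisher_eta(eta, phi)
        H = P + (M.T * w) @ M
        cho = cho_factor(H, lower=True)
        self.warm = z.copy()
        return z, H, cho, obj_old

    def _log_hyper_prior(self, theta):
        lp = 0.0
        if self.n_field:
            lrho, lsig, lphi = theta
            rho, sigma = np.exp(lrho), np.exp(lsig)
            lam_r = np.log(2.0) * self.priors.rho0  # PC range prior, median rho0
            lp += np.log(lam_r) - 2 * np.log(rho) - lam_r / rho + lrho
            lam_s = -np.log(0.1) / self.priors.sigma_u  # P(sigma > sigma_u) = 0.1
            lp += np.log(lam_s) - lam_s * sigma + lsig
        else:
            lphi = theta[0]
        phi = np.exp(lphi)
        lp += (self.priors.phi_shape * np.log(self.priors.phi_rate)
               + (self.priors.phi_shape - 1) * lphi - self.priors.phi_rate * phi + lphi)
        return lp

    def evaluate(self, theta) -> dict:
        key = tuple(np.round(theta, 10))
        if key in self.cache:
            return self.cache[key]
        if self.n_field:
            rho, sigma, phi = np.exp(theta)
        else:
            rho = sigma = None
            phi = float(np.exp(theta[0]))
        P, logdet_p = self._prior_matrices(rho, sigma)
        z, H, cho, inner_obj = self._newton(P, phi)
        logdet_h = 2.0 * np.sum(np.log(np.diag(cho[0])))
        log_marg = inner_obj + 0.5 * logdet_p - 0.5 * logdet_h
        log_post = log_marg + self._log_hyper_prior(theta)
        out = {"theta": np.asarray(theta, dtype=float), "z": z, "cho": cho,
               "phi": phi, "rho": rho, "sigma": sigma,
               "log_marg": log_marg, "log_post": log_post}
        self.cache[key] = out
        return out

    def neg(self, theta) -> float:
        try:
            return -self.evaluate(theta)["log_post"]
        except np.linalg.LinAlgError:
            return 1e10


def _hyper_configs(obj: _Objective, theta0: np.ndarray, priors: Priors):
    """Optimise the hyper-posterior, then evaluate a small axis grid around
    the mode; return weighted Gaussian configurations."""
    if priors.fixed_hyper is not None:
        if obj.n_field:
            theta = np.log(np.asarray(priors.fixed_hyper, dtype=float))
        else:
            theta = np.log([priors.fixed_hyper[-1]])
        return [obj.evaluate(theta)], np.array([1.0]), True
    res = minimize(obj.neg, theta0, method="Nelder-Mead",
                   options={"maxfev": priors.nm_maxfev, "xatol": 0.01, "fatol": 0.01})
    mode = res.x
    configs = [obj.evaluate(mode)]
    if priors.grid_integration:
        for k in range(len(mode)):
            # curvature-scaled axis steps (clipped to a sane log-scale window)
            h = 0.3
            f0 = obj.neg(mode)
            fp, fm = obj.neg(mode + h * np.eye(len(mode))[k]), obj.neg(mode - h * np.eye(len(mode))[k])
            curv = max((fp + fm - 2 * f0) / h ** 2, 1e-2)
            step = float(np.clip(1.1 / np.sqrt(curv), 0.15, 1.2))
            for s in (step, -step):
                try:
                    configs.append(obj.evaluate(mode + s * np.eye(len(mode))[k]))
                except np.linalg.LinAlgError:
                    pass
    lps = np.array([c["log_post"] for c in configs])
    w = np.exp(lps - lps.max())
    return configs, w / w.sum(), res.success or res.fun < 1e9


def fit_component(
    response: np.ndarray,
    covariates: pd.DataFrame | None,
    locations: np.ndarray | None,
    mesh: Mesh | None,
    priors: Priors | None = None,
    component_id: str = "component",
    seed: int = 0,
) -> FitResult:
    """Fit the spatial beta regression for one susceptibility component.

    ``covariates`` holds the non-intercept design columns (already on the
    model scale, e.g. standardized geocovariates at the cluster locations);
    an intercept is always added.  ``response`` must be strictly inside (0, 1)
    (apply :func:`squeeze_response` first).
    """
    priors = priors or Priors()
    y = np.asarray(response, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("response must be strictly inside (0, 1); squeeze it first")
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((len(y), 1))
        cov_names: list[str] = []
    else:
        cov_names = list(covariates.columns)
        vals = covariates.to_numpy(dtype=float)
        if np.any(vals.std(axis=0) == 0):
            bad = [c for c, s in zip(cov_names, vals.std(axis=0)) if s == 0]
            raise ValueError(f"constant non-intercept design column(s): {bad}")
        X = np.column_stack([np.ones(len(y)), vals])

    if priors.include_field:
        if mesh is None or locations is None:
            raise ValueError("mesh and locations are required when the field is on")
        A = mesh.projector(np.asarray(locations, dtype=float))
        n_field = mesh.n_vertices
        M = np.hstack([A, X])
        fem = fem_matrices(mesh)
        if priors.rho0 is None:
            span = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
            priors.rho0 = 0.3 * float(np.hypot(*span))
        theta0 = np.log([priors.rho0, 0.5 * priors.sigma_u, 20.0])
    else:
        M, n_field, fem = X, 0, None
        theta0 = np.log([20.0])

    obj = _Objective(y, M, n_field, fem, mesh, priors)
    configs, weights, converged = _hyper_configs(obj, theta0, priors)
    if not converged:
        raise RuntimeError("hyperparameter optimisation failed to converge")

    # ---- posterior draws allocated across hyper configurations
    rng = np.random.default_rng(seed)
    S = priors.n_draws
    counts = rng.multinomial(S, weights)
    z_draws, phi_draws = [], []
    for cfg, cnt in zip(configs, counts):
        if cnt == 0:
            continue
        Lw = cfg["cho"][0]  # lower Cholesky of H
        eps = rng.standard_normal((M.shape[1], cnt))
        z_draws.append(cfg["z"][None, :] + solve_triangular(Lw.T, eps, lower=False).T)
        phi_draws.append(np.full(cnt, cfg["phi"]))
    z_draws = np.vstack(z_draws)
    phi_draws = np.concatenate(phi_draws)

    # ---- fixed-effect summaries via the weighted Gaussian mixture
    p = M.shape[1] - n_field
    means = np.stack([c["z"][n_field:] for c in configs])
    variances = []
    for cfg in configs:
        E = np.zeros((M.shape[1], p))
        E[n_field:, :] = np.eye(p)
        variances.append(np.diag(cho_solve(cfg["cho"], E)[n_field:, :]))
    variances = np.stack(variances)
    fe_mean = weights @ means
    fe_var = weights @ (variances + means ** 2) - fe_mean ** 2
    fe_sd = np.sqrt(np.maximum(fe_var, 0))
    names = ["intercept"] + cov_names
    fixed = pd.DataFrame({
        "mean": fe_mean, "sd": fe_sd,
        "lo": fe_mean + norm.ppf(0.025) * fe_sd,
        "hi": fe_mean + norm.ppf(0.975) * fe_sd,
    }, index=names)

    # ---- field summaries from draws
    if n_field:
        field_mean = z_draws[:, :n_field].mean(axis=0)
        field_sd = z_draws[:, :n_field].std(axis=0)
        rho_mean = float(np.sum(weights * np.array([c["rho"] for c in configs])))
        sig_mean = float(np.sum(weights * np.array([c["sigma"] for c in configs])))
        hyper = {"rho_mean": rho_mean, "sigma_mean": sig_mean}
    else:
        field_mean = field_sd = np.zeros(0)
        hyper = {}
    phi_mean = float(np.sum(weights * np.array([c["phi"] for c in configs])))
    phi_summary = {"mean": phi_mean,
                   "lo": float(np.quantile(phi_draws, 0.025)),
                   "hi": float(np.quantile(phi_draws, 0.975))}

    # ---- pointwise predictive quantities: DIC, WAIC, LOO-PIT
    # Deterministic Gauss-Hermite quadrature over each observation's Gaussian
    # posterior of eta (per hyper config), so information criteria carry no
    # Monte-Carlo noise and model selection compares like with like.
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(25)
    gh_w = gh_w / gh_w.sum()
    n_obs = len(y)
    e_ll = np.zeros(n_obs)  # E[log p]
    e_ll2 = np.zeros(n_obs)  # E[(log p)^2]
    p_bar = np.zeros(n_obs)  # E[p] (for lppd)
    pit_num = np.zeros(n_obs)  # IS-LOO PIT numerator E[F / p]
    pit_den = np.zeros(n_obs)  # and denominator E[1 / p]
    for cfg, wgt in zip(configs, weights):
        m_i = M @ cfg["z"]
        v_i = np.maximum(np.einsum("ij,ji->i", M, cho_solve(cfg["cho"], M.T)), 0.0)
        eta_nodes = m_i[:, None] + np.sqrt(v_i)[:, None] * gh_x[None, :]
        ll_nodes = beta_loglik(y[:, None], eta_nodes, cfg["phi"])
        mu_nodes = inv_logit(eta_nodes)
        cdf_nodes = beta_dist.cdf(y[:, None], mu_nodes * cfg["phi"],
                                  (1.0 - mu_nodes) * cfg["phi"])
        dens = np.exp(ll_nodes)
        e_ll += wgt * (ll_nodes @ gh_w)
        e_ll2 += wgt * ((ll_nodes ** 2) @ gh_w)
        p_bar += wgt * (dens @ gh_w)
        inv_dens = 1.0 / np.maximum(dens, 1e-290)
        pit_num += wgt * ((cdf_nodes * inv_dens) @ gh_w)
        pit_den += wgt * (inv_dens @ gh_w)

    z_bar = weights @ np.stack([c["z"] for c in configs])
    d_at_mean = -2.0 * beta_loglik(y, M @ z_bar, phi_mean).sum()
    d_mean = -2.0 * e_ll.sum()
    p_d = d_mean - d_at_mean
    dic = float(d_at_mean + 2.0 * p_d)

    lppd = np.log(np.maximum(p_bar, 1e-290))
    p_waic = e_ll2 - e_ll ** 2
    waic = float(-2.0 * np.sum(lppd - p_waic))

    pit = np.clip(pit_num / pit_den, 0.0, 1.0)

    # posterior predictive intervals from sampled replicates
    eta_draws = z_draws @ M.T  # S x n
    mu_draws = inv_logit(eta_draws)
    a = mu_draws * phi_draws[:, None]
    b = (1.0 - mu_draws) * phi_draws[:, None]

    rng_ppc = np.random.default_rng(seed + 1)
    y_rep = rng_ppc.beta(a, b)
    ppc = pd.DataFrame({
        "observed": y,
        "pred_mean": mu_draws.mean(axis=0),
        "pred_lo": np.quantile(y_rep, 0.025, axis=0),
        "pred_hi": np.quantile(y_rep, 0.975, axis=0),
    })

    best = configs[int(np.argmax([c["log_post"] for c in configs]))]
    return FitResult(
        component_id=component_id, covariate_names=cov_names, fixed_effects=fixed,
        phi=phi_summary, hyper=hyper, field_mean=field_mean, field_sd=field_sd,
        dic=float(dic), waic=waic, pit=pit, ppc=ppc, mesh=mesh,
        draws_z=z_draws, draws_phi=phi_draws, n_field=n_field,
        log_marginal=float(best["log_marg"]),
    )


def forward_select(
    response: np.ndarray,
    candidates: pd.DataFrame,
    locations: np.ndarray,
    mesh: Mesh,
    priors: Priors | None = None,
    waic_improvement: float = 6.0,
    component_id: str = "component",
    seed: int = 0,
) -> tuple[list[str], FitResult]:
    """Greedy forward covariate selection on WAIC (primary) and DIC.

    Starting from the intercept-only model, each round refits every
    not-yet-included candidate; the best candidate is accepted only if it
    lowers WAIC by more than ``waic_improvement`` AND lowers DIC.
    """
    if candidates.shape[1] == 0:
        raise ValueError("need at least one candidate covariate")
    priors = priors or Priors()

    def _fit(cols):
        design = candidates[cols] if cols else None
        return fit_component(response, design, locations, mesh, priors,
                             component_id=component_id, seed=seed)

    selected: list[str] = []
    current = _fit(selected)
    remaining = list(candidates.columns)
    while remaining:
        trials = []
        for name in remaining:
            try:
                trials.append((name, _fit(selected + [name])))
            except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
                log.warning("forward_select: candidate %s failed (%s); skipped", name, exc)
        if not trials:
            break
        name, fit = min(trials, key=lambda t: t[1].waic)
        if (current.waic - fit.waic) > waic_improvement and (current.dic - fit.dic) > 0:
            log.info("forward_select: accepted %s (WAIC %.2f -> %.2f)",
                     name, current.waic, fit.waic)
            selected.append(name)
            remaining.remove(name)
            current = fit
        else:
            break
    return selected, current


def diagnostics(fit: FitResult, n_bins: int = 10) -> dict:
    """PIT uniformity and posterior predictive coverage report."""
    pit = np.asarray(fit.pit)
    hist, _ = np.histogram(pit, bins=n_bins, range=(0.0, 1.0))
    grid = np.sort(pit)
    ecdf = np.arange(1, len(grid) + 1) / len(grid)
    ks = float(np.max(np.abs(ecdf - grid)))
    covered = ((fit.ppc["observed"] >= fit.ppc["pred_lo"])
               & (fit.ppc["observed"] <= fit.ppc["pred_hi"]))
    return {
        "pit_hist": hist.tolist(),
        "pit_ks": ks,
        "coverage_95": float(covered.mean()),
        "dic": fit.dic,
        "waic": fit.waic,
    }
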