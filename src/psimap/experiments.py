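"""Replicated simulation experiments at the package's study conditions.

These are the canonical scenarios used by the test suite and by
``scripts/acceptance.py``; they live in the library so both recompute the
same quantities from scratch.

Study conditions (see docs/methods.md for rationale):

* Country: 150 x 150 km, 3 provinces x 4 districts, 1.5 km covariate cells.
* Recovery / selection: one roster-sourced proportion component,
  beta0 = -1, beta_ACCESS = 0.8 (recovery) or 1.0 (selection),
  Matern range 30 km, marginal sd 0.7, 300 clusters of 25 households,
  no geomasking jitter (masking is exercised in the end-to-end run).
* End-to-end: the three-component demo scenario with 2 km jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psi_scoring import compose_psi, pss_for_direction, zonal_summary
from .spatialfield import (
    Priors, build_mesh, fit_component, forward_select, predict_surface,
    squeeze_response,
)
from .surveyprep import IndicatorSpec, aggregate_clusters
from .synthdata import (
    TruthFieldSpec, district_truth_summary, generate_admin_hierarchy,
    generate_covariates, generate_shdi, generate_truth_and_survey,
)
from .validation import spearman, validate

EXTENT_M = (150_000.0, 150_000.0)
N_PROVINCES, DISTRICTS_PER_PROVINCE = 3, 4
CELL_M = 1500.0
N_CLUSTERS, HOUSEHOLDS_PER_CLUSTER = 300, 25
MESH_CUTOFF_M, MESH_MAX_EDGE_M = 8_000.0, (20_000.0, 50_000.0)
TRUE_RANGE_M, TRUE_SD = 30_000.0, 0.7
CANDIDATES = ["ACCESS", "LST", "POPPP", "DMROADS", "NLIGHTS"]


@dataclass
class ClusterData:
    y: np.ndarray  # squeezed cluster proportions
    locations: np.ndarray
    candidates: pd.DataFrame  # standardized covariates at cluster locations
    mesh: object


def simulate_cluster_component(
    seed: int,
    betas: dict[str, float],
    beta0: float = -1.0,
    mask_jitter_m: float = 0.0,
) -> ClusterData:
    """One roster-sourced component at the recovery/selection conditions."""
    hierarchy = generate_admin_hierarchy(N_PROVINCES, DISTRICTS_PER_PROVINCE,
                                         EXTENT_M, seed=seed)
    stack = generate_covariates(hierarchy, cell_m=CELL_M, seed=seed + 100)
    spec = TruthFieldSpec("comp", "HSHS", beta0, betas, TRUE_RANGE_M, TRUE_SD,
                          table="roster")
    survey, _ = generate_truth_and_survey(
        hierarchy, stack, [spec], n_clusters=N_CLUSTERS,
        households_per_cluster=HOUSEHOLDS_PER_CLUSTER,
        mask_jitter_m=mask_jitter_m, seed=seed + 200)
    agg = aggregate_clusters(survey, {"comp": IndicatorSpec("roster", "proportion")})
    y = squeeze_response(agg.table["comp"].to_numpy(), agg.counts["comp"].to_numpy())
    loc = agg.table[["x", "y"]].to_numpy()
    std = stack.standardized()
    cand = pd.DataFrame({n: std.sample(n, loc[:, 0], loc[:, 1]) for n in CANDIDATES})
    mesh = build_mesh(loc, MESH_CUTOFF_M, MESH_MAX_EDGE_M)
    return ClusterData(y, loc, cand, mesh)


def recovery_replicate(seed: int, beta0: float = -1.0, beta1: float = 0.8) -> dict:
    """Fit the single-covariate model and report credible-interval coverage
    of the true fixed effects."""
    data = simulate_cluster_component(seed, {"ACCESS": beta1}, beta0)
    fit = fit_component(data.y, data.candidates[["ACCESS"]], data.locations,
                        data.mesh, Priors(), seed=seed)
    fe = fit.fixed_effects
    return {
        "covers_intercept": bool(fe.loc["intercept", "lo"] <= beta0 <= fe.loc["intercept", "hi"]),
        "covers_slope": bool(fe.loc["ACCESS", "lo"] <= beta1 <= fe.loc["ACCESS", "hi"]),
        "beta0_mean": float(fe.loc["intercept", "mean"]),
        "beta1_mean": float(fe.loc["ACCESS", "mean"]),
        "fit": fit,
    }


def selection_replicate(seed: int, active_beta: float | None = 1.0) -> list[str]:
    """Forward selection over the five candidates; ``active_beta=None`` runs
    the null (no active covariate) scenario."""
    betas = {} if active_beta is None else {"ACCESS": active_beta}
    data = simulate_cluster_component(seed, betas)
    selected, _ = forward_select(data.y, data.candidates, data.locations,
                                 data.mesh, Priors(), seed=seed)
    return selected


END_TO_END_COMPONENTS = [
    TruthFieldSpec("owns_car", "HSLS", -0.8, {"ACCESS": 0.9}, TRUE_RANGE_M, 0.5,
                   table="households"),
    TruthFieldSpec("chronic_sickness", "HSHS", -1.2, {"LST": 0.7, "DMROADS": 0.4},
                   TRUE_RANGE_M, 0.5, table="roster"),
    TruthFieldSpec("no_employment", "HSHS", -0.5, {"POPPP": -0.6}, TRUE_RANGE_M, 0.5,
                   table="individuals"),
]


def end_to_end_replicate(seed: int, aggregation_factor: int = 2,
                         shdi_noise_sd: float = 0.0) -> dict:
    """Full chain on one synthetic country: survey -> aggregation -> spatial
    fits (each component on its generating covariates) -> surfaces -> zonal
    PSS -> composite PSI -> comparison against district-mean true
    susceptibility and noise-free development indices."""
    hierarchy = generate_admin_hierarchy(N_PROVINCES, DISTRICTS_PER_PROVINCE,
                                         EXTENT_M, seed=seed)
    stack = generate_covariates(hierarchy, cell_m=CELL_M, seed=seed + 100)
    survey, truths = generate_truth_and_survey(
        hierarchy, stack, END_TO_END_COMPONENTS, n_clusters=N_CLUSTERS,
        households_per_cluster=HOUSEHOLDS_PER_CLUSTER,
        mask_jitter_m=2000.0, seed=seed + 200)
    spec = {t.component_id: IndicatorSpec(t.spec.table, "proportion", t.spec.direction)
            for t in truths}
    agg = aggregate_clusters(survey, spec)
    loc = agg.table[["x", "y"]].to_numpy()
    std = stack.standardized()
    mesh = build_mesh(loc, MESH_CUTOFF_M, MESH_MAX_EDGE_M)

    scores = []
    for t in truths:
        name = t.component_id
        y = squeeze_response(agg.table[name].to_numpy(), agg.counts[name].to_numpy())
        X = pd.DataFrame({c: std.sample(c, loc[:, 0], loc[:, 1])
                          for c in t.spec.betas})
        fit = fit_component(y, X, loc, mesh, Priors(), component_id=name, seed=seed)
        surface = predict_surface(fit, std, aggregation_factor)
        z = zonal_summary(surface, hierarchy)
        scores.append(pss_for_direction(z, t.spec.direction))

    psi = compose_psi(scores, hierarchy)
    truth = district_truth_summary(truths, hierarchy, stack.grid)
    joined = psi.merge(truth, on=["district_id", "province_id"])
    rho_truth = spearman(joined["psi"], joined["true_susceptibility"])

    shdi = generate_shdi(hierarchy, truths, stack.grid,
                         noise_sd=shdi_noise_sd, seed=seed + 300)
    val = validate(psi, hierarchy, shdi)
    return {"spearman_truth": rho_truth, "validation": val, "psi": psi}


def validation_sign_replicate(seed: int) -> "ValidationResult":
    """Sign contract of the convergent-validity test under perfect recovery:
    the district PSI is set to the true susceptibility (no estimation error)
    and the development indices are noise-free, so both Spearman coefficients
    must come out negative ("aligned") in every replicate.

    This isolates the validation module's sign logic; the state-relative PSS
    normalisation itself does not preserve between-province ordering (the
    estimated-PSI alignment is reported by :func:`end_to_end_replicate`).
    """
    hierarchy = generate_admin_hierarchy(N_PROVINCES, DISTRICTS_PER_PROVINCE,
                                         EXTENT_M, seed=seed)
    stack = generate_covariates(hierarchy, cell_m=CELL_M, seed=seed + 100)
    rng = np.random.default_rng(seed + 200)
    from .synthdata.fields import realize_truth
    truths = [realize_truth(spec, stack.standardized().layers, stack.grid, rng)
              for spec in END_TO_END_COMPONENTS]
    truth = district_truth_summary(truths, hierarchy, stack.grid)
    perfect = truth.rename(columns={"true_susceptibility": "psi"})
    shdi = generate_shdi(hierarchy, truths, stack.grid, noise_sd=0.0, seed=seed + 300)
    return validate(perfect, hierarchy, shdi)
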