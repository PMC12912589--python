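"""PHIA-like survey tables with known ground truth.

Emulates the three-table survey structure (household / roster / individual)
with the three named weights used downstream, a clustered design with masked
(jittered) cluster centroids, and province-level development indices that are
negatively correlated with true susceptibility (for convergent-validity
testing).  No biomarker content is generated: the scoring pipeline only uses
sociodemographic indicators and weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .admin import AdminHierarchy
from .covariates import CovariateStack
from .fields import TruthField, TruthFieldSpec, realize_truth

WEIGHT_COLUMNS = {
    "households": "household_final_weight",
    "roster": "trimmed_person_nonresponse_weight",
    "individuals": "individual_final_weight",
}


@dataclass
class SurveyTables:
    households: pd.DataFrame
    roster: pd.DataFrame
    individuals: pd.DataFrame
    clusters: pd.DataFrame  # cluster_id, x, y (masked), province_id, district_id

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("households", "roster", "individuals", "clusters"):
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "SurveyTables":
        directory = Path(directory)
        return cls(**{
            name: pd.read_csv(directory / f"{name}.csv")
            for name in ("households", "roster", "individuals", "clusters")
        })


@dataclass
class ShdiTable:
    """Province-level health / life-expectancy development indices in [0, 1]."""

    table: pd.DataFrame  # province_id, health_index, life_expectancy_index

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ShdiTable":
        return cls(pd.read_csv(path))


def _assign_districts(hierarchy: AdminHierarchy, xy: np.ndarray) -> np.ndarray:
    """District id per point; points on shared boundaries go to the first
    district in id order that covers them."""
    out = np.array([None] * len(xy), dtype=object)
    for d in sorted(hierarchy.districts, key=lambda u: u.unit_id):
        unassigned = out == None  # noqa: E711
        if not unassigned.any():
            break
        hit = shapely.intersects_xy(d.geometry, xy[unassigned, 0], xy[unassigned, 1])
        idx = np.flatnonzero(unassigned)[hit]
        out[idx] = d.unit_id
    return out


def _jitter_within(rng, x, y, district_geom, radius: float, tries: int = 200):
    """Uniform-disc jitter clamped to stay inside the district."""
    if radius <= 0:
        return x, y
    for _ in range(tries):
        r = radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        jx, jy = x + r * np.cos(theta), y + r * np.sin(theta)
        if district_geom.covers(shapely.points(jx, jy)):
            return jx, jy
    return x, y  # clamp to the true location if the disc barely overlaps


def generate_truth_and_survey(
    hierarchy: AdminHierarchy,
    covariates: CovariateStack,
    components: list[TruthFieldSpec],
    n_clusters: int = 300,
    households_per_cluster: int = 25,
    mask_jitter_m: float = 2000.0,
    seed: int = 0,
    weight_sigma: float = 0.3,
    mean_household_size: float = 4.5,
) -> tuple[SurveyTables, list[TruthField]]:
    """Draw cluster locations, realise each component's truth field, and
    simulate the three weighted survey tables.

    For each component the cluster-level linear predictor is
    eta = beta0 + sum_j beta_j * z_j(s) + u(s), with z_j the standardized
    covariates and u the Matern latent field.  Binary indicators are
    Bernoulli(inv-logit(eta)) per row of their source table; count
    (median-type) indicators are drawn as 1 + Poisson(6 * p).  The roster
    lists every household member (household sizes 1 + Poisson(mean - 1), as in
    a census-style listing); the individual table holds the interviewed adults
    (one plus roughly 40% of the remaining members).  Weights are
    log-normal(0, weight_sigma), independent across rows.
    """
    rng = np.random.default_rng(seed)
    std = covariates.standardized()
    truths = [realize_truth(spec, std.layers, covariates.grid, rng) for spec in components]

    # cluster locations uniform over the country
    minx, miny, maxx, maxy = hierarchy.extent
    pts = []
    while len(pts) < n_clusters:
        xy = rng.uniform([minx, miny], [maxx, maxy], size=(2 * n_clusters, 2))
        keep = shapely.contains_xy(hierarchy.extent_polygon, xy[:, 0], xy[:, 1])
        pts.extend(xy[keep].tolist())
    xy = np.asarray(pts[:n_clusters])
    district_ids = _assign_districts(hierarchy, xy)
    prov_of = hierarchy.province_of_district()
    geom_of = {d.unit_id: d.geometry for d in hierarchy.districts}

    cluster_rows = []
    for ci in range(n_clusters):
        cid = f"C{ci + 1:04d}"
        did = district_ids[ci]
        mx, my = _jitter_within(rng, xy[ci, 0], xy[ci, 1], geom_of[did], mask_jitter_m)
        cluster_rows.append({
            "cluster_id": cid, "x": mx, "y": my,
            "true_x": xy[ci, 0], "true_y": xy[ci, 1],
            "district_id": did, "province_id": prov_of[did],
        })
    clusters = pd.DataFrame(cluster_rows)

    # cluster-level true probabilities per component (at the TRUE location)
    r, c = covariates.grid.index_of(xy[:, 0], xy[:, 1])
    p_cluster = {t.component_id: np.clip(t.p_raster[r, c], 1e-9, 1 - 1e-9) for t in truths}

    # household skeleton
    n_hh = n_clusters * households_per_cluster
    hh_cluster_idx = np.repeat(np.arange(n_clusters), households_per_cluster)
    hh_ids = np.array([f"C{ci + 1:04d}-H{hi + 1:03d}"
                       for ci in range(n_clusters)
                       for hi in range(households_per_cluster)])
    households = pd.DataFrame({
        "cluster_id": clusters["cluster_id"].to_numpy()[hh_cluster_idx],
        "household_id": hh_ids,
        "household_final_weight": rng.lognormal(0.0, weight_sigma, n_hh),
    })

    # roster: every member of every household; individuals: interviewed adults
    hh_size = 1 + rng.poisson(max(mean_household_size - 1.0, 0.0), n_hh)
    n_adults = 1 + rng.binomial(hh_size - 1, 0.4)
    ro_hh_idx = np.repeat(np.arange(n_hh), hh_size)
    member_no = np.concatenate([np.arange(s) for s in hh_size])
    roster = pd.DataFrame({
        "cluster_id": households["cluster_id"].to_numpy()[ro_hh_idx],
        "household_id": hh_ids[ro_hh_idx],
        "person_id": [f"{h}-R{m + 1}" for h, m in zip(hh_ids[ro_hh_idx], member_no)],
        "trimmed_person_nonresponse_weight": rng.lognormal(0.0, weight_sigma, len(ro_hh_idx)),
    })
    ind_hh_idx = np.repeat(np.arange(n_hh), n_adults)
    adult_no = np.concatenate([np.arange(s) for s in n_adults])
    individuals = pd.DataFrame({
        "cluster_id": households["cluster_id"].to_numpy()[ind_hh_idx],
        "person_id": [f"{h}-I{m + 1}" for h, m in zip(hh_ids[ind_hh_idx], adult_no)],
        "individual_final_weight": rng.lognormal(0.0, weight_sigma, len(ind_hh_idx)),
    })

    table_cluster_idx = {
        "households": hh_cluster_idx,
        "roster": hh_cluster_idx[ro_hh_idx],
        "individuals": hh_cluster_idx[ind_hh_idx],
    }
    tables = {"households": households, "roster": roster, "individuals": individuals}
    for t in truths:
        p_rows = p_cluster[t.component_id][table_cluster_idx[t.spec.table]]
        if t.spec.response_type == "median_count":
            vals = 1 + rng.poisson(6.0 * p_rows)
        else:
            vals = (rng.uniform(size=len(p_rows)) < p_rows).astype(int)
        tables[t.spec.table][t.component_id] = vals

    return SurveyTables(households, roster, individuals, clusters), truths


def district_truth_summary(
    truths: list[TruthField], hierarchy: AdminHierarchy, grid
) -> pd.DataFrame:
    """District-mean true susceptibility (sum over components, HSLS flipped)."""
    total = sum(t.susceptibility_raster() for t in truths)
    gx, gy = grid.cell_centers()
    flat_x, flat_y, flat_v = gx.ravel(), gy.ravel(), total.ravel()
    rows = []
    for d in hierarchy.districts:
        inside = shapely.contains_xy(d.geometry, flat_x, flat_y)
        rows.append({
            "district_id": d.unit_id,
            "province_id": d.parent_id,
            "true_susceptibility": float(flat_v[inside].mean()) if inside.any() else np.nan,
        })
    return pd.DataFrame(rows)


def generate_shdi(
    hierarchy: AdminHierarchy,
    truths: list[TruthField],
    grid,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> ShdiTable:
    """Province development indices as a decreasing affine transform of
    province-level true susceptibility plus Gaussian noise, clamped to [0, 1].

    The province statistic is the median over districts of district-mean
    truth — the same aggregation the convergent-validity test applies to the
    PSI — so with noise_sd = 0 the health-index ranking is exactly the
    reverse of the true susceptibility ranking."""
    if len(hierarchy.provinces) < 2:
        raise ValueError("need at least 2 provinces")
    rng = np.random.default_rng(seed)
    dist = district_truth_summary(truths, hierarchy, grid)
    prov = dist.groupby("province_id")["true_susceptibility"].median()
    lo, hi = prov.min(), prov.max()
    span = (hi - lo) if hi > lo else 1.0
    rows = []
    for pid, s in prov.items():
        base = 0.8 - 0.5 * (s - lo) / span  # decreasing in susceptibility
        rows.append({
            "province_id": pid,
            "health_index": float(np.clip(base + rng.normal(0, noise_sd), 0, 1)),
            "life_expectancy_index": float(np.clip(base + rng.normal(0, noise_sd), 0, 1)),
        })
    return ShdiTable(pd.DataFrame(rows))
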