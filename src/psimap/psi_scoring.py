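"""District susceptibility scoring: zonal summaries of component surfaces,
directional PSS formulas, composite PSI, Jenks natural-breaks classes and
distribution summaries.

Directionality:

* HSLS ("high value confers low susceptibility", e.g. car ownership):
  X_i = state_median_i - lga_median_i; Y = X + max(X); PSS = Y / max(Y).
* HSHS ("high value confers high susceptibility", e.g. chronic sickness):
  X_i = lga_median_i / state_median_i; PSS = X / max(X).

The composite PSI is the unweighted sum of component PSS (equal weighting);
districts missing any component stay unscored and classify as Unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .grids import RasterGrid
from .spatialfield.predict import PredictionSurface
from .synthdata.admin import AdminHierarchy

log = logging.getLogger(__name__)

CLASS_LABELS = ["Low", "Relatively Low", "Relatively Moderate",
                "Relatively High", "Very High"]
UNCLASSIFIED = "Unclassified"


# ----------------------------------------------------------------- zonal stats

@dataclass
class ZonalSummary:
    component_id: str
    districts: pd.DataFrame  # district_id, province_id, lga_median, lga_max
    provinces: pd.DataFrame  # province_id, state_median, state_max


def _assign_cells(grid: RasterGrid, hierarchy: AdminHierarchy) -> dict[str, np.ndarray]:
    """Flat cell indices per district by cell-centre containment; a centre on
    a shared boundary goes to the first district in id order (deterministic)."""
    gx, gy = grid.cell_centers()
    fx, fy = gx.ravel(), gy.ravel()
    taken = np.zeros(fx.size, dtype=bool)
    out = {}
    for d in sorted(hierarchy.districts, key=lambda u: u.unit_id):
        hit = shapely.intersects_xy(d.geometry, fx, fy) & ~taken
        out[d.unit_id] = np.flatnonzero(hit)
        taken |= hit
    return out


def zonal_summary(surface: PredictionSurface, hierarchy: AdminHierarchy) -> ZonalSummary:
    """Median and max of the posterior-mean surface per district and province.

    Even-count medians are the mean of the two middle values.  Districts with
    no covered cell are flagged missing (NaN) and logged.
    """
    cells = _assign_cells(surface.grid, hierarchy)
    flat = surface.mean.ravel()
    if not any(len(ix) for ix in cells.values()):
        raise ValueError("surface grid does not overlap any district")
    drows = []
    for d in hierarchy.districts:
        vals = flat[cells[d.unit_id]]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            log.warning("district %s has no covered cells; flagged missing", d.unit_id)
            med = mx = np.nan
        else:
            med, mx = float(np.median(vals)), float(np.max(vals))
        drows.append({"district_id": d.unit_id, "province_id": d.parent_id,
                      "lga_median": med, "lga_max": mx})
    prows = []
    for p in hierarchy.provinces:
        member = np.concatenate([cells[d.unit_id] for d in hierarchy.districts
                                 if d.parent_id == p.unit_id] or [np.array([], dtype=int)])
        vals = flat[member]
        vals = vals[np.isfinite(vals)]
        prows.append({"province_id": p.unit_id,
                      "state_median": float(np.median(vals)) if len(vals) else np.nan,
                      "state_max": float(np.max(vals)) if len(vals) else np.nan})
    return ZonalSummary(surface.component_id, pd.DataFrame(drows), pd.DataFrame(prows))


# ----------------------------------------------------------------- PSS formulas

def _with_state_median(z: ZonalSummary) -> pd.DataFrame:
    return z.districts.merge(z.provinces[["province_id", "state_median"]],
                             on="province_id", how="left")


def pss_hsls(z: ZonalSummary) -> pd.Series:
    """PSS for a high-value-confers-LOW-susceptibility component.

    Negative Y (possible when min(X) < -max(X)) is clamped to zero before
    normalisation; an all-degenerate component (max Y = 0) scores all zeros.
    """
    df = _with_state_median(z)
    x = df["state_median"] - df["lga_median"]
    max_x = np.nanmax(x.to_numpy()) if np.isfinite(x).any() else np.nan
    y = x + max_x
    n_neg = int((y < 0).sum())
    if n_neg:
        log.info("pss_hsls(%s): clamped %d negative Y values to 0", z.component_id, n_neg)
    y = y.clip(lower=0.0)
    max_y = np.nanmax(y.to_numpy()) if np.isfinite(y).any() else np.nan
    if not np.isfinite(max_y) or max_y == 0:
        log.warning("pss_hsls(%s): degenerate (max Y = 0); all PSS set to 0", z.component_id)
        pss = pd.Series(np.where(df["lga_median"].notna(), 0.0, np.nan))
    else:
        pss = y / max_y
    return pd.Series(pss.to_numpy(), index=df["district_id"], name=z.component_id)


def pss_hshs(z: ZonalSummary) -> pd.Series:
    """PSS for a high-value-confers-HIGH-susceptibility component."""
    df = _with_state_median(z)
    state = df["state_median"].where(df["state_median"] != 0)
    n_zero = int((df["state_median"] == 0).sum())
    if n_zero:
        log.warning("pss_hshs(%s): %d district(s) under a zero state median; flagged missing",
                    z.component_id, n_zero)
    x = df["lga_median"] / state
    max_x = np.nanmax(x.to_numpy()) if np.isfinite(x).any() else np.nan
    pss = x / max_x if np.isfinite(max_x) and max_x != 0 else x * np.nan
    return pd.Series(pss.to_numpy(), index=df["district_id"], name=z.component_id)


def pss_for_direction(z: ZonalSummary, direction: str) -> pd.Series:
    if direction == "HSLS":
        return pss_hsls(z)
    if direction == "HSHS":
        return pss_hshs(z)
    raise ValueError(f"unknown direction {direction!r}")


# ----------------------------------------------------------------- composite

@dataclass
class ScoreTable:
    table: pd.DataFrame  # district_id, province_id, <component PSS...>, psi, psi_class
    n_components: int
    breaks: "ClassBreaks | None" = None


def compose_psi(scores: list[pd.Series], hierarchy: AdminHierarchy | None = None) -> pd.DataFrame:
    """Unweighted sum of component PSS per district; a district missing any
    component gets a missing PSI."""
    if not scores:
        raise ValueError("need at least one component PSS")
    df = pd.concat(scores, axis=1)
    df.index.name = "district_id"
    df["psi"] = df.sum(axis=1, skipna=False)
    out = df.reset_index()
    if hierarchy is not None:
        out.insert(1, "province_id", out["district_id"].map(hierarchy.province_of_district()))
    return out


# ----------------------------------------------------------------- Jenks breaks

@dataclass
class ClassBreaks:
    k: int
    breakpoints: list[float]  # k - 1 interior cut values (upper bound of each class but the last)
    labels: list[str] = field(default_factory=lambda: list(CLASS_LABELS))
    gvf: float = np.nan  # goodness of variance fit


def fisher_jenks(values: np.ndarray, k: int) -> list[np.ndarray]:
    """Exact optimal 1-D partition into k contiguous classes minimising the
    within-class sum of squared deviations (Fisher's dynamic programme)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v ** 2)])

    def ssd(i, j):  # within-class SSD of v[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                val = cost[c - 1, i] + ssd(i, j)
                if val < best:
                    best, arg = val, i
            cost[c, j], back[c, j] = best, arg
    bounds = [n]
    for c in range(k, 0, -1):
        bounds.append(back[c, bounds[-1]])
    bounds = bounds[::-1]
    return [v[bounds[c]: bounds[c + 1]] for c in range(k)]


def jenks_classify(psi: pd.Series | np.ndarray, k: int = 5) -> tuple[ClassBreaks, pd.Series]:
    """Classify PSI values into k natural-breaks classes with ascending labels;
    missing values label as Unclassified."""
    s = pd.Series(psi)
    vals = s.dropna().to_numpy(dtype=float)
    if len(np.unique(vals)) < k:
        raise ValueError(
            f"only {len(np.unique(vals))} distinct finite values; choose k < that"
        )
    classes = fisher_jenks(vals, k)
    breakpoints = [float(c[-1]) for c in classes[:-1]]
    total_ss = float(np.sum((vals - vals.mean()) ** 2))
    within = float(sum(np.sum((c - c.mean()) ** 2) for c in classes))
    gvf = 1.0 - within / total_ss if total_ss > 0 else 1.0
    labels = CLASS_LABELS if k == 5 else [f"class_{i + 1}" for i in range(k)]

    def label_of(v):
        if not np.isfinite(v):
            return UNCLASSIFIED
        idx = int(np.searchsorted(breakpoints, v, side="left"))
        return labels[min(idx, k - 1)]

    assigned = s.apply(label_of)
    assigned.name = "psi_class"
    return ClassBreaks(k, breakpoints, list(labels), gvf), assigned


def score_table(
    scores: list[pd.Series],
    hierarchy: AdminHierarchy,
    k: int = 5,
) -> ScoreTable:
    """Compose PSI and attach Jenks class labels (full scoring stage)."""
    df = compose_psi(scores, hierarchy)
    breaks, labels = jenks_classify(df["psi"], k)
    df["psi_class"] = labels.to_numpy()
    return ScoreTable(df, n_components=len(scores), breaks=breaks)


# ----------------------------------------------------------------- summaries

def describe_distribution(psi: pd.Series | np.ndarray) -> dict:
    """Mean / median / sample sd / adjusted Fisher-Pearson skewness etc."""
    s = pd.Series(psi, dtype=float)
    vals = s.dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError("need at least 2 finite values")
    return {
        "n": int(len(vals)),
        "n_missing": int(s.isna().sum()),
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "sd": float(np.std(vals, ddof=1)),
        "skewness": float(stats.skew(vals, bias=False)) if np.std(vals) > 0 else 0.0,
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
    }
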