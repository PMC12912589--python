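"""Survey-cluster aggregation and variable reduction.

The reduction pipeline runs in a fixed order: weighted cluster aggregation ->
zero-variance filter -> positive-correlation pruning (threshold 0.7) ->
Kaiser-Meyer-Olkin sampling adequacy -> principal-axis factor analysis with
Varimax rotation -> one representative (highest-|loading|) variable per
factor.  Representatives feed the geostatistical surface stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata.survey import SurveyTables, WEIGHT_COLUMNS

log = logging.getLogger(__name__)


# ----------------------------------------------------------------- weighted stats

def weighted_proportion(values, weights) -> float:
    """sum(w*x)/sum(w) for binary (or already 0/1-coded) values."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return float(np.sum(w * v) / np.sum(w))


def weighted_median(values, weights) -> float:
    """Lower weighted median: smallest value whose cumulative weight reaches
    half the total.  Applied identically at every aggregation level."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(v[order][idx])


# ----------------------------------------------------------------- aggregation

@dataclass
class IndicatorSpec:
    """Where an indicator lives and how it is aggregated."""

    table: str  # households | roster | individuals
    kind: str  # proportion | median
    direction: str = "HSHS"  # used downstream in scoring
    weight: str | None = None  # defaults to the table's canonical weight

    def weight_column(self) -> str:
        return self.weight or WEIGHT_COLUMNS[self.table]


@dataclass
class ClusterAggregate:
    table: pd.DataFrame  # cluster_id, x, y + one column per indicator
    provenance: dict[str, dict] = field(default_factory=dict)  # column -> {table, weight, kind}
    counts: pd.DataFrame | None = None  # contributing respondents per cluster x indicator

    @property
    def indicator_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("cluster_id", "x", "y", "district_id", "province_id")]

    def values(self) -> pd.DataFrame:
        return self.table[self.indicator_columns]

    def subset(self, columns: list[str]) -> "ClusterAggregate":
        keep = [c for c in self.table.columns if c not in self.indicator_columns] + list(columns)
        counts = self.counts[[c for c in columns if c in self.counts.columns]] \
            if self.counts is not None else None
        return ClusterAggregate(self.table[keep].copy(),
                                {c: self.provenance[c] for c in columns if c in self.provenance},
                                counts)


def aggregate_clusters(
    survey: SurveyTables, indicator_spec: dict[str, IndicatorSpec]
) -> ClusterAggregate:
    """Weighted per-cluster proportions / medians linked to masked centroids."""
    base = survey.clusters[["cluster_id", "x", "y", "district_id", "province_id"]].copy()
    counts = survey.clusters[["cluster_id"]].copy()
    provenance = {}
    for name, spec in indicator_spec.items():
        df = getattr(survey, spec.table)
        wcol = spec.weight_column()
        if name not in df.columns:
            raise KeyError(f"indicator {name!r} not in table {spec.table!r}")
        stat = weighted_proportion if spec.kind == "proportion" else weighted_median
        vals, ns = {}, {}
        for cid, grp in df.groupby("cluster_id"):
            ok = grp[name].notna()
            ns[cid] = int(ok.sum())
            if not ok.any():
                log.warning("indicator %s: all-missing in cluster %s", name, cid)
                vals[cid] = np.nan
                continue
            vals[cid] = stat(grp.loc[ok, name], grp.loc[ok, wcol])
        base[name] = base["cluster_id"].map(vals)
        counts[name] = counts["cluster_id"].map(ns).fillna(0).astype(int)
        provenance[name] = {"table": spec.table, "weight": wcol, "kind": spec.kind,
                            "direction": spec.direction}
    return ClusterAggregate(base, provenance, counts)


# ----------------------------------------------------------------- reduction

def drop_zero_variance(agg: ClusterAggregate, tol: float = 1e-12) -> ClusterAggregate:
    if not agg.indicator_columns:
        raise ValueError("no indicator columns")
    keep = []
    for col in agg.indicator_columns:
        v = agg.table[col].dropna().to_numpy(dtype=float)
        if len(v) > 1 and np.var(v - v.mean()) > tol:
            keep.append(col)
    if not keep:
        raise ValueError("all indicator columns have zero variance")
    return agg.subset(keep)


def prune_correlated(agg: ClusterAggregate, threshold: float = 0.7) -> ClusterAggregate:
    """Greedy redundancy elimination for highly *positively* correlated pairs.

    While any remaining pair has Pearson r >= threshold, take the pair with
    the largest r and drop the member with the larger mean absolute
    correlation to all other remaining variables (tie -> the lexicographically
    later name).  Negative correlations never trigger elimination.
    """
    cols = list(agg.indicator_columns)
    if len(cols) < 2:
        return agg
    corr = agg.values().corr(method="pearson")
    while True:
        sub = corr.loc[cols, cols]
        best_pair, best_r = None, threshold
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                r = sub.loc[a, b]
                if np.isfinite(r) and r >= best_r:
                    best_r, best_pair = r, (a, b)
        if best_pair is None:
            return agg.subset(cols)
        a, b = best_pair
        others = [c for c in cols if c not in best_pair]
        mean_abs = {
            v: (np.nanmean(np.abs(sub.loc[v, others])) if others else 0.0)
            for v in best_pair
        }
        if np.isclose(mean_abs[a], mean_abs[b]):
            drop = max(a, b)
        else:
            drop = a if mean_abs[a] > mean_abs[b] else b
        log.info("prune_correlated: dropping %s (pair r=%.3f)", drop, best_r)
        cols.remove(drop)


def kmo(agg: ClusterAggregate | pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy: sum r^2 / (sum r^2 + sum q^2)
    over off-diagonal entries, with q the anti-image partial correlations.

    Returns 0.5 (logged) in the degenerate orthogonal case where both sums
    vanish.  Raises on a singular correlation matrix, naming the columns.
    """
    data = agg.values() if isinstance(agg, ClusterAggregate) else agg
    corr = data.corr(method="pearson").to_numpy()
    names = list(data.columns)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular correlation matrix over columns {names}") from exc
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(len(corr), dtype=bool)
    r2 = np.sum(corr[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    if r2 + q2 < 1e-12:
        log.warning("KMO degenerate (orthogonal variables); returning 0.5")
        return 0.5
    return float(r2 / (r2 + q2))


# ----------------------------------------------------------------- factor analysis

def _varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal Varimax rotation (Kaiser, unnormalised)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam ** 3 - lam @ np.diag(np.sum(lam ** 2, axis=0)) / p)
        )
        rot = u @ vt
        if s.sum() < var * (1 + tol):
            break
        var = s.sum()
    return loadings @ rot


@dataclass
class FactorSolution:
    loadings: pd.DataFrame  # variables x factors, Varimax-rotated
    n_factors: int
    communalities: pd.Series
    kmo_overall: float
    representatives: list[str]  # one variable per factor, order = factor order

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "kmo_overall": self.kmo_overall,
            "loadings": self.loadings.round(6).to_dict(),
            "communalities": self.communalities.round(6).to_dict(),
            "representatives": self.representatives,
        }


def factor_select(
    agg: ClusterAggregate,
    n_factors: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-3,
) -> FactorSolution:
    """Principal-axis factoring with iterated communalities, Varimax rotation
    and highest-|loading| representative selection.

    The factor count defaults to the Kaiser rule applied to the reduced
    correlation matrix (squared-multiple-correlation diagonal): eigenvalues
    > 1, floored at one factor.  Heywood communalities are clamped to 0.995.
    """
    data = agg.values().dropna()
    names = list(data.columns)
    adequacy = kmo(agg)
    if adequacy < 0.5:
        warnings.warn(f"KMO sampling adequacy {adequacy:.3f} < 0.5; proceeding", stacklevel=2)
    corr = data.corr(method="pearson").to_numpy()
    p = len(names)

    inv = np.linalg.pinv(corr)
    smc = np.clip(1.0 - 1.0 / np.diag(inv), 0.0, 0.995)  # squared multiple correlations
    if n_factors is None:
        reduced = corr.copy()
        np.fill_diagonal(reduced, smc)
        eig = np.linalg.eigvalsh(reduced)
        n_factors = max(int(np.sum(eig > 1.0)), 1)
    k = min(n_factors, p)

    h = smc.copy()
    loadings = None
    heywood_seen = False
    for it in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h)
        vals, vecs = np.linalg.eigh(reduced)
        idx = np.argsort(vals)[::-1][:k]
        lam = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
        h_new = np.sum(lam ** 2, axis=1)
        heywood = h_new > 1.0
        if heywood.any():
            heywood_seen = True
            log.warning("Heywood case for %s; clamping", [names[i] for i in np.flatnonzero(heywood)])
            h_new = np.minimum(h_new, 0.995)
        change = float(np.max(np.abs(h_new - h)))
        h, loadings = h_new, lam
        if change < tol:
            break
    else:
        # a clamped Heywood case cannot settle below tol; accept the clamped
        # solution rather than abort (the KMO warning already flags such data)
        if heywood_seen and change < 0.05:
            log.warning("accepting clamped Heywood solution after %d iterations "
                        "(last communality change %.2e)", max_iter, change)
        else:
            raise RuntimeError(
                f"principal-axis factoring did not converge in {max_iter} iterations "
                f"(last communality change {change:.2e})"
            )

    rotated = _varimax(loadings)
    # orient each factor so its dominant loading is positive (sign is arbitrary)
    for j in range(rotated.shape[1]):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] *= -1
    lo = pd.DataFrame(rotated, index=names, columns=[f"F{j + 1}" for j in range(k)])
    comm = pd.Series(np.sum(rotated ** 2, axis=1), index=names, name="communality")

    reps = []
    for j in range(k):
        col = lo.iloc[:, j].abs()
        best = col.max()
        tied = sorted(col.index[np.isclose(col, best)],
                      key=lambda v: (-comm[v], v))
        reps.append(tied[0])
    return FactorSolution(lo, k, comm, adequacy, reps)
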