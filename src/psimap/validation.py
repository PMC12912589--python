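"""Convergent-validity testing of the composite PSI.

Province ("State") median PSI is compared by Spearman rank correlation with
the province-level health and life-expectancy development indices.  A valid
susceptibility index should correlate negatively with development: the
alignment flag is "aligned" iff the coefficient is negative.  Coefficients
are reported without significance tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthdata.admin import AdminHierarchy
from .synthdata.survey import ShdiTable

log = logging.getLogger(__name__)


def aggregate_state_psi(scores: pd.DataFrame, hierarchy: AdminHierarchy) -> pd.Series:
    """Median district PSI per province; missing PSI excluded, provinces with
    no valid district stay missing."""
    df = scores.copy()
    if "province_id" not in df.columns:
        df["province_id"] = df["district_id"].map(hierarchy.province_of_district())
    med = df.groupby("province_id")["psi"].median()
    return med.reindex([p.unit_id for p in hierarchy.provinces])


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks
    (average-rank ties).  Returns NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("spearman undefined for a constant vector; returning NaN")
        return float("nan")
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class ValidationResult:
    country_id: str
    rho_health: float
    rho_lifeexp: float
    n_provinces: int
    alignment_health: str  # "aligned" iff negative correlation
    alignment_lifeexp: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    def to_table(self) -> pd.DataFrame:
        """Country-by-coefficient table of the validation correlations."""
        return pd.DataFrame([{
            "country": self.country_id,
            "rho_health": self.rho_health,
            "rho_lifeexp": self.rho_lifeexp,
        }])


def _alignment(rho: float) -> str:
    return "aligned" if rho < 0 else "misaligned"


def validate(
    scores: pd.DataFrame,
    hierarchy: AdminHierarchy,
    shdi: ShdiTable,
    country_id: str = "SYN",
) -> ValidationResult:
    """Spearman correlation of province-median PSI against both development
    indices, with sign-based alignment flags."""
    state_psi = aggregate_state_psi(scores, hierarchy)
    joined = shdi.table.set_index("province_id").join(state_psi.rename("psi"))
    complete = joined.dropna(subset=["psi", "health_index", "life_expectancy_index"])
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 provinces with both PSI and indices, have {len(complete)}"
        )
    rho_h = spearman(complete["psi"], complete["health_index"])
    rho_l = spearman(complete["psi"], complete["life_expectancy_index"])
    return ValidationResult(
        country_id=country_id, rho_health=rho_h, rho_lifeexp=rho_l,
        n_provinces=len(complete),
        alignment_health=_alignment(rho_h), alignment_lifeexp=_alignment(rho_l),
    )
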