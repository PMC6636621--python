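"""Correlation structure among yields, indices and their rank patterns.

Two complementary matrices over the 11 ranked variables:

* Pearson product-moment correlation of the raw values — which indices move
  together, and which track yield under each environment;
* Spearman rank-order correlation, computed as Pearson correlation of the
  *direction-aware* rank columns (rank 1 = most favourable). Because the
  favourability direction is already absorbed into the ranks, a
  minimum-is-best index (TOL, SSI) that orders genotypes identically to a
  maximum-is-best one correlates at +1 here, where a textbook Spearman on
  the raw values would report −1.

Two-sided p-values come from the exact t transform
``t = r·√((n−2)/(1−r²))`` with n−2 degrees of freedom. Pairs with
undefined entries are handled pairwise-complete. No multiple-testing
correction is applied by default (a Bonferroni option exists): the 55
pairwise tests are reported at raw significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .indices import IndexTable
from .ranking import RankTable
from .trial import TrialTable

__all__ = ["AssociationMatrix", "pearson_matrix", "spearman_matrix", "heatmap_data", "HeatmapSpec"]


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric correlation matrix with two-sided p-values.

    ``method`` records what the coefficients were computed on:
    raw index values (``pearson-on-values``) or direction-aware ranks
    (``spearman-on-ranks``). Diagonal is exactly 1 (p = 0).
    """

    variables: tuple[str, ...]
    method: Literal["pearson-on-values", "spearman-on-ranks"]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def bonferroni_p(self) -> pd.DataFrame:
        """Bonferroni-adjusted p-values over the off-diagonal pairs."""
        k = len(self.variables)
        n_tests = k * (k - 1) // 2
        adj = np.minimum(self.p.to_numpy() * n_tests, 1.0)
        np.fill_diagonal(adj, 0.0)
        return pd.DataFrame(adj, index=self.p.index, columns=self.p.columns)


def _corr_matrix(
    frame: pd.DataFrame, method: Literal["pearson-on-values", "spearman-on-ranks"]
) -> AssociationMatrix:
    cols = list(frame.columns)
    k = len(cols)
    data = frame.to_numpy(dtype=float)
    r = np.eye(k)
    p = np.zeros((k, k))
    warned: set[str] = set()
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data[:, i], data[:, j]
            mask = np.isfinite(x) & np.isfinite(y)
            m = int(mask.sum())
            xv, yv = x[mask], y[mask]
            if m < 2 or np.ptp(xv) == 0 or np.ptp(yv) == 0:
                for name, v in ((cols[i], xv), (cols[j], yv)):
                    if m >= 2 and np.ptp(v) == 0 and name not in warned:
                        warned.add(name)
                        warnings.warn(
                            f"{name}: zero variance, correlations undefined", stacklevel=3
                        )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij = float(np.clip(np.corrcoef(xv, yv)[0, 1], -1.0, 1.0))
            r[i, j] = r[j, i] = rij
            if m < 3:
                pij = np.nan
            elif abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((m - 2) / (1.0 - rij**2))
                pij = 2.0 * stats.t.sf(abs(t), df=m - 2)
            p[i, j] = p[j, i] = pij
    idx = pd.Index(cols)
    return AssociationMatrix(
        variables=tuple(cols),
        method=method,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=len(frame),
    )


def pearson_matrix(
    index_table: IndexTable, trial: TrialTable | None = None
) -> AssociationMatrix:
    """Pearson correlations among the raw values of the 11 ranked variables."""
    if trial is not None and tuple(index_table.frame.index) != trial.genotypes:
        raise ValueError("index table and trial table are not aligned on genotypes")
    return _corr_matrix(index_table.ranked_values(), "pearson-on-values")


def spearman_matrix(rank_table: RankTable) -> AssociationMatrix:
    """Spearman correlations among the direction-aware rank columns.

    Ranks are already tie-averaged, so this is exactly Pearson correlation
    applied to the rank vectors. Columns excluded from ranking (undefined
    index values) propagate as NaN coefficients.
    """
    return _corr_matrix(rank_table.ranks, "spearman-on-ranks")


@dataclass(frozen=True)
class HeatmapSpec:
    """Deterministic heat-map layout for an association matrix.

    ``stars`` holds ``'**'`` for p < 0.01, ``'*'`` for p < 0.05, else ``''``.
    The colour scale is diverging and anchored at −1 / 0 / +1. For the
    ``mixed`` style the lower triangle shows numbers, the upper glyphs.
    """

    variables: tuple[str, ...]
    values: pd.DataFrame
    stars: pd.DataFrame
    style: Literal["square", "circle", "mixed"]
    method: str
    vmin: float = -1.0
    vmax: float = 1.0
    center: float = 0.0


def heatmap_data(
    matrix: AssociationMatrix, style: Literal["square", "circle", "mixed"] = "square"
) -> HeatmapSpec:
    """Build the plot specification for one of the three heat-map styles."""
    if style not in ("square", "circle", "mixed"):
        raise ValueError(f"unknown heat-map style: {style!r}")
    pv = matrix.p.to_numpy()
    stars = np.where(pv < 0.01, "**", np.where(pv < 0.05, "*", ""))
    stars[~np.isfinite(pv)] = ""
    np.fill_diagonal(stars, "")
    return HeatmapSpec(
        variables=matrix.variables,
        values=matrix.r.copy(),
        stars=pd.DataFrame(stars, index=matrix.p.index, columns=matrix.p.columns),
        style=style,
        method=matrix.method,
    )
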