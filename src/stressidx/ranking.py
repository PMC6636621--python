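"""Direction-aware genotype ranking and the average sum of ranks (ASR).

Each of the 11 ranked variables (Yp, Ys and the nine indices) is ranked so
that rank 1 is the most favourable genotype under that variable's pattern
of selection — the smallest value for TOL and SSI, the largest for all
others. Ties receive the average of the tied positions (fractional ranks),
which keeps the ranks compatible with Spearman's rank-order correlation
downstream.

Per genotype the rank sum, the average sum of ranks (ASR = mean rank) and
the sample standard deviation of the ranks summarise overall merit: the
lower the ASR, the more consistently superior the genotype across all
selection criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .indices import DIRECTIONS, RANKED_VARIABLES, IndexTable
from .trial import TrialTable

__all__ = ["RankTable", "rank_all", "sort_by_asr"]


@dataclass(frozen=True)
class RankTable:
    """Per-genotype ranks with sum, ASR and rank SD.

    ``ranks`` is indexed by genotype with one column per ranked variable
    (NaN for excluded, i.e. undefined, columns). ``asr_columns`` records
    whether the summary used all 11 columns or only the nine indices.
    """

    ranks: pd.DataFrame
    rank_sum: pd.Series
    asr: pd.Series
    rank_sd: pd.Series
    excluded: tuple[str, ...]
    asr_columns: int

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(self.ranks.index)


def rank_all(
    index_table: IndexTable,
    trial: TrialTable | None = None,
    asr_columns: int = 11,
) -> RankTable:
    """Rank every genotype under each of the 11 variables.

    Parameters
    ----------
    index_table
        Output of :func:`stressidx.compute_indices`; already carries the
        Yp/Ys columns, so ``trial`` is accepted for interface symmetry but
        only used to cross-check alignment.
    asr_columns
        11 (default) aggregates ranks over Yp, Ys and the nine indices;
        9 restricts the sum/ASR/SD to the indices alone. Either way all 11
        rank columns are reported.

    Columns whose values are undefined for the trial (e.g. SSI when
    Ȳs = Ȳp) are excluded from the aggregates and flagged in ``excluded``.
    """
    if asr_columns not in (9, 11):
        raise ValueError("asr_columns must be 9 or 11")
    if trial is not None and tuple(index_table.frame.index) != trial.genotypes:
        raise ValueError("index table and trial table are not aligned on genotypes")

    frame = index_table.frame
    n = len(frame)
    ranks: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for col in RANKED_VARIABLES:
        values = frame[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            excluded.append(col)
            ranks[col] = np.full(n, np.nan)
            continue
        keyed = values if DIRECTIONS[col] == "min" else -values
        ranks[col] = rankdata(keyed, method="average")
    if excluded:
        warnings.warn(
            f"columns excluded from rank aggregation (undefined values): {excluded}",
            stacklevel=2,
        )

    rank_frame = pd.DataFrame(ranks, index=frame.index)
    agg_cols = [
        c
        for c in RANKED_VARIABLES
        if c not in excluded and (asr_columns == 11 or c not in ("Yp", "Ys"))
    ]
    sub = rank_frame[agg_cols]
    return RankTable(
        ranks=rank_frame,
        rank_sum=sub.sum(axis=1).rename("Sum"),
        asr=sub.mean(axis=1).rename("ASR"),
        rank_sd=sub.std(axis=1, ddof=1).rename("SD"),
        excluded=tuple(excluded),
        asr_columns=asr_columns,
    )


def sort_by_asr(rank_table: RankTable) -> list[str]:
    """Genotypes ordered from most to least favourable overall.

    Ascending ASR; ties broken by ascending rank SD, then by input order
    (stable).
    """
    n = len(rank_table.asr)
    order = np.lexsort(
        (
            np.arange(n),
            rank_table.rank_sd.to_numpy(dtype=float),
            rank_table.asr.to_numpy(dtype=float),
        )
    )
    genotypes = rank_table.genotypes
    return [genotypes[i] for i in order]
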