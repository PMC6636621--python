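"""Tolerance and susceptibility indices.

Given per-genotype yields under non-stressed (Yp) and stressed (Ys)
conditions and the trial-wide means Ȳp, Ȳs, nine classical yield-based
selection indices are computed for every genotype, together with the
percent relative change (RC) due to stress:

====  ===============================  =========  ==================
id    formula                          direction  interpretation
====  ===============================  =========  ==================
TOL   Yp − Ys                          min        absolute yield loss
MP    (Yp + Ys) / 2                    max        arithmetic mean yield
GMP   √(Yp · Ys)                       max        geometric mean yield
HM    2·Yp·Ys / (Yp + Ys)              max        harmonic mean yield
SSI   (1 − Ys/Yp) / (1 − Ȳs/Ȳp)        min        loss vs. average loss
STI   Yp·Ys / Ȳp²                      max        joint performance
YI    Ys / Ȳs                          max        stress yield vs. mean
YSI   Ys / Yp                          max        yield retained
RSI   (Ys/Yp) / (Ȳs/Ȳp)                max        retention vs. average
====  ===============================  =========  ==================

RC = 100·(Yp − Ys)/Yp is the percent decrease from control, signed
(negative when the stressed yield exceeds the control).

Useful algebraic identities (exploited by the test suite):
``HM ≤ GMP ≤ MP`` with equality iff Yp = Ys; ``STI = GMP²/Ȳp²``;
``TOL = Yp·(1 − YSI)``; ``RSI = YSI·(Ȳp/Ȳs)``;
``SSI = (1 − YSI)/(1 − Ȳs/Ȳp)``; and mean(YI) = 1 over the trial.

All values are computed in double precision from the raw ratios with no
intermediate rounding; display rounding happens only in the report writer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .trial import TrialTable

__all__ = [
    "EnvironmentMeans",
    "IndexInfo",
    "IndexTable",
    "ALL_VARIABLES",
    "RANKED_VARIABLES",
    "INDEX_IDS",
    "compute_environment_means",
    "compute_indices",
    "index_metadata",
]


class EnvironmentMeans(NamedTuple):
    """Trial-wide mean yields Ȳp (non-stressed) and Ȳs (stressed)."""

    yp_bar: float
    ys_bar: float


@dataclass(frozen=True)
class IndexInfo:
    """Metadata for one ranked variable or index."""

    id: str
    name: str
    direction: Literal["min", "max"]
    reference: str
    ranked: bool  # participates in the rank table / ASR


# Fixed variable order used everywhere: yields, relative change, indices.
_METADATA: tuple[IndexInfo, ...] = (
    IndexInfo("Yp", "Yield under non-stressed conditions", "max", "trial data", True),
    IndexInfo("Ys", "Yield under stressed conditions", "max", "trial data", True),
    IndexInfo("RC", "Relative change (%)", "min", "derived", False),
    IndexInfo("TOL", "Tolerance index", "min", "Rosielle & Hamblin (1981)", True),
    IndexInfo("MP", "Mean productivity", "max", "Rosielle & Hamblin (1981)", True),
    IndexInfo("GMP", "Geometric mean productivity", "max", "Fernandez (1992)", True),
    IndexInfo("HM", "Harmonic mean", "max", "Bidinger et al. (1987)", True),
    IndexInfo("SSI", "Stress susceptibility index", "min", "Fischer & Maurer (1978)", True),
    IndexInfo("STI", "Stress tolerance index", "max", "Fernandez (1992)", True),
    IndexInfo("YI", "Yield index", "max", "Gavuzzi et al. (1997)", True),
    IndexInfo("YSI", "Yield stability index", "max", "Bouslama & Schapaugh (1984)", True),
    IndexInfo("RSI", "Relative stress index", "max", "Fischer & Wood (1979)", True),
)

ALL_VARIABLES: tuple[str, ...] = tuple(m.id for m in _METADATA)
RANKED_VARIABLES: tuple[str, ...] = tuple(m.id for m in _METADATA if m.ranked)
INDEX_IDS: tuple[str, ...] = tuple(
    m.id for m in _METADATA if m.id not in ("Yp", "Ys")
)
DIRECTIONS: dict[str, str] = {m.id: m.direction for m in _METADATA}


def index_metadata() -> tuple[IndexInfo, ...]:
    """Ordered metadata for Yp, Ys, RC and the nine indices (12 entries).

    ``direction`` is the pattern of selection: ``"min"`` means the smallest
    value identifies the most favourable genotype (TOL, SSI, and RC),
    ``"max"`` the largest (everything else, including the yields).
    """
    return _METADATA


def compute_environment_means(trial: TrialTable) -> EnvironmentMeans:
    """Arithmetic means of Yp and Ys over all genotypes (no weighting)."""
    return EnvironmentMeans(float(np.mean(trial.yp)), float(np.mean(trial.ys)))


@dataclass(frozen=True)
class IndexTable:
    """Per-genotype index values plus the environment means used.

    ``frame`` is indexed by genotype, columns in the fixed order
    Yp, Ys, RC, TOL, MP, GMP, HM, SSI, STI, YI, YSI, RSI. Columns that are
    undefined for the whole trial (SSI when Ȳs = Ȳp; YI and RSI when
    Ȳs = 0) are filled with NaN.
    """

    frame: pd.DataFrame
    means: EnvironmentMeans
    trait_name: str = "yield"
    units: str = ""

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def n(self) -> int:
        return len(self.frame)

    def ranked_values(self) -> pd.DataFrame:
        """The 11 columns (Yp, Ys + nine indices) that feed ranking and PCA."""
        return self.frame[list(RANKED_VARIABLES)]


def compute_indices(trial: TrialTable) -> IndexTable:
    """Compute RC and the nine indices for every genotype of ``trial``.

    SSI requires Ȳs ≠ Ȳp (its denominator is the average proportional
    loss); when the means coincide the SSI column is returned as NaN with a
    warning and every other index is still computed. Likewise YI and RSI
    are NaN when Ȳs = 0. When Ȳs > Ȳp (stress "benefit") SSI is computed
    as-is with a warning: the formula stays defined but its minimum-is-best
    reading inverts.
    """
    means = compute_environment_means(trial)
    yp, ys = trial.yp, trial.ys
    n = trial.n
    nan = np.full(n, np.nan)

    ysi = ys / yp
    loss_denom = 1.0 - means.ys_bar / means.yp_bar
    if loss_denom == 0.0:
        warnings.warn(
            "mean yields are equal under both conditions (Ȳs = Ȳp): "
            "SSI is undefined and returned as NaN",
            stacklevel=2,
        )
        ssi = nan
    else:
        if loss_denom < 0:
            warnings.warn(
                "mean stressed yield exceeds the non-stressed mean (Ȳs > Ȳp): "
                "SSI is computed but its selection direction inverts",
                stacklevel=2,
            )
        ssi = (1.0 - ysi) / loss_denom

    if means.ys_bar == 0.0:
        warnings.warn(
            "mean stressed yield is zero: YI and RSI are undefined and returned as NaN",
            stacklevel=2,
        )
        yi = nan
        rsi = nan
    else:
        yi = ys / means.ys_bar
        rsi = ysi / (means.ys_bar / means.yp_bar)

    frame = pd.DataFrame(
        {
            "Yp": yp,
            "Ys": ys,
            "RC": 100.0 * (yp - ys) / yp,
            "TOL": yp - ys,
            "MP": (yp + ys) / 2.0,
            "GMP": np.sqrt(yp * ys),
            "HM": 2.0 * yp * ys / (yp + ys),
            "SSI": ssi,
            "STI": yp * ys / means.yp_bar**2,
            "YI": yi,
            "YSI": ysi,
            "RSI": rsi,
        },
        index=pd.Index(trial.genotypes, name="Genotype"),
    )
    return IndexTable(frame=frame, means=means, trait_name=trial.trait_name, units=trial.units)
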