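"""Fernandez genotype grouping and the 3D (Yp × Ys × index) plot data.

Fernandez's classification splits genotypes into four groups by comparing
each genotype's yields with the trial means:

* **A** — above-average yield in both environments (Yp ≥ Ȳp, Ys ≥ Ȳs);
* **B** — above-average only without stress (Yp ≥ Ȳp, Ys < Ȳs);
* **C** — above-average only under stress (Yp < Ȳp, Ys ≥ Ȳs);
* **D** — below-average in both.

Boundary equality is assigned to the higher-performing side. Group A is the
selection target: genotypes with dependable performance whether or not the
stress occurs. Indices such as STI, GMP and MP — monotone in both yields —
are the ones able to separate group A, which is what the companion 3D plot
(Yp, Ys, chosen index) visualises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .indices import INDEX_IDS, EnvironmentMeans, IndexTable, compute_environment_means
from .trial import TrialTable

__all__ = ["GroupAssignment", "ThreeDSpec", "assign_groups", "threed_plot_data"]

GROUP_DESCRIPTIONS = {
    "A": "above-average yield in both environments",
    "B": "above-average yield only without stress",
    "C": "above-average yield only under stress",
    "D": "below-average yield in both environments",
}


@dataclass(frozen=True)
class GroupAssignment:
    """Fernandez group per genotype plus the mean thresholds used."""

    groups: pd.Series  # genotype -> 'A'|'B'|'C'|'D'
    yp_threshold: float
    ys_threshold: float

    def members(self, group: str) -> tuple[str, ...]:
        """Genotypes assigned to ``group``, in input order."""
        return tuple(self.groups.index[self.groups == group])

    def counts(self) -> dict[str, int]:
        return {g: int((self.groups == g).sum()) for g in "ABCD"}


def assign_groups(trial: TrialTable, means: EnvironmentMeans | None = None) -> GroupAssignment:
    """Classify every genotype into Fernandez group A/B/C/D.

    ``means`` defaults to the trial's own environment means; an explicit
    value lets callers reuse thresholds from a reference population.
    """
    if means is None:
        means = compute_environment_means(trial)
    hi_p = trial.yp >= means.yp_bar
    hi_s = trial.ys >= means.ys_bar
    codes = np.where(hi_p & hi_s, "A", np.where(hi_p, "B", np.where(hi_s, "C", "D")))
    return GroupAssignment(
        groups=pd.Series(codes, index=pd.Index(trial.genotypes, name="Genotype"), name="Group"),
        yp_threshold=means.yp_bar,
        ys_threshold=means.ys_bar,
    )


@dataclass(frozen=True)
class ThreeDSpec:
    """Data behind the 3D plot: x = Yp, y = Ys, z = chosen index.

    Points carry their Fernandez group for colouring and their label.
    """

    index_id: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    groups: tuple[str, ...]
    labels: tuple[str, ...]
    x_label: str
    y_label: str


def threed_plot_data(
    trial: TrialTable,
    index_table: IndexTable,
    index_id: str = "STI",
    genotypes: Sequence[str] | None = None,
) -> ThreeDSpec:
    """Assemble the (Yp, Ys, index) scatter for a chosen index.

    ``genotypes`` restricts the plot to a subset (the "genotypes control
    panel" behaviour); group membership is still computed on the full
    trial so colours keep their meaning.
    """
    if index_id not in INDEX_IDS:
        raise ValueError(f"unknown index id {index_id!r}; choose one of {INDEX_IDS}")
    assignment = assign_groups(trial)
    frame = index_table.frame
    if genotypes is None:
        subset = list(frame.index)
    else:
        missing = [g for g in genotypes if g not in frame.index]
        if missing:
            raise ValueError(f"unknown genotypes: {missing}")
        subset = list(genotypes)
    z = frame.loc[subset, index_id].to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"index {index_id} is undefined for some requested genotypes")
    units = f" ({index_table.units})" if index_table.units else ""
    return ThreeDSpec(
        index_id=index_id,
        x=frame.loc[subset, "Yp"].to_numpy(dtype=float),
        y=frame.loc[subset, "Ys"].to_numpy(dtype=float),
        z=z,
        groups=tuple(assignment.groups.loc[subset]),
        labels=tuple(subset),
        x_label=f"Yp{units}",
        y_label=f"Ys{units}",
    )
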