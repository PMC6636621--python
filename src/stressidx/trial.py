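"""The two-environment trial table.

A trial table is the sole raw input of every analysis in this package: one
row per genotype with its mean yield under non-stressed conditions (``Yp``)
and under stressed conditions (``Ys``), both in the same trait units
(e.g., mg per plant of shoot dry weight). Replicate-level data and the
underlying experimental design are aggregated upstream; this package works
on genotype-level means only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["TrialTable"]


@dataclass(frozen=True)
class TrialTable:
    """Genotype labels with paired (Yp, Ys) yields.

    Parameters
    ----------
    genotypes
        Ordered genotype labels; whitespace-trimmed, must be unique.
    yp
        Yield under non-stressed (control/potential) conditions, strictly
        positive (ratio indices divide by the genotype's Yp).
    ys
        Yield under stressed conditions, non-negative.
    trait_name, units
        Free-text metadata carried into reports.
    """

    genotypes: tuple[str, ...]
    yp: np.ndarray
    ys: np.ndarray
    trait_name: str = "yield"
    units: str = ""

    def __post_init__(self) -> None:
        labels = tuple(str(g).strip() for g in self.genotypes)
        yp = np.asarray(self.yp, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if yp.ndim != 1 or ys.ndim != 1:
            raise ValidationError("yp and ys must be one-dimensional")
        if not (len(labels) == yp.size == ys.size):
            raise ValidationError(
                f"length mismatch: {len(labels)} genotypes, "
                f"{yp.size} Yp values, {ys.size} Ys values"
            )
        if len(labels) < 1:
            raise ValidationError("trial table must contain at least one genotype")
        counts: dict[str, int] = {}
        for g in labels:
            counts[g] = counts.get(g, 0) + 1
        dupes = sorted(g for g, c in counts.items() if c > 1)
        if dupes:
            raise ValidationError(f"duplicate genotype labels: {dupes}")
        if not np.all(np.isfinite(yp)) or not np.all(np.isfinite(ys)):
            raise ValidationError("yields must be finite")
        if np.any(yp <= 0):
            bad = [labels[i] for i in np.nonzero(yp <= 0)[0]]
            raise ValidationError(
                f"Yp must be strictly positive (ratio indices divide by Yp); offending genotypes: {bad}"
            )
        if np.any(ys < 0):
            bad = [labels[i] for i in np.nonzero(ys < 0)[0]]
            raise ValidationError(f"Ys must be non-negative; offending genotypes: {bad}")
        yp.setflags(write=False)
        ys.setflags(write=False)
        object.__setattr__(self, "genotypes", labels)
        object.__setattr__(self, "yp", yp)
        object.__setattr__(self, "ys", ys)

    @property
    def n(self) -> int:
        """Number of genotypes."""
        return len(self.genotypes)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame indexed by genotype."""
        return pd.DataFrame(
            {"Yp": self.yp, "Ys": self.ys},
            index=pd.Index(self.genotypes, name="Genotype"),
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        trait_name: str = "yield",
        units: str = "",
    ) -> "TrialTable":
        """Build a table from a DataFrame with Yp/Ys columns and genotype index."""
        return cls(
            genotypes=tuple(str(g) for g in frame.index),
            yp=frame["Yp"].to_numpy(dtype=float),
            ys=frame["Ys"].to_numpy(dtype=float),
            trait_name=trait_name,
            units=units,
        )
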