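"""Relative-frequency distributions with per-class genotype membership.

Each yield column and index is summarised as an equal-width histogram over
[min, max]; besides counts and relative frequencies, each class carries the
list of genotypes falling in it, so a breeder can read off *which* entries
populate, say, the top yield class. The default number of classes follows
Sturges' rule, ⌈log2(n) + 1⌉.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .indices import IndexTable

__all__ = ["FrequencyDistribution", "frequency_distribution", "all_frequency_distributions"]


@dataclass(frozen=True)
class FrequencyDistribution:
    """Histogram of one variable with class membership lists.

    Bins are half-open ``[lo, hi)`` except the last, which is closed so the
    maximum belongs to the top class. ``members[k]`` lists the genotypes in
    bin k in input order; every genotype with a defined value appears in
    exactly one bin and relative frequencies sum to 1.
    """

    variable: str
    edges: np.ndarray
    counts: np.ndarray
    relative: np.ndarray
    members: tuple[tuple[str, ...], ...]
    n: int  # number of defined values the frequencies refer to

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def intervals(self) -> list[str]:
        """Human-readable class labels like ``'[51, 65)'``."""
        out = []
        for k in range(self.n_bins):
            close = "]" if k == self.n_bins - 1 else ")"
            out.append(f"[{self.edges[k]:g}, {self.edges[k + 1]:g}{close}")
        return out


def frequency_distribution(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[str],
    n_bins: int | None = None,
    variable: str = "value",
) -> FrequencyDistribution:
    """Equal-width relative-frequency distribution of one variable.

    Undefined (NaN/inf) values are excluded with a warning and frequencies
    renormalised over the defined ones. A constant vector collapses to a
    single class of relative frequency 1.
    """
    values = np.asarray(values, dtype=float)
    labels = [str(x) for x in labels]
    if values.ndim != 1 or len(labels) != values.size:
        raise ValidationError("values and labels must be 1-D and of equal length")
    defined = np.isfinite(values)
    if not np.all(defined):
        dropped = [labels[i] for i in np.nonzero(~defined)[0]]
        warnings.warn(
            f"{variable}: undefined values excluded from the distribution: {dropped}",
            stacklevel=2,
        )
    vals = values[defined]
    labs = [l for l, d in zip(labels, defined) if d]
    m = vals.size
    if m < 2:
        raise ValidationError(f"{variable}: need at least 2 defined values, got {m}")

    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        return FrequencyDistribution(
            variable=variable,
            edges=np.array([vmin, vmax]),
            counts=np.array([m]),
            relative=np.array([1.0]),
            members=(tuple(labs),),
            n=m,
        )

    if n_bins is None:
        n_bins = math.ceil(math.log2(m) + 1)  # Sturges
    if n_bins < 1:
        raise ValidationError("n_bins must be a positive integer")
    edges = np.linspace(vmin, vmax, n_bins + 1)
    # [lo, hi) everywhere, last bin closed at the maximum
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    members = tuple(
        tuple(labs[i] for i in range(m) if idx[i] == k) for k in range(n_bins)
    )
    return FrequencyDistribution(
        variable=variable,
        edges=edges,
        counts=counts,
        relative=counts / m,
        members=members,
        n=m,
    )


def all_frequency_distributions(
    index_table: IndexTable, n_bins: int | None = None
) -> list[FrequencyDistribution]:
    """One distribution per column of the index table (yields, RC, indices).

    Columns undefined for every genotype are skipped with a warning.
    """
    out: list[FrequencyDistribution] = []
    labels = list(index_table.frame.index)
    for col in index_table.frame.columns:
        values = index_table.frame[col].to_numpy(dtype=float)
        if np.isfinite(values).sum() < 2:
            warnings.warn(f"{col}: too few defined values, distribution skipped", stacklevel=2)
            continue
        out.append(frequency_distribution(values, labels, n_bins=n_bins, variable=col))
    return out
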