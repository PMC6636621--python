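"""Principal component analysis of the yield/index matrix.

PCA is run on the 11-variable matrix (Yp, Ys and the nine indices; RC is
excluded, mirroring the ranking set) by eigendecomposition of its
correlation matrix (default) or covariance matrix. Correlation mode
standardises each column to zero mean and unit sample SD (n−1 denominator)
before decomposition, which makes the analysis invariant to per-variable
affine rescaling; scores are the projections of the standardised data onto
the eigenvectors, so the sample variance of score column k equals the k-th
eigenvalue exactly.

Because YSI and RSI are exactly collinear (RSI is a positive scalar
multiple of YSI), the correlation matrix of the full variable set is always
singular: at least one zero eigenvalue is expected and legitimate.

Eigenvector signs are solver-dependent in general; here each eigenvector is
flipped, if needed, so that its largest-magnitude entry is positive, making
results reproducible across platforms. Loadings are eigenvectors scaled by
√eigenvalue (i.e., correlations of variables with components in correlation
mode); contributions are squared eigenvector entries as percentages, which
sum to 100% per component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indices import IndexTable
from .trial import TrialTable

__all__ = ["PCAResult", "BiplotSpec", "run_pca", "pca_from_matrix", "biplot_data"]


@dataclass(frozen=True)
class PCAResult:
    """Full eigenstructure of the analysed matrix.

    All tabular fields are DataFrames: ``descriptives`` (variables × min/
    max/mean/SD), ``matrix`` (the correlation or covariance matrix that was
    decomposed), ``eigenvectors``/``loadings``/``contributions``
    (variables × components) and ``scores`` (observations × components).
    ``eigenvalues`` are in descending order; in correlation mode they sum
    to the number of variables.
    """

    variables: tuple[str, ...]
    mode: Literal["correlation", "covariance"]
    descriptives: pd.DataFrame
    matrix: pd.DataFrame
    eigenvalues: np.ndarray
    explained: np.ndarray
    cumulative: np.ndarray
    eigenvectors: pd.DataFrame
    loadings: pd.DataFrame
    contributions: pd.DataFrame
    scores: pd.DataFrame

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca_from_matrix(
    data: np.ndarray | pd.DataFrame,
    variables: Sequence[str] | None = None,
    mode: Literal["correlation", "covariance"] = "correlation",
    observations: Sequence[str] | None = None,
) -> PCAResult:
    """PCA of an arbitrary observations × variables matrix.

    This is the computational core used by :func:`run_pca`; it is exposed
    so that smaller or synthetic matrices can be analysed with the same
    conventions. Constant columns are dropped with a warning (they carry no
    variance and make the correlation undefined); rows with undefined
    entries are dropped with a warning rather than imputed.
    """
    if mode not in ("correlation", "covariance"):
        raise ValueError(f"unknown PCA mode: {mode!r}")
    if isinstance(data, pd.DataFrame):
        variables = variables or list(data.columns)
        observations = observations or list(data.index)
        data = data.to_numpy(dtype=float)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValidationError("PCA input must be a 2-D matrix")
    n, p = X.shape
    variables = list(variables) if variables is not None else [f"V{i+1}" for i in range(p)]
    observations = (
        list(observations) if observations is not None else [f"obs{i+1}" for i in range(n)]
    )

    row_ok = np.all(np.isfinite(X), axis=1)
    if not np.all(row_ok):
        dropped = [observations[i] for i in np.nonzero(~row_ok)[0]]
        warnings.warn(f"rows with undefined values dropped from PCA: {dropped}", stacklevel=2)
        X = X[row_ok]
        observations = [o for o, ok in zip(observations, row_ok) if ok]
        n = X.shape[0]
    if n < 3:
        raise ValidationError(f"PCA needs at least 3 complete observations, got {n}")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        dropped_vars = [variables[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"constant variables dropped from PCA: {dropped_vars}", stacklevel=2)
        X = X[:, keep]
        variables = [v for v, k in zip(variables, keep) if k]
        sd = sd[keep]
        p = X.shape[1]

    mean = X.mean(axis=0)
    descriptives = pd.DataFrame(
        {"min": X.min(axis=0), "max": X.max(axis=0), "mean": mean, "SD": sd},
        index=pd.Index(variables, name="Variable"),
    )

    centered = X - mean
    if mode == "correlation":
        Z = centered / sd
    else:
        Z = centered
    M = (Z.T @ Z) / (n - 1)  # correlation or covariance matrix, exactly

    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # numerical noise can push zero eigenvalues slightly negative
    eigvals = np.where(eigvals < 0, 0.0, eigvals)
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for k in range(p):
        lead = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[lead, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]

    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)
    loadings = eigvecs * np.sqrt(eigvals)
    contributions = 100.0 * eigvecs**2
    scores = Z @ eigvecs

    pcs = [f"PC{k+1}" for k in range(p)]
    var_idx = pd.Index(variables, name="Variable")
    return PCAResult(
        variables=tuple(variables),
        mode=mode,
        descriptives=descriptives,
        matrix=pd.DataFrame(M, index=var_idx, columns=variables),
        eigenvalues=eigvals,
        explained=explained,
        cumulative=np.cumsum(explained),
        eigenvectors=pd.DataFrame(eigvecs, index=var_idx, columns=pcs),
        loadings=pd.DataFrame(loadings, index=var_idx, columns=pcs),
        contributions=pd.DataFrame(contributions, index=var_idx, columns=pcs),
        scores=pd.DataFrame(scores, index=pd.Index(observations, name="Genotype"), columns=pcs),
    )


def run_pca(
    index_table: IndexTable,
    trial: TrialTable | None = None,
    mode: Literal["correlation", "covariance"] = "correlation",
) -> PCAResult:
    """PCA of the 11 ranked variables (Yp, Ys + nine indices) of a trial."""
    if trial is not None and tuple(index_table.frame.index) != trial.genotypes:
        raise ValueError("index table and trial table are not aligned on genotypes")
    return pca_from_matrix(index_table.ranked_values(), mode=mode)


@dataclass(frozen=True)
class BiplotSpec:
    """Scores and loading vectors on a chosen pair of components.

    ``points`` are genotype scores, ``arrows`` variable loadings
    (eigenvector·√eigenvalue) on the two components. ``arrow_scale`` is the
    factor that, applied to the arrows, makes the two layers co-visible; it
    is recorded rather than silently baked in.
    """

    component_pair: tuple[int, int]
    points: pd.DataFrame
    arrows: pd.DataFrame
    arrow_scale: float
    x_label: str
    y_label: str


def biplot_data(pca: PCAResult, component_pair: tuple[int, int] = (1, 2)) -> BiplotSpec:
    """Biplot data on any ordered pair of principal components (1-based)."""
    j, k = component_pair
    if not (1 <= j < k <= pca.n_components):
        raise ValueError(
            f"component pair must satisfy 1 <= j < k <= {pca.n_components}, got {component_pair}"
        )
    cj, ck = f"PC{j}", f"PC{k}"
    points = pca.scores[[cj, ck]].copy()
    arrows = pca.loadings[[cj, ck]].copy()
    max_score = float(np.abs(points.to_numpy()).max(initial=0.0))
    max_load = float(np.abs(arrows.to_numpy()).max(initial=0.0))
    arrow_scale = max_score / max_load if max_load > 0 and max_score > 0 else 1.0
    return BiplotSpec(
        component_pair=(j, k),
        points=points,
        arrows=arrows,
        arrow_scale=arrow_scale,
        x_label=f"PC{j} ({100 * pca.explained[j - 1]:.2f}%)",
        y_label=f"PC{k} ({100 * pca.explained[k - 1]:.2f}%)",
    )
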