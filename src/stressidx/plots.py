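"""Static figure rendering: heat maps, histograms, biplot, 3D plot.

All functions take the plot *specifications* produced by the analysis
modules and write an image file, keeping rendering strictly separate from
computation. Layouts are deterministic: identical inputs give identical
figures.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .association import HeatmapSpec
from .distribution import FrequencyDistribution
from .grouping import ThreeDSpec
from .multivariate import BiplotSpec

__all__ = ["plot_heatmap", "plot_histogram", "plot_biplot", "plot_threed"]

GROUP_COLORS = {"A": "#1b9e77", "B": "#d95f02", "C": "#7570b3", "D": "#e7298a"}


def plot_heatmap(spec: HeatmapSpec, path: str | os.PathLike) -> Path:
    """Render an association heat map in square, circle or mixed style."""
    path = Path(path)
    k = len(spec.variables)
    values = spec.values.to_numpy(dtype=float)
    annot = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            v = values[i, j]
            annot[i, j] = "" if not np.isfinite(v) else f"{v:.2f}{spec.stars.iat[i, j]}"

    fig, ax = plt.subplots(figsize=(0.75 * k + 2, 0.75 * k + 1.5))
    if spec.style == "square":
        sns.heatmap(
            spec.values, annot=annot, fmt="", cmap="RdBu_r", vmin=spec.vmin,
            vmax=spec.vmax, center=spec.center, square=True, ax=ax,
            cbar_kws={"label": "correlation"},
        )
    else:
        # circle / mixed: glyph size encodes |r|, colour encodes sign+size
        cmap = plt.get_cmap("RdBu_r")
        ax.set_xlim(-0.5, k - 0.5)
        ax.set_ylim(k - 0.5, -0.5)
        ax.set_aspect("equal")
        for i in range(k):
            for j in range(k):
                v = values[i, j]
                if not np.isfinite(v):
                    continue
                numeric_cell = spec.style == "mixed" and i > j
                if numeric_cell or i == j:
                    ax.text(j, i, annot[i, j], ha="center", va="center", fontsize=8)
                else:
                    ax.scatter(
                        j, i, s=900 * abs(v), c=[cmap((v + 1) / 2)],
                        edgecolors="grey", linewidths=0.4,
                    )
        ax.set_xticks(range(k), spec.variables, rotation=90)
        ax.set_yticks(range(k), spec.variables)
        sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(-1, 1))
        fig.colorbar(sm, ax=ax, label="correlation")
    ax.set_title(spec.method)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_histogram(fd: FrequencyDistribution, path: str | os.PathLike) -> Path:
    """Relative-frequency histogram of one variable."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    if fd.n_bins == 1:
        ax.bar([0], fd.relative, width=0.6)
        ax.set_xticks([0], [f"{fd.edges[0]:g}"])
    else:
        widths = np.diff(fd.edges)
        ax.bar(fd.edges[:-1], fd.relative, width=widths, align="edge",
               edgecolor="white", linewidth=0.6)
    ax.set_xlabel(fd.variable)
    ax.set_ylabel("relative frequency")
    ax.set_title(f"Distribution of {fd.variable} (n = {fd.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_biplot(spec: BiplotSpec, path: str | os.PathLike) -> Path:
    """PCA biplot: genotype scores as points, variable loadings as arrows."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 6))
    pts = spec.points.to_numpy(dtype=float)
    ax.scatter(pts[:, 0], pts[:, 1], s=18, color="#444444", zorder=3)
    for label, (x, y) in zip(spec.points.index, pts):
        ax.annotate(str(label), (x, y), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    arrows = spec.arrows.to_numpy(dtype=float) * spec.arrow_scale
    for var, (dx, dy) in zip(spec.arrows.index, arrows):
        ax.annotate("", xy=(dx, dy), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="#b2182b", lw=1.2))
        ax.annotate(str(var), (dx, dy), color="#b2182b", fontsize=9,
                    xytext=(4, 4), textcoords="offset points")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    ax.set_title(f"PCA biplot (PC{spec.component_pair[0]} vs PC{spec.component_pair[1]})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_threed(spec: ThreeDSpec, path: str | os.PathLike) -> Path:
    """3D scatter of (Yp, Ys, index) coloured by Fernandez group."""
    path = Path(path)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for group in "ABCD":
        sel = [i for i, g in enumerate(spec.groups) if g == group]
        if not sel:
            continue
        ax.scatter(
            spec.x[sel], spec.y[sel], spec.z[sel],
            color=GROUP_COLORS[group], label=f"Group {group}", s=30,
        )
    for i, label in enumerate(spec.labels):
        ax.text(spec.x[i], spec.y[i], spec.z[i], label, fontsize=6)
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    ax.set_zlabel(spec.index_id)
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(f"{spec.index_id} over yield performance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
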