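"""End-to-end pipeline: read → indices → ranks → frequencies →
correlations → PCA → groups → report (+ optional figures).

The pipeline is the library composed in the canonical order, with a small
validated configuration object. It is fully deterministic: the analysis
path contains no randomness, so identical configuration and input produce
byte-identical numeric output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import plots
from .association import heatmap_data, pearson_matrix, spearman_matrix
from .distribution import all_frequency_distributions
from .grouping import assign_groups, threed_plot_data
from .indices import INDEX_IDS, compute_indices
from .io import ReportBundle, read_trial_table, write_report
from .multivariate import biplot_data, run_pca
from .ranking import rank_all
from .trial import TrialTable

__all__ = ["RunConfig", "Manifest", "run_pipeline"]

logger = logging.getLogger(__name__)

SKIPPABLE_STAGES = ("frequencies", "correlations", "pca", "groups", "plots")
VALID_FORMATS = ("workbook", "csv", "png")
HEATMAP_STYLES = ("square", "circle", "mixed")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input: str | Path
    sheet: str | int | None = None
    columns: Mapping[str, str] | None = None
    out: str | Path = "results"
    formats: Sequence[str] = ("workbook",)
    bins: int | None = None
    pca_mode: str = "correlation"
    biplot_pair: tuple[int, int] = (1, 2)
    index3d: str = "STI"
    heatmap_style: str = "square"
    skip: Sequence[str] = ()
    precision: int = 2
    asr_columns: int = 11
    log_level: str = "INFO"

    def validate(self) -> None:
        bad = set(self.formats) - set(VALID_FORMATS)
        if bad:
            raise ValueError(f"unknown formats {sorted(bad)}; valid: {VALID_FORMATS}")
        if not self.formats:
            raise ValueError("at least one output format is required")
        bad = set(self.skip) - set(SKIPPABLE_STAGES)
        if bad:
            raise ValueError(f"unknown skip stages {sorted(bad)}; valid: {SKIPPABLE_STAGES}")
        if self.pca_mode not in ("correlation", "covariance"):
            raise ValueError("pca_mode must be 'correlation' or 'covariance'")
        if self.heatmap_style not in HEATMAP_STYLES:
            raise ValueError(f"heatmap_style must be one of {HEATMAP_STYLES}")
        if self.index3d not in INDEX_IDS:
            raise ValueError(f"index3d must be one of {INDEX_IDS}")
        if self.asr_columns not in (9, 11):
            raise ValueError("asr_columns must be 9 or 11")
        if self.bins is not None and self.bins < 1:
            raise ValueError("bins must be a positive integer")
        j, k = self.biplot_pair
        if not (1 <= j < k):
            raise ValueError("biplot pair must be two increasing 1-based component indices")
        if self.precision < 0:
            raise ValueError("precision must be non-negative")


@dataclass
class Manifest:
    """What a pipeline run produced."""

    files: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig, trial: TrialTable | None = None) -> Manifest:
    """Run the full analysis described by ``config``.

    ``trial`` may be passed directly (bypassing file input) for
    programmatic use; otherwise ``config.input`` is read. Stages listed in
    ``config.skip`` are omitted, and stages whose inputs are degenerate
    degrade gracefully with warnings rather than aborting the run.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    manifest = Manifest()
    out_dir = Path(config.out)
    skip = set(config.skip)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if trial is None:
            trial = read_trial_table(config.input, sheet=config.sheet, columns=config.columns)
        logger.info("read %d genotypes from %s", trial.n, config.input)

        index_table = compute_indices(trial)
        ranks = rank_all(index_table, trial, asr_columns=config.asr_columns)

        bundle = ReportBundle(indices=index_table, trial=trial, ranks=ranks)

        if "frequencies" not in skip:
            bundle.frequencies = all_frequency_distributions(index_table, n_bins=config.bins)
        else:
            manifest.skipped.append("frequencies")

        if "correlations" not in skip:
            bundle.pearson = pearson_matrix(index_table, trial)
            bundle.spearman = spearman_matrix(ranks)
        else:
            manifest.skipped.append("correlations")

        if "pca" not in skip:
            try:
                bundle.pca = run_pca(index_table, trial, mode=config.pca_mode)
            except Exception as exc:  # degenerate input: report still useful without PCA
                warnings.warn(f"PCA stage failed and was skipped: {exc}")
        else:
            manifest.skipped.append("pca")

        if "groups" not in skip:
            bundle.groups = assign_groups(trial)
        else:
            manifest.skipped.append("groups")

        table_formats = [f for f in config.formats if f in ("workbook", "csv")] or ["workbook"]
        manifest.files.extend(
            write_report(bundle, out_dir, formats=table_formats, precision=config.precision)
        )

        if "png" in config.formats and "plots" not in skip:
            if bundle.pearson is not None:
                spec = heatmap_data(bundle.pearson, style=config.heatmap_style)
                manifest.files.append(
                    plots.plot_heatmap(spec, out_dir / "heatmap_pearson.png")
                )
            if bundle.spearman is not None:
                spec = heatmap_data(bundle.spearman, style=config.heatmap_style)
                manifest.files.append(
                    plots.plot_heatmap(spec, out_dir / "heatmap_spearman.png")
                )
            for fd in bundle.frequencies:
                manifest.files.append(
                    plots.plot_histogram(fd, out_dir / f"frequency_{fd.variable.lower()}.png")
                )
            if bundle.pca is not None:
                pair = config.biplot_pair
                if pair[1] <= bundle.pca.n_components:
                    manifest.files.append(
                        plots.plot_biplot(
                            biplot_data(bundle.pca, pair),
                            out_dir / f"biplot_pc{pair[0]}_pc{pair[1]}.png",
                        )
                    )
                else:
                    warnings.warn(
                        f"biplot pair {pair} exceeds {bundle.pca.n_components} components; skipped"
                    )
            if bundle.groups is not None:
                manifest.files.append(
                    plots.plot_threed(
                        threed_plot_data(trial, index_table, config.index3d),
                        out_dir / f"plot3d_{config.index3d.lower()}.png",
                    )
                )
        elif "plots" in skip:
            manifest.skipped.append("plots")

    for w in caught:
        logger.warning("%s", w.message)
        manifest.warnings.append(str(w.message))
    logger.info("wrote %d files to %s", len(manifest.files), out_dir)
    return manifest
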