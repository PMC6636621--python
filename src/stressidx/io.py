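"""Reading trial tables and writing the multi-sheet results report.

Input is a spreadsheet (xlsx) or CSV with one row per genotype: a label
column and two numeric yield columns (Yp then Ys). Columns are resolved by
name when a mapping is given, otherwise the first text column is taken as
the labels and the next two fully numeric columns as Yp and Ys, matching
the simple template such tools expect. Parsing uses the dot decimal
separator regardless of locale.

Output is a single workbook (and/or one CSV per sheet) with fixed sheet
names: Indices, Ranks, Frequencies, Correlations, the PCA sheets
(Descriptives, Matrix, Eigenvalues, Eigenvectors, Loadings, Contributions,
Scores) and Groups. Numeric cells are written at full double precision;
the configurable display precision only sets the Excel number format, so
values round-trip exactly.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .distribution import FrequencyDistribution
from .errors import ParseError, SchemaError, ValidationError
from .grouping import GROUP_DESCRIPTIONS, GroupAssignment
from .indices import IndexTable
from .multivariate import PCAResult
from .ranking import RankTable
from .trial import TrialTable

__all__ = ["read_trial_table", "write_report", "ReportBundle"]

logger = logging.getLogger(__name__)

PCA_SHEETS = (
    "PCA Descriptives",
    "PCA Matrix",
    "PCA Eigenvalues",
    "PCA Eigenvectors",
    "PCA Loadings",
    "PCA Contributions",
    "PCA Scores",
)


def _read_raw(path: Path, sheet: str | int | None) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, sheet_name=0 if sheet is None else sheet, dtype=object)
    return pd.read_csv(path, dtype=object, skipinitialspace=True)


def _is_numeric(col: pd.Series) -> bool:
    # mostly-numeric columns count as yield candidates, so that a stray
    # non-numeric cell surfaces as a ParseError with its row, not as a
    # schema-resolution failure
    stripped = col.astype(str).str.strip()
    converted = pd.to_numeric(stripped, errors="coerce")
    return len(col) > 0 and bool(converted.notna().mean() >= 0.5)


def _resolve_columns(
    raw: pd.DataFrame, columns: Mapping[str, str] | None
) -> tuple[str, str, str]:
    names = list(raw.columns)
    if columns:
        unknown_keys = set(columns) - {"label", "yp", "ys"}
        if unknown_keys:
            raise SchemaError(
                f"unknown column-mapping keys {sorted(unknown_keys)}; use 'label', 'yp', 'ys'"
            )
        try:
            label, yp, ys = columns["label"], columns["yp"], columns["ys"]
        except KeyError as exc:
            raise SchemaError(
                f"column mapping must name 'label', 'yp' and 'ys'; missing {exc}"
            ) from exc
        missing = [c for c in (label, yp, ys) if c not in names]
        if missing:
            raise SchemaError(f"mapped columns {missing} not found; available: {names}")
        return label, yp, ys
    text_cols = [c for c in names if not _is_numeric(raw[c])]
    numeric_cols = [c for c in names if _is_numeric(raw[c])]
    if not text_cols:
        raise SchemaError(
            f"no text column found for genotype labels; available columns: {names} "
            "(pass an explicit column mapping)"
        )
    label = text_cols[0]
    numeric_after = [c for c in names if c in numeric_cols and names.index(c) > names.index(label)]
    if len(numeric_after) < 2:
        numeric_after = numeric_cols
    if len(numeric_after) < 2:
        raise SchemaError(
            f"need two numeric yield columns (Yp, Ys); numeric candidates: {numeric_cols} "
            f"out of {names}"
        )
    return label, numeric_after[0], numeric_after[1]


def read_trial_table(
    path: str | os.PathLike,
    sheet: str | int | None = None,
    columns: Mapping[str, str] | None = None,
    trait_name: str = "yield",
    units: str = "",
) -> TrialTable:
    """Read and validate a two-environment trial table from xlsx or CSV.

    Parameters
    ----------
    path
        Spreadsheet (.xlsx) or CSV file; for spreadsheets ``sheet`` selects
        a sheet by name or position (first sheet by default).
    columns
        Optional explicit mapping ``{"label": ..., "yp": ..., "ys": ...}``
        of header names; without it the first text column holds the labels
        and the next two numeric columns Yp and Ys, in that order.

    Raises
    ------
    SchemaError
        Columns missing or ambiguous (message names the candidates).
    ParseError
        A yield cell is not numeric (message gives the row).
    ValidationError
        Fewer than 2 rows, duplicate labels, or non-positive Yp.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_raw(path, sheet)
    raw.columns = [str(c).strip() for c in raw.columns]
    raw = raw.dropna(how="all")
    label_col, yp_col, ys_col = _resolve_columns(raw, columns)

    labels = raw[label_col].astype(str).str.strip()
    yields = {}
    for name, col in (("Yp", yp_col), ("Ys", ys_col)):
        cells = list(raw[col].astype(str).str.strip())
        # Python's float() is correctly rounded; pandas' fast parser can be
        # off by one ulp, which would break full-precision round-trips
        values = np.empty(len(cells))
        bad_rows = []
        for i, cell in enumerate(cells):
            try:
                values[i] = float(cell)
            except ValueError:
                values[i] = np.nan
                bad_rows.append(i + 1)
            else:
                if not np.isfinite(values[i]):
                    bad_rows.append(i + 1)
        if bad_rows:
            raise ParseError(
                f"non-numeric {name} value in column {col!r} at data row(s) {bad_rows[:5]}"
            )
        yields[name] = values

    if len(raw) < 2:
        raise ValidationError(f"trial table needs at least 2 genotypes, got {len(raw)}")
    return TrialTable(
        genotypes=tuple(labels),
        yp=yields["Yp"],
        ys=yields["Ys"],
        trait_name=trait_name,
        units=units,
    )


@dataclass
class ReportBundle:
    """Everything the report writer can lay out; only ``indices`` is required."""

    indices: IndexTable
    trial: TrialTable | None = None
    ranks: RankTable | None = None
    frequencies: Sequence[FrequencyDistribution] = field(default_factory=tuple)
    pearson: AssociationMatrix | None = None
    spearman: AssociationMatrix | None = None
    pca: PCAResult | None = None
    groups: GroupAssignment | None = None


def _indices_sheet(bundle: ReportBundle) -> pd.DataFrame:
    frame = bundle.indices.frame.reset_index()
    means = bundle.indices.means
    footer = pd.DataFrame(
        {
            "Genotype": ["", "Mean Yp (non-stressed)", "Mean Ys (stressed)"],
            "Yp": [np.nan, means.yp_bar, np.nan],
            "Ys": [np.nan, np.nan, means.ys_bar],
        }
    )
    return pd.concat([frame, footer], ignore_index=True)


def _ranks_sheet(ranks: RankTable) -> pd.DataFrame:
    out = ranks.ranks.copy()
    out["Sum"] = ranks.rank_sum
    out["ASR"] = ranks.asr
    out["SD"] = ranks.rank_sd
    return out.reset_index()


def _frequencies_sheet(freqs: Sequence[FrequencyDistribution]) -> pd.DataFrame:
    blocks = []
    for fd in freqs:
        blocks.append(
            pd.DataFrame(
                {
                    "Variable": [fd.variable] * fd.n_bins,
                    "Class": fd.intervals(),
                    "Lower edge": fd.edges[:-1],
                    "Upper edge": fd.edges[1:],
                    "Count": fd.counts,
                    "Relative frequency": fd.relative,
                    "Genotypes": [", ".join(m) for m in fd.members],
                }
            )
        )
        blocks.append(pd.DataFrame({"Variable": [""]}))
    return pd.concat(blocks[:-1], ignore_index=True) if blocks else pd.DataFrame()


def _correlations_sheet(
    pearson: AssociationMatrix | None, spearman: AssociationMatrix | None
) -> pd.DataFrame:
    blocks = []
    for title, mat in (
        ("Pearson correlation (values)", pearson),
        ("Spearman rank-order correlation (direction-aware ranks)", spearman),
    ):
        if mat is None:
            continue
        for sub, what in ((mat.r, "coefficients"), (mat.p, "two-sided p-values")):
            head = pd.DataFrame({"Matrix": [f"{title} — {what}"]})
            body = sub.reset_index().rename(columns={"index": "Variable"})
            body.insert(0, "Matrix", "")
            blocks.extend([head, body, pd.DataFrame({"Matrix": [""]})])
    return pd.concat(blocks[:-1], ignore_index=True) if blocks else pd.DataFrame()


def _eigenvalues_sheet(pca: PCAResult) -> pd.DataFrame:
    pcs = [f"PC{k+1}" for k in range(pca.n_components)]
    return pd.DataFrame(
        {
            "Component": pcs,
            "Eigenvalue": pca.eigenvalues,
            "Explained variance (%)": 100 * pca.explained,
            "Cumulative (%)": 100 * pca.cumulative,
        }
    )


def _groups_sheet(groups: GroupAssignment, indices: IndexTable) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "Genotype": list(groups.groups.index),
            "Yp": indices.frame["Yp"].to_numpy(),
            "Ys": indices.frame["Ys"].to_numpy(),
            "Group": groups.groups.to_numpy(),
            "Meaning": [GROUP_DESCRIPTIONS[g] for g in groups.groups],
        }
    )
    footer = pd.DataFrame(
        {
            "Genotype": ["", "Yp threshold (mean)", "Ys threshold (mean)"],
            "Yp": [np.nan, groups.yp_threshold, np.nan],
            "Ys": [np.nan, np.nan, groups.ys_threshold],
        }
    )
    return pd.concat([frame, footer], ignore_index=True)


def _sheets(bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    sheets: dict[str, pd.DataFrame] = {"Indices": _indices_sheet(bundle)}
    if bundle.ranks is not None:
        sheets["Ranks"] = _ranks_sheet(bundle.ranks)
    if bundle.frequencies:
        sheets["Frequencies"] = _frequencies_sheet(bundle.frequencies)
    if bundle.pearson is not None or bundle.spearman is not None:
        sheets["Correlations"] = _correlations_sheet(bundle.pearson, bundle.spearman)
    if bundle.pca is not None:
        pca = bundle.pca
        sheets["PCA Descriptives"] = pca.descriptives.reset_index()
        sheets["PCA Matrix"] = pca.matrix.reset_index()
        sheets["PCA Eigenvalues"] = _eigenvalues_sheet(pca)
        sheets["PCA Eigenvectors"] = pca.eigenvectors.reset_index()
        sheets["PCA Loadings"] = pca.loadings.reset_index()
        sheets["PCA Contributions"] = pca.contributions.reset_index()
        sheets["PCA Scores"] = pca.scores.reset_index()
    else:
        logger.info("PCA results absent; PCA sheets omitted from the report")
    if bundle.groups is not None:
        sheets["Groups"] = _groups_sheet(bundle.groups, bundle.indices)
    return sheets


def _apply_precision(workbook_path: Path, precision: int) -> None:
    from openpyxl import load_workbook

    fmt = "0." + "0" * precision if precision > 0 else "0"
    wb = load_workbook(workbook_path)
    for ws in wb.worksheets:
        for row in ws.iter_rows(min_row=2):
            for cell in row:
                if isinstance(cell.value, float):
                    cell.number_format = fmt
    wb.save(workbook_path)


def write_report(
    bundle: ReportBundle,
    path: str | os.PathLike,
    formats: Iterable[str] = ("workbook",),
    precision: int = 2,
    basename: str = "report",
) -> list[Path]:
    """Write the results bundle to ``path`` (a directory).

    ``formats`` is a subset of ``{"workbook", "csv"}``: the workbook is a
    single ``<basename>.xlsx`` with one sheet per section; csv writes one
    ``<basename>_<sheet>.csv`` per sheet with identical values. The
    workbook is written atomically (temp file + rename), so a failure
    leaves no partial workbook behind. ``precision`` controls the Excel
    display format only; stored values keep full double precision.

    Returns the list of files written.
    """
    formats = set(formats)
    unknown = formats - {"workbook", "csv"}
    if unknown:
        raise ValueError(f"unknown report formats: {sorted(unknown)}")
    if not formats:
        raise ValueError("at least one output format is required")
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = _sheets(bundle)
    written: list[Path] = []

    if "workbook" in formats:
        final = out_dir / f"{basename}.xlsx"
        fd, tmp_name = tempfile.mkstemp(suffix=".xlsx", dir=out_dir)
        os.close(fd)
        tmp = Path(tmp_name)
        try:
            with pd.ExcelWriter(tmp, engine="openpyxl") as writer:
                for name, frame in sheets.items():
                    # Excel sheet names are capped at 31 characters
                    frame.to_excel(writer, sheet_name=name[:31], index=False)
            _apply_precision(tmp, precision)
            os.replace(tmp, final)
        except BaseException:
            tmp.unlink(missing_ok=True)
            raise
        written.append(final)

    if "csv" in formats:
        for name, frame in sheets.items():
            slug = name.lower().replace(" ", "_")
            target = out_dir / f"{basename}_{slug}.csv"
            frame.to_csv(target, index=False)
            written.append(target)
    return written
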