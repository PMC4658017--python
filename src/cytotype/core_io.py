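"""Data model and tabular IO for the pipeline.

The central container is :class:`ExpressionMatrix`, a genes x cells table of
non-negative abundance values (FPKM/TPM scale) together with a per-cell
sample (batch/preparation) label.  All readers and writers use plain TSV so
that every intermediate artifact of a run remains human-inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "MarkerPanel",
    "FormatError",
    "ConsistencyError",
    "read_expression_matrix",
    "write_expression_matrix",
    "apply_expression_floor",
    "read_gene_sets",
    "read_marker_panel",
    "DEFAULT_FLOOR",
]

#: Minimal abundance; every value below it is raised to it so that logs and
#: fold changes are always defined downstream.
DEFAULT_FLOOR = 0.01


class FormatError(ValueError):
    """Malformed input table (duplicates, missing columns, bad values)."""


class ConsistencyError(ValueError):
    """Tables that are individually valid but mutually inconsistent."""


@dataclass
class ExpressionMatrix:
    """Genes x cells abundance matrix with per-cell sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with cell IDs as columns; entries are
        non-negative abundances (FPKM/TPM scale).
    sample_of_cell
        Series mapping each cell ID to its sample/preparation label, in the
        same order as ``values.columns``.
    """

    values: pd.DataFrame
    sample_of_cell: pd.Series = field(repr=False)
    #: transformed matrices (e.g. z-scores) may carry negative entries
    signed: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene IDs: {dup[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].tolist()
            raise FormatError(f"duplicate cell IDs: {dup[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (no NaN/inf)")
        if not self.signed and (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = v.columns.difference(self.sample_of_cell.index)
        if len(missing):
            raise ConsistencyError(
                f"cells missing from metadata: {list(missing)[:5]}"
            )
        # align metadata to column order, dropping extraneous cells
        self.sample_of_cell = self.sample_of_cell.reindex(v.columns)
        if self.sample_of_cell.isna().any():
            raise ConsistencyError("cells with undefined sample label")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> list[str]:
        """Sample labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_of_cell:
            seen.setdefault(s, None)
        return list(seen)

    def cells_in_sample(self, sample: str) -> list[str]:
        mask = self.sample_of_cell == sample
        return list(self.sample_of_cell.index[mask])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[genes], self.sample_of_cell, self.signed
        )

    def subset_cells(self, cells: Iterable[str]) -> "ExpressionMatrix":
        cells = [c for c in cells if c in self.values.columns]
        return ExpressionMatrix(
            self.values[cells], self.sample_of_cell.loc[cells], self.signed
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g., genes associated with a cell type)."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if self.universe is not None and not genes <= self.universe:
                raise ValueError(f"gene set {name!r} not within universe")


@dataclass
class MarkerPanel:
    """Ordered marker gene lists keyed by cell type."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        for ct, genes in self.markers.items():
            if not genes:
                raise ValueError(f"marker list for {ct!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate markers for {ct!r}")


# ---------------------------------------------------------------------------
# readers / writers

def read_expression_matrix(
    matrix_path: str | Path,
    metadata_path: str | Path,
    signed: bool = False,
) -> ExpressionMatrix:
    """Read an expression TSV (genes x cells) plus a cell metadata TSV.

    The matrix file has a header row of cell IDs and gene IDs in the first
    column.  The metadata file must contain columns ``cell_id`` and
    ``sample``; every cell in the matrix must appear exactly once.
    Abundance input must be non-negative; pass ``signed=True`` for
    transformed (e.g. z-scored) matrices.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("cell_id", "sample"):
        if col not in meta.columns:
            raise FormatError(f"metadata is missing column {col!r}")
    if meta["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id rows in metadata")
    sample_of_cell = meta.set_index("cell_id")["sample"]
    return ExpressionMatrix(values, sample_of_cell, signed=signed)


def write_expression_matrix(
    E: ExpressionMatrix,
    matrix_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the matrix (and optionally cell metadata) as TSV."""
    out = E.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {"cell_id": E.cell_ids, "sample": E.sample_of_cell.values}
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


def apply_expression_floor(
    E: ExpressionMatrix, floor: float = DEFAULT_FLOOR
) -> ExpressionMatrix:
    """Raise every abundance below ``floor`` to ``floor``.

    Guarantees strictly positive values so that log transforms and quantile
    ratios downstream are always defined.  Idempotent.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return ExpressionMatrix(E.values.clip(lower=floor), E.sample_of_cell)


def read_gene_sets(
    path: str | Path,
    format: str = "gmt",
    pvalue_max: float = 0.05,
    require_no_negative: bool = True,
) -> GeneSetCollection:
    """Read gene sets from GMT or a gene/cell-type association table.

    For ``association_table`` input (columns ``gene``, ``cell_type``,
    ``support_pvalue``, ``direction``), a gene joins a cell type's set only
    if it has at least one *positive* association with
    ``support_pvalue < pvalue_max`` and -- when ``require_no_negative`` --
    no negative association for that cell type.  Empty sets are dropped.
    """
    if format == "gmt":
        sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = {g for g in parts[2:] if g}
        return GeneSetCollection(sets)
    if format == "association_table":
        tab = pd.read_csv(path, sep="\t")
        required = {"gene", "cell_type", "support_pvalue", "direction"}
        missing = required - set(tab.columns)
        if missing:
            raise FormatError(f"association table missing columns {missing}")
        bad = set(tab["direction"]) - {"positive", "negative"}
        if bad:
            raise FormatError(f"unknown direction values {bad}")
        sets = {}
        for ct, rows in tab.groupby("cell_type"):
            pos = rows[
                (rows["direction"] == "positive")
                & (rows["support_pvalue"] < pvalue_max)
            ]["gene"]
            genes = set(pos)
            if require_no_negative:
                neg = set(rows[rows["direction"] == "negative"]["gene"])
                genes -= neg
            if genes:
                sets[str(ct)] = genes
        return GeneSetCollection(sets)
    raise ValueError(f"unknown gene-set format {format!r}")


def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Read a marker TSV with columns ``cell_type`` and ``gene``."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_type", "gene"):
        if col not in tab.columns:
            raise FormatError(f"marker table missing column {col!r}")
    markers: dict[str, list[str]] = {}
    for ct, rows in tab.groupby("cell_type", sort=False):
        markers[str(ct)] = list(rows["gene"])
    return MarkerPanel(markers)
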