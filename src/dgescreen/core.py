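"""Expression-matrix data model, loaders, and cell-set selection.

The central object is :class:`ExpressionDataset`: a cells x genes matrix of
depth-normalised counts (CPM) together with a per-cell annotation table
(``region_label``, ``subclass_label``, ``class_label``).  All contrast
construction downstream operates on ordered lists of cell ids drawn from
this dataset; selection is purely metadata-driven.

On-disk formats
---------------
dense-delimited
    CSV/TSV, first column the cell id, header row of gene symbols.  The
    delimiter is auto-detected from the header line (tab wins over comma).
matrix-market
    MatrixMarket coordinate file plus two side files with one gene symbol /
    one cell id per line.  Either on-disk orientation is accepted; the
    matrix is transposed to cells x genes if the index lengths say so.

Cell order is the metadata file order; CPM values are accepted as given
and never re-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import IntegrityError, SchemaError

REQUIRED_META_COLUMNS = ("sample_name", "region_label", "subclass_label", "class_label")


def _detect_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


@dataclass
class ExpressionDataset:
    """CPM matrix (cells x genes) plus per-cell metadata.

    Parameters
    ----------
    cpm : ndarray, shape (n_cells, n_genes)
        Non-negative, finite counts-per-million values.
    gene_names : sequence of str
        Unique gene symbols, one per matrix column.
    cell_ids : sequence of str
        Unique cell identifiers, one per matrix row, in metadata order.
    cell_meta : DataFrame
        Indexed by cell id with columns ``region_label``,
        ``subclass_label``, ``class_label`` (all non-empty strings).
    """

    cpm: np.ndarray
    gene_names: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.cpm = np.asarray(self.cpm, dtype=float)
        self.gene_names = pd.Index(self.gene_names)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.cpm.ndim != 2:
            raise IntegrityError("expression matrix must be two-dimensional")
        n_cells, n_genes = self.cpm.shape
        if len(self.cell_ids) != n_cells or len(self.gene_names) != n_genes:
            raise IntegrityError(
                f"matrix shape {self.cpm.shape} does not match index lengths "
                f"({len(self.cell_ids)} cells, {len(self.gene_names)} genes)"
            )
        if self.gene_names.has_duplicates:
            dupes = self.gene_names[self.gene_names.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate gene symbols: {dupes[:10]}")
        if self.cell_ids.has_duplicates:
            dupes = self.cell_ids[self.cell_ids.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate cell ids: {dupes[:10]}")
        if not np.all(np.isfinite(self.cpm)):
            raise IntegrityError("expression matrix contains non-finite values")
        if np.any(self.cpm < 0):
            raise IntegrityError("expression matrix contains negative values")
        missing = [c for c in REQUIRED_META_COLUMNS[1:] if c not in self.cell_meta.columns]
        if missing:
            raise SchemaError(f"cell metadata missing required columns: {missing}")
        self.cell_meta = self.cell_meta.loc[self.cell_ids, list(REQUIRED_META_COLUMNS[1:])]
        for col in REQUIRED_META_COLUMNS[1:]:
            vals = self.cell_meta[col]
            if vals.isna().any() or (vals.astype(str).str.len() == 0).any():
                raise IntegrityError(f"empty or missing values in metadata column {col!r}")

    @property
    def n_cells(self) -> int:
        return self.cpm.shape[0]

    @property
    def n_genes(self) -> int:
        return self.cpm.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = self.gene_names.get_indexer([gene])[0]
        if idx < 0:
            raise KeyError(f"gene {gene!r} not in dataset")
        return int(idx)

    def cell_indices(self, cells: Sequence[str]) -> np.ndarray:
        idx = self.cell_ids.get_indexer(cells)
        if np.any(idx < 0):
            missing = [c for c, i in zip(cells, idx) if i < 0]
            raise IntegrityError(f"cells not in dataset: {missing[:10]}")
        return idx

    def values(self, gene: str, cells: Sequence[str]) -> np.ndarray:
        """CPM values of one gene over the given cells, in the given order."""
        return self.cpm[self.cell_indices(cells), self.gene_index(gene)]


@dataclass(frozen=True)
class CellSelector:
    """Metadata filter: all given criteria are ANDed, exclusions subtracted."""

    regions: frozenset[str] | None = None
    subclasses: frozenset[str] | None = None
    classes: frozenset[str] | None = None
    exclude_subclasses: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name in ("regions", "subclasses", "classes", "exclude_subclasses"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, frozenset(val))
        if not (self.regions or self.subclasses or self.classes):
            raise SchemaError("selector needs at least one of regions/subclasses/classes")
        if self.subclasses and self.exclude_subclasses:
            overlap = self.subclasses & self.exclude_subclasses
            if overlap:
                raise SchemaError(f"subclasses and exclude_subclasses overlap: {sorted(overlap)}")

    def describe(self) -> str:
        parts = []
        for name in ("regions", "subclasses", "classes", "exclude_subclasses"):
            val = getattr(self, name)
            if val:
                parts.append(f"{name}={sorted(val)}")
        return "CellSelector(" + ", ".join(parts) + ")"


@dataclass(frozen=True)
class ContrastSpec:
    """One target-vs-contrast comparison: ordered, disjoint, non-empty id lists."""

    label: str
    target_cells: tuple[str, ...]
    contrast_cells: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_cells", tuple(self.target_cells))
        object.__setattr__(self, "contrast_cells", tuple(self.contrast_cells))
        if not self.target_cells:
            raise IntegrityError(f"contrast {self.label!r}: empty target set")
        if not self.contrast_cells:
            raise IntegrityError(f"contrast {self.label!r}: empty contrast set")
        overlap = set(self.target_cells) & set(self.contrast_cells)
        if overlap:
            raise IntegrityError(
                f"contrast {self.label!r}: target and contrast sets share "
                f"{len(overlap)} cells"
            )

    def validate_against(self, ds: ExpressionDataset) -> None:
        ds.cell_indices(self.target_cells)
        ds.cell_indices(self.contrast_cells)


def _read_meta(meta_path: str | Path) -> pd.DataFrame:
    sep = _detect_sep(meta_path)
    meta = pd.read_csv(meta_path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata file {meta_path}: missing columns {missing}")
    if meta["sample_name"].duplicated().any():
        raise IntegrityError(f"metadata file {meta_path}: duplicate sample_name entries")
    return meta.set_index("sample_name", drop=False)


def load_expression(
    matrix_path: str | Path,
    meta_path: str | Path,
    format: str = "dense-delimited",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionDataset:
    """Load a CPM matrix and its cell metadata into an :class:`ExpressionDataset`.

    ``format`` is ``"dense-delimited"`` or ``"matrix-market"``; the latter
    requires ``genes_path`` and ``cells_path`` index files.  Cells present
    in the matrix but absent from the metadata raise
    :class:`~dgescreen.errors.IntegrityError`.  Cell order follows the
    metadata file.
    """
    meta = _read_meta(meta_path)

    if format == "dense-delimited":
        sep = _detect_sep(matrix_path)
        frame = pd.read_csv(matrix_path, sep=sep, index_col=0)
        cell_ids = frame.index.astype(str)
        gene_names = frame.columns.astype(str)
        matrix = frame.to_numpy(dtype=float)
    elif format == "matrix-market":
        if genes_path is None or cells_path is None:
            raise SchemaError("matrix-market format requires genes_path and cells_path")
        gene_names = pd.Index(_read_lines(genes_path))
        cell_ids = pd.Index(_read_lines(cells_path))
        mat = scipy.io.mmread(str(matrix_path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if mat.shape == (len(cell_ids), len(gene_names)):
            matrix = mat
        elif mat.shape == (len(gene_names), len(cell_ids)):
            matrix = mat.T
        else:
            raise IntegrityError(
                f"matrix shape {mat.shape} matches neither (cells, genes)="
                f"({len(cell_ids)}, {len(gene_names)}) nor its transpose"
            )
    else:
        raise SchemaError(f"unknown matrix format {format!r}")

    unknown = cell_ids.difference(meta.index)
    if len(unknown):
        raise IntegrityError(
            f"{len(unknown)} matrix cells absent from metadata, e.g. {list(unknown[:5])}"
        )
    # Metadata order is authoritative; restrict to cells in the matrix.
    ordered = meta.index[meta.index.isin(set(cell_ids))]
    pos = pd.Index(cell_ids).get_indexer(ordered)
    return ExpressionDataset(
        cpm=matrix[pos],
        gene_names=gene_names,
        cell_ids=ordered,
        cell_meta=meta.loc[ordered],
    )


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_dense(ds: ExpressionDataset, matrix_path: str | Path, sep: str = ",") -> None:
    """Write the matrix as delimited text (cell id column + gene header).

    Values are written with repr-level precision so a dense round-trip is
    value-identical.
    """
    frame = pd.DataFrame(ds.cpm, index=ds.cell_ids, columns=ds.gene_names)
    frame.index.name = "sample_name"
    frame.to_csv(matrix_path, sep=sep, float_format="%.17g")


def write_matrix_market(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write sparse coordinate triplets plus gene/cell index side files."""
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(ds.cpm), precision=17)
    Path(genes_path).write_text("".join(f"{g}\n" for g in ds.gene_names))
    Path(cells_path).write_text("".join(f"{c}\n" for c in ds.cell_ids))


def write_meta(ds: ExpressionDataset, meta_path: str | Path, sep: str = "\t") -> None:
    out = ds.cell_meta.copy()
    out.insert(0, "sample_name", ds.cell_ids)
    out.to_csv(meta_path, sep=sep, index=False)


def select_cells(ds: ExpressionDataset, sel: CellSelector) -> list[str]:
    """Cells matching every given criterion, minus exclusions, in dataset order.

    An empty result is not an error here; contrast construction rejects
    empty sets downstream.
    """
    meta = ds.cell_meta
    mask = np.ones(ds.n_cells, dtype=bool)
    if sel.regions is not None:
        mask &= meta["region_label"].isin(sel.regions).to_numpy()
    if sel.subclasses is not None:
        mask &= meta["subclass_label"].isin(sel.subclasses).to_numpy()
    if sel.classes is not None:
        mask &= meta["class_label"].isin(sel.classes).to_numpy()
    if sel.exclude_subclasses is not None:
        mask &= ~meta["subclass_label"].isin(sel.exclude_subclasses).to_numpy()
    return list(ds.cell_ids[mask])


def pool_cells(ds: ExpressionDataset, selectors: Iterable[CellSelector]) -> list[str]:
    """Deduplicated union of per-selector results, in dataset order."""
    selectors = list(selectors)
    if not selectors:
        raise SchemaError("pool_cells requires at least one selector")
    chosen: set[str] = set()
    for sel in selectors:
        chosen.update(select_cells(ds, sel))
    return [c for c in ds.cell_ids if c in chosen]
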