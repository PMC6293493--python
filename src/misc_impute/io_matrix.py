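"""Expression-matrix container and file I/O.

The whole package works on a single coordinate convention: genes are rows,
cells are columns, both 0-based internally; gene and cell identifiers are
the external contract.  Matrices are stored sparse (CSR) so that zero
positions can be enumerated without densifying a genome-scale matrix.

Supported on-disk formats:

* Matrix Market coordinate (``.mtx``) with two sidecar text files holding
  row and column names (``<stem>.rows.txt`` / ``<stem>.cols.txt``, one
  identifier per line).
* Delimited text (TSV/CSV, auto-detected by extension) with gene ids in
  the first column and a header row of cell ids.
* Gene lists as plain text, one identifier per line, ``#`` comments allowed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

VALID_UNITS = ("counts", "umi", "rpkm", "unknown")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(ValueError):
    """Parsed data violates a matrix invariant (duplicates, negatives, NaN)."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {axis} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of non-negative expression values.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique identifier lists; ``values.shape == (len(gene_ids), len(cell_ids))``.
    values
        Non-negative matrix; accepted dense or sparse, stored as CSR.
    unit
        Metadata tag, one of ``counts | umi | rpkm | unknown``.  No operation
        renormalizes silently based on it.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: sp.csr_matrix
    unit: str = "unknown"

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if not sp.issparse(self.values):
            arr = np.asarray(self.values, dtype=float)
            if arr.ndim != 2:
                raise ValidationError("values must be a 2-D matrix")
            self.values = sp.csr_matrix(arr)
        else:
            self.values = sp.csr_matrix(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.values.data
        if np.isnan(data).any():
            raise ValidationError("matrix contains NaN values")
        if (data < 0).any():
            raise ValidationError("matrix contains negative values")
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        self.values.eliminate_zeros()

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_cells)

    def dense(self) -> np.ndarray:
        """Materialize as a dense float array (use only at desk scale)."""
        return np.asarray(self.values.todense(), dtype=float)

    def gene_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def row(self, i: int) -> np.ndarray:
        return np.asarray(self.values.getrow(i).todense()).ravel()

    def iter_zero_positions(self, gene_rows: Sequence[int] | None = None) -> Iterator[tuple[int, np.ndarray]]:
        """Yield ``(gene_row, zero_cell_columns)`` without densifying.

        Zero columns are derived per row from the CSR structure, so a
        genome-scale matrix is traversed in O(nnz + zeros emitted).
        """
        indptr, indices = self.values.indptr, self.values.indices
        all_cols = np.arange(self.n_cells)
        rows = range(self.n_genes) if gene_rows is None else gene_rows
        for g in rows:
            nz = indices[indptr[g]:indptr[g + 1]]
            yield g, np.setdiff1d(all_cols, nz, assume_unique=True)

    def zero_positions(self, gene_rows: Sequence[int] | None = None) -> np.ndarray:
        """All zero (gene_row, cell_col) pairs as an (k, 2) int array."""
        chunks = [
            np.column_stack([np.full(len(cols), g), cols])
            for g, cols in self.iter_zero_positions(gene_rows)
            if len(cols)
        ]
        if not chunks:
            return np.empty((0, 2), dtype=int)
        return np.concatenate(chunks)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.cell_ids), self.values.copy(), self.unit
        )


@dataclass
class GeneList:
    """An ordered, duplicate-free set of gene identifiers."""

    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        if not self.ids:
            raise ValidationError("gene list is empty")
        _check_unique(self.ids, "gene-list")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in set(self.ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def _read_names(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} sidecar file: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def read_gene_list(path: str | os.PathLike) -> GeneList:
    """Read a plain-text gene list; blank lines and ``#`` comments skipped."""
    ids = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if ln:
            ids.append(ln)
    if not ids:
        raise ParseError(f"{path}: no gene identifiers found")
    return GeneList(ids)


def read_expression_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    orientation: str = "genes_in_rows",
    unit: str = "unknown",
) -> ExpressionMatrix:
    """Read an expression matrix from MTX or delimited text.

    The returned matrix is always genes x cells regardless of the on-disk
    orientation.  ``format`` is inferred from the extension when omitted.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "delimited"
    if orientation not in ("genes_in_rows", "cells_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if format == "mtx":
        rows_path, cols_path = _sidecar_paths(path)
        try:
            values = scipy.io.mmread(os.fspath(path))
        except Exception as exc:  # scipy raises bare ValueError on bad files
            raise ParseError(f"{path}: malformed Matrix Market file ({exc})") from exc
        row_names = _read_names(rows_path, "row-name")
        col_names = _read_names(cols_path, "column-name")
        values = sp.csr_matrix(values)
        if values.shape != (len(row_names), len(col_names)):
            raise ValidationError(
                f"{path}: declared shape {values.shape} does not match sidecar "
                f"name counts ({len(row_names)}, {len(col_names)})"
            )
    elif format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: malformed delimited file ({exc})") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: no data columns found (wrong separator?)")
        row_names = [str(i) for i in df.index]
        col_names = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "cells_in_rows":
        values = values.T if sp.issparse(values) else values.T
        row_names, col_names = col_names, row_names
    return ExpressionMatrix(row_names, col_names, values, unit=unit)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a matrix to MTX (+ name sidecars) or delimited text.

    Round-trip ``read(write(m))`` returns an equal matrix up to the text
    representation precision of the format.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "delimited"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        scipy.io.mmwrite(os.fspath(path), sp.coo_matrix(matrix.values))
        rows_path, cols_path = _sidecar_paths(path)
        rows_path.write_text("\n".join(matrix.gene_ids) + "\n")
        cols_path.write_text("\n".join(matrix.cell_ids) + "\n")
    elif format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids)
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_gene_list(genes: GeneList | Sequence[str], path: str | os.PathLike) -> None:
    ids = list(genes.ids if isinstance(genes, GeneList) else genes)
    Path(path).write_text("\n".join(ids) + "\n")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def rpkm_normalize(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalization of a count matrix.

    ``rpkm[i, j] = counts[i, j] * 1e9 / (length_i * total_counts_j)`` with
    gene length in bases.  The zero pattern is preserved exactly.
    """
    if counts.unit not in ("counts", "umi", "unknown"):
        raise ValidationError(f"cannot RPKM-normalize a matrix with unit {counts.unit!r}")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValidationError(f"missing gene lengths for: {', '.join(missing[:10])}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
    if (lengths <= 0).any():
        bad = counts.gene_ids[int(np.argmax(lengths <= 0))]
        raise ValidationError(f"non-positive length for gene {bad!r}")
    totals = np.asarray(counts.values.sum(axis=0)).ravel()
    if (totals <= 0).any():
        bad = counts.cell_ids[int(np.argmax(totals <= 0))]
        raise ValidationError(f"cell {bad!r} has zero total counts")
    out = sp.csr_matrix(counts.values, copy=True)
    # scale each stored entry; zeros stay structural zeros
    coo = out.tocoo()
    coo.data = coo.data * 1e9 / (lengths[coo.row] * totals[coo.col])
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.cell_ids), coo.tocsr(), unit="rpkm"
    )
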