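"""Expression-matrix container and plain-text readers/writers.

The package's canonical orientation is cells as rows and genes as columns;
every formula elsewhere in the package is stated in that orientation.
Dense matrices travel as labelled CSV/TSV, sparse ones as MatrixMarket
triplets with companion barcode/feature files (the 10x convention: genes
as MTX rows, cells as MTX columns).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Non-negative expression values, stored as float64.
    cell_ids, gene_ids : sequences of str
        Unique, ordered identifiers for rows and columns.
    space : {"raw", "log"}
        Whether ``values`` are raw counts or log1p-transformed.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    space: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n_cells)]
        if not self.gene_ids:
            self.gene_ids = [f"gene{j}" for j in range(n_genes)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValidationError("identifier lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene identifiers")
        if self.space not in ("raw", "log"):
            raise ValidationError(f"unknown space {self.space!r}")
        if self.values.size:
            if not np.all(np.isfinite(self.values)):
                raise ValidationError("matrix contains non-finite values")
            if self.values.min() < 0:
                raise ValidationError("matrix contains negative values")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.cell_ids), columns=list(self.gene_ids)
        )

    @classmethod
    def from_df(cls, df: pd.DataFrame, space: str = "raw") -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=np.float64),
            cell_ids=[str(c) for c in df.index],
            gene_ids=[str(g) for g in df.columns],
            space=space,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            space=self.space,
        )


def _sniff_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).name.lower()
    if suffix.endswith((".tsv", ".txt", ".tsv.gz", ".txt.gz")):
        return "\t"
    return ","


def read_dense(
    path: str | Path,
    orientation: str = "cells_as_rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a labelled dense matrix from CSV/TSV.

    ``orientation`` says what the *file* rows are; the returned matrix is
    always cells x genes.
    """
    if orientation not in ("cells_as_rows", "genes_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _sniff_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if len(df) and not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValidationError(f"non-numeric values in {path}")
    df = df.astype(np.float64)
    if orientation == "genes_as_rows":
        df = df.T
    return ExpressionMatrix.from_df(df, space="raw")


def write_dense(matrix: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write a matrix as labelled delimited text, cells as rows.

    Full repr precision is used so an integer-count round-trip is exact.
    """
    sep = _sniff_delimiter(path, delimiter)
    matrix.to_df().to_csv(path, sep=sep, float_format="%.17g", quoting=csv.QUOTE_MINIMAL)


def read_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket triplet (genes x cells) plus companions.

    Returns the densified matrix in cells x genes orientation.
    """
    sparse = mmread(str(matrix_path))
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    n_genes, n_cells = sparse.shape
    if len(features) != n_genes:
        raise ValidationError(
            f"feature file has {len(features)} entries but matrix declares {n_genes} genes"
        )
    if len(barcodes) != n_cells:
        raise ValidationError(
            f"barcode file has {len(barcodes)} entries but matrix declares {n_cells} cells"
        )
    dense = np.asarray(sparse.todense(), dtype=np.float64).T  # -> cells x genes
    return ExpressionMatrix(dense, cell_ids=barcodes, gene_ids=features, space="raw")


def _read_id_column(path: str | Path) -> list[str]:
    # 10x feature files may carry extra columns (id, symbol, type); take the first.
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (cell_id, label) TSV into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"label file {path} needs two columns")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")
    if s.index.duplicated().any():
        raise ValidationError("duplicate cell identifiers in label file")
    return s


def validate_labels(labels: pd.Series, matrix: ExpressionMatrix) -> None:
    missing = set(labels.index) - set(matrix.cell_ids)
    if missing:
        raise ValidationError(f"labelled cells absent from matrix: {sorted(missing)[:5]}")
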