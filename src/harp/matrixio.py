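"""Domain containers and delimited-matrix I/O.

Two thin containers are used throughout the package:

* :class:`ExpressionMatrix` — a genes x columns non-negative matrix with gene
  and column identifiers.  It plays the role of the bulk matrix ``Y`` (columns
  are samples), the reference / anchor matrix ``X`` (columns are cell types),
  and the harmonized reference ``X'``.
* :class:`CompositionMatrix` — a cell types x samples matrix of (possibly
  distorted) cell fractions, optionally extended by a reserved "UI"
  (unidentified) row absorbing cell types not covered by the measurement.

Matrices are serialized as plain TSV/CSV with one header row and the
identifiers in the first column; the delimiter is inferred from the file
extension (``.tsv`` -> tab, anything else -> comma).  Canonical in-memory
orientation is genes-in-rows for expression and cell-types-in-rows for
compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CompositionMatrix",
    "ScalingVector",
    "ValidationReport",
    "read_matrix",
    "write_matrix",
    "read_composition",
    "align_features",
    "validate_inputs",
    "UI_TOKEN",
]

#: Reserved identifier for the unidentified-compartment row/column.
UI_TOKEN = "UI"


def _check_ids(ids: Sequence[str], what: str, n_expected: int) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) != n_expected:
        raise ValueError(
            f"{what}: got {len(ids)} identifiers for {n_expected} rows/columns"
        )
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise ValueError(f"{what}: duplicate identifiers {dups}")
    return ids


def _check_values(values: np.ndarray, what: str, allow_negative: bool = False) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{what}: expected a 2-D matrix, got ndim={values.ndim}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: non-finite entries present")
    if not allow_negative and np.any(values < 0):
        raise ValueError(f"{what}: negative entries present")
    return values


@dataclass
class ExpressionMatrix:
    """Non-negative genes x columns matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_columns)
        Linear-scale, non-negative expression values.
    gene_ids : sequence of str
        Unique row identifiers.
    column_ids : sequence of str
        Unique column identifiers (samples or cell types).
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, "ExpressionMatrix")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids", self.values.shape[0])
        self.column_ids = _check_ids(self.column_ids, "column_ids", self.values.shape[1])

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[rows, :], list(genes), list(self.column_ids))

    def subset_columns(self, cols: Sequence[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.column_ids)}
        j = [idx[c] for c in cols]
        return ExpressionMatrix(self.values[:, j], list(self.gene_ids), list(cols))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids), list(self.column_ids))


@dataclass
class CompositionMatrix:
    """Cell types x samples matrix of cell fractions.

    ``is_extended`` marks the presence of the reserved "UI" row (must then be
    the last cell type).  Columns of a freshly extended matrix sum to one, but
    the constructor does not enforce that: distorted compositions are
    deliberately off-simplex, and over-complete measurements are clamped.
    """

    values: np.ndarray
    celltype_ids: list[str]
    sample_ids: list[str]
    is_extended: bool = False

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, "CompositionMatrix")
        self.celltype_ids = _check_ids(self.celltype_ids, "celltype_ids", self.values.shape[0])
        self.sample_ids = _check_ids(self.sample_ids, "sample_ids", self.values.shape[1])
        if self.is_extended and self.celltype_ids[-1] != UI_TOKEN:
            raise ValueError("extended CompositionMatrix must have the reserved "
                             f"'{UI_TOKEN}' row last")
        if not self.is_extended and UI_TOKEN in self.celltype_ids:
            raise ValueError(f"'{UI_TOKEN}' is a reserved cell-type identifier")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.celltype_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, is_extended: bool = False) -> "CompositionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), is_extended)

    def subset_samples(self, samples: Sequence[str]) -> "CompositionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        j = [idx[s] for s in samples]
        return CompositionMatrix(self.values[:, j], list(self.celltype_ids),
                                 list(samples), self.is_extended)

    def drop_ui(self) -> "CompositionMatrix":
        """Return the matrix restricted to identified cell types."""
        if not self.is_extended:
            return self
        return CompositionMatrix(self.values[:-1, :], self.celltype_ids[:-1],
                                 list(self.sample_ids), False)

    def copy(self) -> "CompositionMatrix":
        return CompositionMatrix(self.values.copy(), list(self.celltype_ids),
                                 list(self.sample_ids), self.is_extended)


@dataclass
class ScalingVector:
    """Per-cell-type non-negative multiplicative composition correction.

    One entry per (extended) cell type; ``alpha[l]`` rescales the measured
    fraction of cell type ``l`` to correct systematic losses (e.g. cell-type
    specific dissociation or gating bias).
    """

    alpha: np.ndarray
    celltype_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("ScalingVector: non-finite entries")
        if np.any(self.alpha < 0):
            raise ValueError("ScalingVector: negative entries")
        if self.celltype_ids is not None:
            self.celltype_ids = _check_ids(self.celltype_ids, "celltype_ids", len(self.alpha))

    def __len__(self) -> int:
        return len(self.alpha)


@dataclass
class ValidationReport:
    """Outcome of an input consistency check; ``ok`` is False on fatal issues."""

    n_shared_genes: int = 0
    dropped_genes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    ok: bool = True


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise ValueError(f"{path}: duplicate row identifiers {dup_rows}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise ValueError(f"{path}: duplicate column identifiers {dup_cols}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix ({exc})") from exc
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: missing values in matrix")
    return df


def read_matrix(path: str | Path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Parameters
    ----------
    path : str or Path
        TSV or CSV file with one header row and identifiers in the first
        column.
    orientation : {"genes_in_rows", "genes_in_cols"}
        How the file on disk is laid out; the returned matrix is always
        genes-in-rows.
    """
    if orientation not in ("genes_in_rows", "genes_in_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_frame(path)
    if orientation == "genes_in_cols":
        df = df.T
    return ExpressionMatrix.from_frame(df)


def read_composition(path: str | Path) -> CompositionMatrix:
    """Read a cell types x samples composition matrix (cell types in rows)."""
    df = _read_frame(path)
    extended = len(df.index) > 0 and df.index[-1] == UI_TOKEN
    return CompositionMatrix.from_frame(df, is_extended=extended)


def write_matrix(m: ExpressionMatrix | CompositionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV/CSV (delimiter from extension, 17 sig. digits)."""
    path = Path(path)
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("cannot serialize an empty matrix")
    m.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")


# ---------------------------------------------------------------------------
# Alignment & validation
# ---------------------------------------------------------------------------

def align_features(
    y: ExpressionMatrix, x: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, ValidationReport]:
    """Restrict two expression matrices to their shared genes, same row order.

    Gene matching is exact string equality; the shared genes keep the order
    they have in ``y``.  Raises if the intersection is empty.
    """
    if y.n_genes == 0 or x.n_genes == 0:
        raise ValueError("align_features: empty input matrix")
    x_set = set(x.gene_ids)
    shared = [g for g in y.gene_ids if g in x_set]
    if not shared:
        raise ValueError("align_features: no shared genes between matrices")
    report = ValidationReport(
        n_shared_genes=len(shared),
        dropped_genes=sorted((set(y.gene_ids) | set(x.gene_ids)) - set(shared)),
        ok=True,
    )
    if report.dropped_genes:
        report.warnings.append(
            f"dropped {len(report.dropped_genes)} genes absent from one side"
        )
    return y.subset_genes(shared), x.subset_genes(shared), report


def validate_inputs(
    y: ExpressionMatrix, x: ExpressionMatrix, c: CompositionMatrix
) -> ValidationReport:
    """Check that a (Y, X, C) triple is mutually consistent.

    Findings are reported, never raised: the caller decides.  ``ok`` turns
    False on structural problems (samples or cell types missing from the
    expression matrices, negative entries); fraction columns summing above one
    only warn.
    """
    report = ValidationReport(ok=True)
    missing_samples = [s for s in c.sample_ids if s not in set(y.column_ids)]
    if missing_samples:
        report.ok = False
        report.warnings.append(
            f"composition samples absent from bulk matrix: {missing_samples}"
        )
    identified = c.celltype_ids[:-1] if c.is_extended else c.celltype_ids
    missing_types = [t for t in identified if t not in set(x.column_ids)]
    if missing_types:
        report.ok = False
        report.warnings.append(
            f"composition cell types absent from reference: {missing_types}"
        )
    for m, what in ((y, "bulk"), (x, "reference")):
        if np.any(m.values < 0):
            report.ok = False
            report.warnings.append(f"negative entries in {what} matrix")
    if np.any(c.values < 0):
        report.ok = False
        report.warnings.append("negative entries in composition matrix")
    col_sums = c.values.sum(axis=0)
    over = np.nonzero(col_sums > 1.0 + 1e-6)[0]
    for j in over:
        report.warnings.append(
            f"composition column sum exceeds 1: sample {c.sample_ids[j]!r} "
            f"sums to {col_sums[j]:.6g}"
        )
    report.n_shared_genes = len(set(y.gene_ids) & set(x.gene_ids))
    return report


def emit_warnings(report: ValidationReport) -> None:
    for w in report.warnings:
        warnings.warn(w, stacklevel=2)
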