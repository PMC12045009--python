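"""Readers and writers for every on-disk format the toolkit touches.

Formats: MatrixMarket sparse counts plus TSV gene/cell annotation tables,
dense TSV matrices (bulk, reference, proportions), TSV scale-factor and
imaging-measurement tables, and JSON evaluation reports. Dense text uses
17 significant digits so read/write pairs round-trip within 1e-12 relative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, LabelError, ValidationError
from .evaluate import EvaluationReport
from .model import BulkMatrix, CellTypeReference, ProportionMatrix, SingleCellDataset

FLOAT_FORMAT = "%.17g"


@dataclass(eq=False)
class ScaleFactorTable:
    """Tabular cell-size scale factors: one (cell_type, factor, source) row per type."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = ["cell_type", "factor"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"scale-factor table missing required columns: {missing}")
        if "source" not in df.columns:
            df = df.assign(source="")
        df = df[["cell_type", "factor", "source"]].copy()
        if df["cell_type"].duplicated().any():
            dups = df.loc[df["cell_type"].duplicated(), "cell_type"].tolist()
            raise LabelError(f"duplicate cell types in scale-factor table: {dups}")
        try:
            df["factor"] = df["factor"].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric scale factor: {exc}") from exc
        if (~np.isfinite(df["factor"])).any() or (df["factor"] <= 0).any():
            bad = df.loc[(df["factor"] <= 0) | ~np.isfinite(df["factor"]), "cell_type"].tolist()
            raise ValidationError(f"non-positive or non-finite scale factors for: {bad}")
        self.table = df.reset_index(drop=True)

    def to_factors(self):
        from .model import CellScaleFactors

        return CellScaleFactors(dict(zip(self.table["cell_type"], self.table["factor"])))

    def ratio(self, numerator: str, denominator: str) -> float:
        """Ratio of two cell types' factors (e.g. neuron / glial)."""
        s = dict(zip(self.table["cell_type"], self.table["factor"]))
        for label in (numerator, denominator):
            if label not in s:
                raise LabelError(f"cell type {label!r} not in scale-factor table")
        return s[numerator] / s[denominator]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], source: str = "") -> "ScaleFactorTable":
        rows = [{"cell_type": str(k), "factor": float(v), "source": source} for k, v in mapping.items()]
        return cls(pd.DataFrame(rows))


@dataclass(eq=False)
class MeasurementTable:
    """Per-cell imaging measurements: cell_id, cell_type, nucleus_area, marker_copies."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = ["cell_id", "cell_type", "nucleus_area", "marker_copies"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"measurement table missing required columns: {missing}")
        df = df[required].copy()
        if df.empty:
            raise ValidationError("measurement table is empty")
        if df["cell_type"].isna().any() or (df["cell_type"].astype(str).str.len() == 0).any():
            raise ValidationError("measurement rows must carry a non-empty cell_type")
        df["nucleus_area"] = df["nucleus_area"].astype(float)
        if (~np.isfinite(df["nucleus_area"])).any() or (df["nucleus_area"] < 0).any():
            raise ValidationError("nucleus_area must be finite and >= 0")
        df["marker_copies"] = df["marker_copies"].astype(float)
        if (df["marker_copies"] < 0).any() or not np.array_equal(
            df["marker_copies"], np.rint(df["marker_copies"])
        ):
            raise ValidationError("marker_copies must be nonnegative integers")
        df["marker_copies"] = df["marker_copies"].astype(int)
        self.table = df.reset_index(drop=True)


def _read_annotation(path: str | Path, expected_columns: list[str]) -> pd.DataFrame:
    """Read a TSV annotation table that may be headered or header-less.

    Header-less files are assumed to carry ``expected_columns`` in order
    (identifier first); headered files must contain them by name.
    """
    path = Path(path)
    probe = pd.read_csv(path, sep="\t", header=None, dtype=str, nrows=1)
    first_row = probe.iloc[0].astype(str).tolist()
    headered = expected_columns[0] in first_row
    if headered:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        return df
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < len(expected_columns):
        raise FormatError(
            f"{path}: expected at least {len(expected_columns)} columns "
            f"({expected_columns}), got {df.shape[1]}"
        )
    df = df.iloc[:, : len(expected_columns)]
    df.columns = expected_columns
    return df


def read_sparse_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    cell_type_col: str = "cell_type",
    sample_col: str = "sample",
    transpose: bool = False,
) -> SingleCellDataset:
    """Load a MatrixMarket count matrix with gene and cell annotation TSVs.

    Genes are rows and cells columns by default (the common single-cell export
    convention); pass ``transpose=True`` for cells-as-rows dialects.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if transpose:
        mat = mat.T
    if (mat < 0).any():
        raise ValidationError(f"{matrix_path}: count matrix contains negative entries")
    genes = _read_annotation(genes_path, ["gene"])
    cells = _read_annotation(cells_path, ["cell_id", cell_type_col, sample_col])
    if genes.shape[0] != mat.shape[0]:
        raise FormatError(
            f"gene annotation rows ({genes.shape[0]}) do not match matrix rows ({mat.shape[0]})"
        )
    if cells.shape[0] != mat.shape[1]:
        raise FormatError(
            f"cell annotation rows ({cells.shape[0]}) do not match matrix columns ({mat.shape[1]})"
        )
    counts = pd.DataFrame(mat, index=pd.Index(genes["gene"], name="gene"),
                          columns=pd.Index(cells["cell_id"], name="cell_id"))
    annotations = cells.set_index("cell_id").rename(
        columns={cell_type_col: "cell_type", sample_col: "sample"}
    )
    return SingleCellDataset(counts=counts, cells=annotations)


def write_sparse_counts(
    dataset: SingleCellDataset,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write a dataset as MatrixMarket coordinate integers plus annotation TSVs."""
    sparse = scipy.sparse.coo_matrix(dataset.counts.to_numpy(dtype=np.int64))
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer")
    pd.DataFrame({"gene": dataset.genes}).to_csv(genes_path, sep="\t", index=False)
    cells = dataset.cells.reset_index()
    cells = cells.rename(columns={cells.columns[0]: "cell_id"})
    cells.to_csv(cells_path, sep="\t", index=False)


def _read_dense_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated row identifiers: {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric value {df.at[row, col]!r} at row {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().argmax()]
            raise FormatError(f"{path}: missing value at row {row!r}, column {col!r}")
        numeric[col] = converted
    return numeric


def read_dense_matrix(path: str | Path, kind: str = "bulk"):
    """Read a dense TSV matrix (first column = gene/row id, header = column labels).

    ``kind`` selects the returned domain type: "bulk", "reference", or
    "proportions".
    """
    values = _read_dense_frame(path)
    if kind == "bulk":
        return BulkMatrix(values)
    if kind == "reference":
        return CellTypeReference(values)
    if kind == "proportions":
        return ProportionMatrix(values)
    raise ValidationError(f"unknown dense matrix kind: {kind!r}")


def write_dense_matrix(matrix, path: str | Path) -> None:
    """Write a labeled matrix (or bare DataFrame) to TSV at full precision."""
    values = getattr(matrix, "values", matrix)
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(values)
    values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_scale_factors(path: str | Path) -> ScaleFactorTable:
    df = pd.read_csv(path, sep="\t", dtype={"cell_type": str})
    missing = [c for c in ("cell_type", "factor") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: scale-factor file missing required columns {missing}")
    return ScaleFactorTable(df)


def write_scale_factors(table: ScaleFactorTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_measurements(path: str | Path) -> MeasurementTable:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cell_type": str})
    return MeasurementTable(df)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Serialize an evaluation report as JSON with deterministic field order."""
    payload = report.to_dict()
    try:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, allow_nan=False)
            handle.write("\n")
    except OSError as exc:
        raise FormatError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> EvaluationReport:
    with open(path, encoding="utf-8") as handle:
        return EvaluationReport.from_dict(json.load(handle))
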