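"""Core domain types and the scaling/aggregation math shared by all modules.

The linear model is ``Y = Z @ diag(s) @ P``:

* ``Y`` — bulk expression, genes x samples (:class:`BulkMatrix`)
* ``Z`` — cell-type signature matrix, genes x types (:class:`CellTypeReference`)
* ``s`` — per-type cell-size scale factors (:class:`CellScaleFactors`)
* ``P`` — cell-type proportions, types x samples, columns on the probability
  simplex (:class:`ProportionMatrix`)

All matrices carry explicit pandas label indices; operations align by label,
never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import LabelError, ValidationError

SIMPLEX_ATOL = 1e-9


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise LabelError(f"duplicate {what}: {dups}")


def _as_numeric_frame(values, what: str) -> pd.DataFrame:
    df = pd.DataFrame(values)
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{what} values must be numeric: {exc}") from exc
    if not np.isfinite(arr).all():
        raise ValidationError(f"{what} values must be finite")
    return df


@dataclass(eq=False)
class BulkMatrix:
    """Bulk expression matrix, genes (rows) x samples (columns)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = _as_numeric_frame(self.values, "bulk")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValidationError("bulk matrix must have at least one gene and one sample")
        _check_unique(self.values.index, "gene identifiers in bulk matrix")
        _check_unique(self.values.columns, "sample identifiers in bulk matrix")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("bulk matrix contains negative entries")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(eq=False)
class CellTypeReference:
    """Signature matrix ``Z`` (genes x cell types).

    ``scaled`` records whether cell-size rescaling (``Z' = Z @ diag(s)``) has
    already been applied, so a second application must be forced explicitly.
    """

    values: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = _as_numeric_frame(self.values, "reference")
        if self.values.shape[1] < 1:
            raise ValidationError("reference must have at least one cell type")
        if self.values.shape[0] < 1:
            raise ValidationError("reference must have at least one gene")
        _check_unique(self.values.index, "gene identifiers in reference")
        _check_unique(self.values.columns, "cell-type labels in reference")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("reference contains negative entries")
        dead = [c for c, col in self.values.items() if not (col.to_numpy() > 0).any()]
        if dead:
            raise ValidationError(f"reference columns with no positive entry: {dead}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    @property
    def n_types(self) -> int:
        return self.values.shape[1]


@dataclass(eq=False)
class CellScaleFactors:
    """Per-cell-type size scale factors ``s`` (unitless relative sizes)."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        cleaned: dict[str, float] = {}
        for label, value in dict(self.factors).items():
            try:
                f = float(value)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"scale factor for {label!r} is not numeric: {value!r}") from exc
            if not np.isfinite(f) or f <= 0:
                raise ValidationError(f"scale factor for {label!r} must be positive and finite, got {f}")
            cleaned[str(label)] = f
        if not cleaned:
            raise ValidationError("scale-factor mapping is empty")
        self.factors = cleaned

    def __getitem__(self, label: str) -> float:
        return self.factors[label]

    def __contains__(self, label: str) -> bool:
        return label in self.factors

    def __len__(self) -> int:
        return len(self.factors)

    def covers(self, labels: Iterable[str]) -> bool:
        return all(lbl in self.factors for lbl in labels)

    def as_series(self, order: Iterable[str] | None = None) -> pd.Series:
        """Factors as a pandas Series, optionally reindexed to ``order``."""
        s = pd.Series(self.factors, dtype=float)
        if order is not None:
            order = list(order)
            missing = [lbl for lbl in order if lbl not in self.factors]
            if missing:
                raise LabelError(f"missing scale factors for cell types: {missing}")
            s = s.reindex(order)
        return s

    @classmethod
    def ones(cls, labels: Iterable[str]) -> "CellScaleFactors":
        return cls({lbl: 1.0 for lbl in labels})


@dataclass(eq=False)
class ProportionMatrix:
    """Cell-type proportions ``P`` (types x samples); columns sum to 1."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = _as_numeric_frame(self.values, "proportions")
        _check_unique(self.values.index, "cell-type labels in proportions")
        _check_unique(self.values.columns, "sample identifiers in proportions")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1 + SIMPLEX_ATOL).any():
            raise ValidationError("proportions must lie in [0, 1]")
        sums = arr.sum(axis=0)
        bad = np.abs(sums - 1.0) > SIMPLEX_ATOL
        if bad.any():
            offenders = self.values.columns[bad].tolist()
            raise ValidationError(
                f"proportion columns must sum to 1 within {SIMPLEX_ATOL}: {offenders}"
            )

    @property
    def cell_types(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ProportionMatrix":
        """Explicit renormalization of nonnegative columns onto the simplex."""
        arr = counts.to_numpy(dtype=float)
        sums = arr.sum(axis=0)
        if (sums <= 0).any():
            offenders = counts.columns[sums <= 0].tolist()
            raise ValidationError(f"columns with non-positive totals cannot be normalized: {offenders}")
        return cls(pd.DataFrame(arr / sums, index=counts.index, columns=counts.columns))


@dataclass(eq=False)
class SingleCellDataset:
    """Single-cell/nucleus counts with per-cell type and sample annotations.

    ``counts`` is genes x cells with nonnegative integral values; ``cells`` is
    indexed by cell identifier (one row per count column, same order) and must
    carry a ``cell_type`` column; a ``sample`` column is optional but needed
    for per-sample operations.
    """

    counts: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = _as_numeric_frame(self.counts, "counts")
        self.cells = pd.DataFrame(self.cells)
        if self.counts.shape[1] != self.cells.shape[0]:
            raise ValidationError(
                "cell annotations do not match count matrix: expected "
                f"{self.counts.shape[1]} rows, got {self.cells.shape[0]}"
            )
        if not self.counts.columns.equals(self.cells.index):
            raise ValidationError("cell annotation index must equal count matrix columns, in order")
        _check_unique(self.counts.index, "gene identifiers in counts")
        _check_unique(self.counts.columns, "cell identifiers in counts")
        arr = self.counts.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("counts contain negative entries")
        if not np.array_equal(arr, np.rint(arr)):
            raise ValidationError("counts must be integral")
        if "cell_type" not in self.cells.columns:
            raise ValidationError("cell annotations must carry a 'cell_type' column")
        types = self.cells["cell_type"]
        if types.isna().any() or (types.astype(str).str.len() == 0).any():
            raise ValidationError("every cell must have a non-empty cell_type label")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cells["cell_type"].unique().tolist())

    def library_sizes(self) -> pd.Series:
        """Total counts per cell."""
        return self.counts.sum(axis=0)

    def type_means(self) -> pd.DataFrame:
        """Per-gene arithmetic mean of counts within each cell type (genes x types)."""
        groups = self.cells.groupby("cell_type", sort=True).groups
        cols = {
            str(ct): self.counts.loc[:, idx].to_numpy(dtype=float).mean(axis=1)
            for ct, idx in groups.items()
        }
        return pd.DataFrame(cols, index=self.counts.index)


def rescale_reference(
    reference: CellTypeReference,
    factors: CellScaleFactors | Mapping[str, float],
    force: bool = False,
) -> CellTypeReference:
    """Apply cell-size scale factors as a column-wise scalar product: ``Z' = Z @ diag(s)``.

    Raises if a factor is missing for any reference cell type, or if the
    reference is already scaled (unless ``force=True``).
    """
    if not isinstance(factors, CellScaleFactors):
        factors = CellScaleFactors(dict(factors))
    if reference.scaled and not force:
        raise ValidationError(
            "reference is already scaled; pass force=True to rescale deliberately"
        )
    s = factors.as_series(order=reference.cell_types)  # raises LabelError if missing
    values = reference.values.mul(s, axis=1)
    return CellTypeReference(values=values, scaled=True)


def aggregate_cell_types(
    dataset: SingleCellDataset,
    label_map: Mapping[str, str],
    drop_unmapped: bool = False,
) -> SingleCellDataset:
    """Collapse fine cell-type labels to broad labels (counts untouched).

    Every fine label present must appear in ``label_map``; with
    ``drop_unmapped=True``, cells with unmapped labels are removed instead.
    """
    present = pd.unique(dataset.cells["cell_type"])
    unmapped = [lbl for lbl in present if lbl not in label_map]
    if unmapped and not drop_unmapped:
        raise LabelError(f"unmapped cell-type labels: {sorted(map(str, unmapped))}")
    cells = dataset.cells.copy()
    keep = cells["cell_type"].isin(label_map)
    cells = cells.loc[keep].copy()
    cells["cell_type"] = cells["cell_type"].map(dict(label_map))
    counts = dataset.counts.loc[:, cells.index]
    return SingleCellDataset(counts=counts, cells=cells)


def compute_known_proportions(
    dataset: SingleCellDataset, by_sample: bool = False
) -> ProportionMatrix:
    """Cell-type proportions as the fraction of total cells, per sample or overall."""
    if dataset.n_cells == 0:
        raise ValidationError("dataset has no cells")
    if by_sample:
        if "sample" not in dataset.cells.columns:
            raise ValidationError("by_sample requires a 'sample' annotation column")
        table = pd.crosstab(dataset.cells["cell_type"], dataset.cells["sample"])
        empty = table.columns[table.sum(axis=0) == 0].tolist()
        if empty:
            raise ValidationError(f"samples with zero cells: {empty}")
    else:
        counts = dataset.cells["cell_type"].value_counts().sort_index()
        table = counts.to_frame(name="all")
    table = table.sort_index()
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return ProportionMatrix.from_counts(table.astype(float))
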