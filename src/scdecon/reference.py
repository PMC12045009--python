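"""Signature-matrix construction and cell-size scale-factor estimation.

Scale factors can come from three places: per-cell library sizes in the
single-cell data (computational), per-cell imaging measurements such as
nucleus area or size-marker copy counts (experimental), or a manual table
(e.g. integer sizes 10 for neurons and 3 for glia).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import LabelError, ValidationError
from .io_formats import MeasurementTable, ScaleFactorTable
from .markers import MarkerSet
from .model import CellTypeReference, SingleCellDataset


@dataclass(frozen=True)
class SizeEstimate:
    """One cell type's estimated relative size and its provenance."""

    cell_type: str
    estimate: float
    method: str  # one of {"library_sum", "nucleus_area", "marker_copies", "manual"}
    n_cells: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate) or self.estimate <= 0:
            raise ValidationError(f"size estimate for {self.cell_type!r} must be positive")
        if self.method != "manual" and self.n_cells < 1:
            raise ValidationError("data-derived size estimates need n_cells >= 1")


def _marker_genes(dataset: SingleCellDataset, markers: MarkerSet | None) -> pd.Index:
    if markers is None:
        return dataset.genes
    wanted = markers.genes()
    missing = [g for g in wanted if g not in dataset.genes]
    if missing:
        raise LabelError(f"marker genes absent from dataset: {missing}")
    return pd.Index(wanted)


def build_reference(
    dataset: SingleCellDataset,
    markers: MarkerSet | None = None,
    normalized_input: bool = False,
) -> CellTypeReference:
    """Mean expression per cell type (genes x types), optionally marker-restricted.

    The default is the arithmetic mean of raw counts per type; set
    ``normalized_input=True`` to record that the dataset holds pre-normalized
    expression (the math is identical — the flag is provenance for reports).
    """
    genes = _marker_genes(dataset, markers)
    means = dataset.type_means().loc[genes]
    return CellTypeReference(values=means, scaled=False)


def estimate_scale_factors_from_library_sizes(
    dataset: SingleCellDataset,
    markers: MarkerSet | None = None,
    normalize_min_to_one: bool = False,
    statistic: str = "median",
) -> ScaleFactorTable:
    """Estimate relative cell sizes from per-cell total counts over a gene set.

    Per cell: sum counts over the marker genes (or all genes). Per type: the
    median (default, robust) or mean of those per-cell totals. With
    ``normalize_min_to_one`` the smallest type gets factor exactly 1 and all
    pairwise ratios are preserved.
    """
    if statistic not in ("median", "mean"):
        raise ValidationError(f"unknown statistic {statistic!r}; use 'median' or 'mean'")
    genes = _marker_genes(dataset, markers)
    totals = dataset.counts.loc[genes].sum(axis=0)
    rows = []
    for cell_type, group in dataset.cells.groupby("cell_type", sort=True):
        values = totals.loc[group.index].to_numpy(dtype=float)
        if not (values > 0).any():
            raise ValidationError(f"cell type {cell_type!r} has all-zero library totals")
        estimate = float(np.median(values) if statistic == "median" else np.mean(values))
        if estimate <= 0:
            raise ValidationError(f"cell type {cell_type!r} has non-positive {statistic} library total")
        rows.append({"cell_type": str(cell_type), "factor": estimate, "source": f"library_{statistic}"})
    table = pd.DataFrame(rows)
    if normalize_min_to_one:
        table["factor"] = table["factor"] / table["factor"].min()
    return ScaleFactorTable(table)


def estimate_scale_factors_from_measurements(
    measurements: MeasurementTable,
    max_nucleus_area: float = 78.0,
    variable: str = "nucleus_area",
    statistic: str = "median",
) -> tuple[ScaleFactorTable, pd.DataFrame]:
    """Estimate relative cell sizes from per-cell imaging measurements.

    Rows with ``nucleus_area`` above ``max_nucleus_area`` (default 78, the
    out-of-focus cutoff) are removed first; the per-type factor is then the
    median (or mean) of the chosen size variable ("nucleus_area" or
    "marker_copies"). Returns the table plus a per-type filter log.
    """
    if max_nucleus_area <= 0:
        raise ValidationError("max_nucleus_area must be positive")
    if variable not in ("nucleus_area", "marker_copies"):
        raise ValidationError(f"unknown size variable {variable!r}")
    if statistic not in ("median", "mean"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    df = measurements.table
    kept = df[df["nucleus_area"] <= max_nucleus_area]
    log_rows = []
    rows = []
    for cell_type, group in df.groupby("cell_type", sort=True):
        surviving = kept[kept["cell_type"] == cell_type]
        log_rows.append(
            {
                "cell_type": str(cell_type),
                "n_total": int(len(group)),
                "n_removed": int(len(group) - len(surviving)),
                "n_kept": int(len(surviving)),
            }
        )
        if surviving.empty:
            raise ValidationError(
                f"cell type {cell_type!r} has no cells with nucleus_area <= {max_nucleus_area}"
            )
        values = surviving[variable].to_numpy(dtype=float)
        estimate = float(np.median(values) if statistic == "median" else np.mean(values))
        if estimate <= 0:
            raise ValidationError(f"cell type {cell_type!r} has non-positive {statistic} {variable}")
        rows.append({"cell_type": str(cell_type), "factor": estimate, "source": variable})
    return ScaleFactorTable(pd.DataFrame(rows)), pd.DataFrame(log_rows)


def quantile_filter(values: pd.Series, quantile: float = 0.97) -> pd.Series:
    """Generic upper-quantile filter (e.g. for image nuclei counts)."""
    if not 0 < quantile <= 1:
        raise ValidationError("quantile must be in (0, 1]")
    cutoff = values.quantile(quantile)
    return values[values <= cutoff]


def manual_scale_factors(mapping: Mapping[str, float]) -> ScaleFactorTable:
    """Wrap user-chosen scale factors (e.g. neuron=10, glial=3) as a table."""
    for label, value in mapping.items():
        if not np.isfinite(float(value)) or float(value) <= 0:
            raise ValidationError(f"manual scale factor for {label!r} must be positive, got {value}")
    return ScaleFactorTable.from_mapping(mapping, source="manual")
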