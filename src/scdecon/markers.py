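"""Marker-gene scoring and selection, plus count-level preprocessing.

The marker score for a gene and a target cell type is the target type's mean
expression divided by the single highest mean among all non-target types
("mean ratio"). A gene expressed in the target type but in no other type has
an undefined ratio; it is ranked above every finite score via an infinity
sentinel, and sentinels are ordered among themselves by target mean,
descending.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import LabelError, ValidationError
from .model import BulkMatrix, SingleCellDataset


@dataclass(eq=False)
class MarkerSet:
    """Per-cell-type ordered marker lists: type -> [(gene, score), ...]."""

    markers: dict[str, list[tuple[str, float]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cell_type, entries in self.markers.items():
            scores = [s for _, s in entries]
            if any(s2 > s1 for s1, s2 in zip(scores, scores[1:])):
                raise ValidationError(f"marker list for {cell_type!r} is not sorted by descending score")
            for gene, _ in entries:
                if gene in seen:
                    raise ValidationError(
                        f"gene {gene!r} claimed by both {seen[gene]!r} and {cell_type!r}"
                    )
                seen[gene] = cell_type

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    def genes(self, cell_type: str | None = None) -> list[str]:
        if cell_type is not None:
            if cell_type not in self.markers:
                raise LabelError(f"no markers for cell type {cell_type!r}")
            return [g for g, _ in self.markers[cell_type]]
        return [g for entries in self.markers.values() for g, _ in entries]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_type": ct, "gene": g, "score": s, "rank": i + 1}
            for ct, entries in self.markers.items()
            for i, (g, s) in enumerate(entries)
        ]
        return pd.DataFrame(rows, columns=["cell_type", "gene", "score", "rank"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerSet":
        markers: dict[str, list[tuple[str, float]]] = {}
        for ct, group in df.groupby("cell_type", sort=False):
            group = group.sort_values("rank")
            markers[str(ct)] = [(str(g), float(s)) for g, s in zip(group["gene"], group["score"])]
        return cls(markers)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "MarkerSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"cell_type": str, "gene": str}))


def _type_means(data: SingleCellDataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, SingleCellDataset):
        return data.type_means()
    means = pd.DataFrame(data)
    if means.shape[1] < 2:
        raise ValidationError("mean-ratio scoring needs at least 2 cell types")
    return means


def mean_ratio_scores(
    data: SingleCellDataset | pd.DataFrame,
    target_type: str,
    log_input: bool = False,
) -> pd.Series:
    """Score every gene for ``target_type``: target mean / highest non-target mean.

    ``data`` is either a dataset (means computed per cell on linear counts) or
    a precomputed genes x types mean matrix — e.g. batch-adjusted expression
    produced by an external tool. ``log_input`` declares that the supplied
    matrix is on log1p scale; means are then mapped back to linear scale with
    expm1 before the ratio is taken.
    """
    means = _type_means(data)
    if means.shape[1] < 2:
        raise ValidationError("mean-ratio scoring needs at least 2 cell types")
    if target_type not in means.columns:
        raise LabelError(
            f"target cell type {target_type!r} not present; available: {sorted(means.columns)}"
        )
    if log_input:
        means = np.expm1(means)
    target = means[target_type].to_numpy(dtype=float)
    others = means.drop(columns=[target_type]).to_numpy(dtype=float)
    max_other = others.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(max_other > 0, target / np.where(max_other > 0, max_other, 1.0), np.inf)
    scores = np.where((max_other == 0) & (target == 0), 0.0, scores)
    return pd.Series(scores, index=means.index, name=target_type)


def select_markers(
    data: SingleCellDataset | pd.DataFrame,
    n_per_type: int = 40,
    min_ratio: float = 1.0,
    log_input: bool = False,
) -> MarkerSet:
    """Pick the top ``n_per_type`` genes per cell type by mean-ratio score.

    A gene is claimed only by the type where its score is highest. Within a
    type, qualifying genes (score > min_ratio) are ordered by score
    descending; infinity-sentinel ties by target mean descending; remaining
    ties lexicographically by gene identifier. If a type has fewer than
    ``n_per_type`` qualifying genes, a warning is recorded in the result
    metadata (and emitted), not raised.
    """
    if n_per_type < 1:
        raise ValidationError("n_per_type must be >= 1")
    means = _type_means(data)
    if log_input:
        means = np.expm1(means)
    score_matrix = pd.DataFrame(
        {ct: mean_ratio_scores(means, ct) for ct in means.columns}, index=means.index
    )
    # each gene belongs to the type where it scores highest (ties -> first
    # type in column order, which is deterministic)
    owner = score_matrix.idxmax(axis=1)
    markers: dict[str, list[tuple[str, float]]] = {}
    shortfalls: dict[str, int] = {}
    for cell_type in means.columns:
        owned = score_matrix.index[owner == cell_type]
        candidates = []
        for gene in owned:
            score = float(score_matrix.at[gene, cell_type])
            if score > min_ratio:
                tie_break = -float(means.at[gene, cell_type]) if math.isinf(score) else 0.0
                candidates.append((-score, tie_break, str(gene), score))
        candidates.sort()
        chosen = [(gene, score) for _, _, gene, score in candidates[:n_per_type]]
        markers[str(cell_type)] = chosen
        if len(chosen) < n_per_type:
            shortfalls[str(cell_type)] = len(chosen)
    metadata: dict = {"n_per_type": n_per_type, "min_ratio": min_ratio}
    if shortfalls:
        message = ", ".join(f"{ct}: {n}/{n_per_type}" for ct, n in shortfalls.items())
        metadata["warnings"] = [f"fewer qualifying markers than requested ({message})"]
        warnings.warn(metadata["warnings"][0], stacklevel=2)
    return MarkerSet(markers, metadata=metadata)


def sample_qc_filter(
    bulk: BulkMatrix,
    markers: MarkerSet,
    min_counts: float = 38750,
    max_zero_markers: int = 30,
) -> tuple[BulkMatrix, pd.DataFrame]:
    """Drop bulk samples failing marker-level QC; return the kept matrix and a log.

    A sample is retained when its total counts over marker genes are at least
    ``min_counts`` AND it has at most ``max_zero_markers`` marker genes with
    zero expression.
    """
    marker_genes = [g for g in markers.genes() if g in bulk.genes]
    if not marker_genes:
        raise ValidationError("no marker genes present in the bulk matrix")
    sub = bulk.values.loc[marker_genes]
    totals = sub.sum(axis=0)
    zeros = (sub == 0).sum(axis=0)
    passed = (totals >= min_counts) & (zeros <= max_zero_markers)
    log = pd.DataFrame(
        {
            "sample": bulk.samples.astype(str),
            "marker_counts": totals.to_numpy(dtype=float),
            "zero_markers": zeros.to_numpy(dtype=int),
            "passed": passed.to_numpy(dtype=bool),
        }
    )
    if not passed.any():
        raise ValidationError("all samples removed by QC filter")
    return BulkMatrix(bulk.values.loc[:, passed[passed].index]), log


def downsample_counts(
    dataset: SingleCellDataset,
    grouping: str = "sample",
    seed: int | None = None,
) -> SingleCellDataset:
    """Downsample every cell's library to its cell type's minimum library size.

    Within each cell type the target is the smallest library size observed
    across ``grouping`` batches; each cell's counts are then subsampled
    without replacement (multivariate hypergeometric), so output library
    sizes are exactly the target and no entry increases.
    """
    if grouping not in dataset.cells.columns:
        raise ValidationError(f"grouping column {grouping!r} absent from cell annotations")
    rng = np.random.default_rng(seed)
    libs = dataset.library_sizes()
    counts = dataset.counts.to_numpy(dtype=np.int64).copy()
    col_of = {cid: i for i, cid in enumerate(dataset.cell_ids)}
    for cell_type, group in dataset.cells.groupby("cell_type", sort=True):
        target = int(libs.loc[group.index].min())
        if target <= 0:
            raise ValidationError(
                f"cell type {cell_type!r} has a zero minimum library size; cannot downsample"
            )
        for cid in group.index:
            j = col_of[cid]
            column = counts[:, j]
            total = int(column.sum())
            if total == target:
                continue
            counts[:, j] = rng.multivariate_hypergeometric(column, target)
    out = pd.DataFrame(counts, index=dataset.genes, columns=dataset.cell_ids)
    return SingleCellDataset(counts=out, cells=dataset.cells.copy())
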