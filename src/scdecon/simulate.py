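"""Pseudobulk construction, synthetic single-cell generation, and shuffle experiments.

Pseudobulks are reference-level mixtures: ``Y = Z @ diag(s) @ P`` computed
exactly, with optional Poisson or negative-binomial noise around that mean.
The negative binomial is parameterized by mean ``mu`` and dispersion
``theta`` with variance ``mu + mu**2 / theta``.

The shuffle experiment separates the five terms of the pipeline — the
reference, the scale factors and the proportions used to *build* the
pseudobulk versus the reference and scale factors used to *deconvolve* it —
so each can be matched or swapped independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import AlgorithmRegistry, run_deconvolution
from .errors import LabelError, ValidationError
from .evaluate import EvaluationReport, evaluate_predictions
from .io_formats import ScaleFactorTable
from .model import (
    BulkMatrix,
    CellScaleFactors,
    CellTypeReference,
    ProportionMatrix,
    SingleCellDataset,
)

NOISE_MODELS = ("none", "poisson", "negative_binomial")


def _as_factors(factors) -> CellScaleFactors | None:
    if factors is None:
        return None
    if isinstance(factors, CellScaleFactors):
        return factors
    if isinstance(factors, ScaleFactorTable):
        return factors.to_factors()
    return CellScaleFactors(dict(factors))


def generate_pseudobulk(
    reference: CellTypeReference,
    factors: CellScaleFactors | ScaleFactorTable | Mapping[str, float] | None,
    proportions: ProportionMatrix,
    noise: str = "none",
    dispersion: float | None = None,
    seed: int | None = None,
) -> BulkMatrix:
    """Build bulk samples as ``Y = Z @ diag(s) @ P`` (exact unless noise is on)."""
    if noise not in NOISE_MODELS:
        raise ValidationError(f"unknown noise model {noise!r}; use one of {NOISE_MODELS}")
    cell_factors = _as_factors(factors)
    ref_types = set(reference.cell_types)
    prop_types = set(proportions.cell_types)
    if ref_types != prop_types:
        raise LabelError(
            "cell-type labels differ between reference and proportions: "
            f"reference-only={sorted(ref_types - prop_types)}, "
            f"proportions-only={sorted(prop_types - ref_types)}"
        )
    z = reference.values.to_numpy(dtype=float)
    p = proportions.values.reindex(index=reference.cell_types).to_numpy(dtype=float)
    if cell_factors is not None:
        s = cell_factors.as_series(order=reference.cell_types).to_numpy()
        z = z * s[None, :]
    y = z @ p
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        y = rng.poisson(y).astype(float)
    elif noise == "negative_binomial":
        if dispersion is None or dispersion <= 0:
            raise ValidationError("negative_binomial noise requires dispersion > 0")
        rng = np.random.default_rng(seed)
        # mean mu, variance mu + mu^2/theta; numpy wants (n, p) with n=theta
        mu = y
        prob = np.where(mu > 0, dispersion / (dispersion + mu), 1.0)
        y = np.where(mu > 0, rng.negative_binomial(dispersion, prob), 0.0).astype(float)
    return BulkMatrix(pd.DataFrame(y, index=reference.genes, columns=proportions.samples))


@dataclass(eq=False)
class PseudobulkDesign:
    """A reproducible pseudobulk recipe: sources for Z, s, P plus noise and seed."""

    reference: CellTypeReference
    proportions: ProportionMatrix
    factors: CellScaleFactors | ScaleFactorTable | Mapping[str, float] | None = None
    noise: str = "none"
    dispersion: float | None = None
    seed: int | None = None

    def run(self) -> BulkMatrix:
        return generate_pseudobulk(
            self.reference, self.factors, self.proportions,
            noise=self.noise, dispersion=self.dispersion, seed=self.seed,
        )


def generate_synthetic_sc(
    n_types: int = 2,
    n_genes: int = 200,
    markers_per_type: int = 40,
    fold_change: float = 8.0,
    base_mean: float = 2.0,
    dispersion: float = 2.0,
    size_multipliers: Sequence[float] | Mapping[str, float] | None = None,
    cells_per_type: int = 100,
    n_samples: int = 2,
    seed: int | None = None,
    type_labels: Sequence[str] | None = None,
) -> SingleCellDataset:
    """Negative-binomial synthetic single-cell counts with planted marker structure.

    Gene ``mk_<type>_<i>`` has mean ``fold_change * base_mean`` in its own
    type and ``base_mean`` elsewhere; background genes ``bg_<i>`` have mean
    ``base_mean`` everywhere. Every cell's expected counts are multiplied by
    its type's size multiplier, so per-type library sizes scale accordingly.
    Cells are assigned cyclically to ``n_samples`` samples within each type.
    """
    if n_types < 2:
        raise ValidationError("n_types must be >= 2")
    if markers_per_type < 1:
        raise ValidationError("markers_per_type must be >= 1")
    if fold_change <= 1:
        raise ValidationError("fold_change must be > 1")
    if base_mean <= 0 or dispersion <= 0:
        raise ValidationError("base_mean and dispersion must be positive")
    if cells_per_type < 1 or n_samples < 1:
        raise ValidationError("cells_per_type and n_samples must be >= 1")
    if n_genes < n_types * markers_per_type:
        raise ValidationError(
            f"n_genes ({n_genes}) must be >= n_types * markers_per_type "
            f"({n_types * markers_per_type})"
        )
    if type_labels is None:
        type_labels = [f"type{k}" for k in range(n_types)]
    type_labels = [str(t) for t in type_labels]
    if len(type_labels) != n_types:
        raise ValidationError("type_labels length must equal n_types")
    if size_multipliers is None:
        multipliers = {t: 1.0 for t in type_labels}
    elif isinstance(size_multipliers, Mapping):
        multipliers = {str(k): float(v) for k, v in size_multipliers.items()}
    else:
        if len(size_multipliers) != n_types:
            raise ValidationError("size_multipliers length must equal n_types")
        multipliers = {t: float(m) for t, m in zip(type_labels, size_multipliers)}
    missing = [t for t in type_labels if t not in multipliers]
    if missing:
        raise LabelError(f"missing size multipliers for types: {missing}")
    if any(m <= 0 for m in multipliers.values()):
        raise ValidationError("size multipliers must be positive")

    genes = [
        f"mk_{t}_{i:03d}" for t in type_labels for i in range(markers_per_type)
    ] + [f"bg_{i:05d}" for i in range(n_genes - n_types * markers_per_type)]

    mean_matrix = np.full((n_genes, n_types), base_mean, dtype=float)
    for k in range(n_types):
        start = k * markers_per_type
        mean_matrix[start : start + markers_per_type, k] = fold_change * base_mean

    rng = np.random.default_rng(seed)
    blocks = []
    cell_ids: list[str] = []
    annotations: list[dict] = []
    for k, label in enumerate(type_labels):
        mu = mean_matrix[:, k][:, None] * multipliers[label]  # genes x 1
        prob = dispersion / (dispersion + mu)
        draws = rng.negative_binomial(dispersion, np.broadcast_to(prob, (n_genes, cells_per_type)))
        blocks.append(draws)
        for i in range(cells_per_type):
            cid = f"{label}_c{i:04d}"
            cell_ids.append(cid)
            annotations.append(
                {"cell_id": cid, "cell_type": label, "sample": f"sample{i % n_samples}"}
            )
    counts = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=pd.Index(genes, name="gene"),
        columns=pd.Index(cell_ids, name="cell_id"),
    )
    cells = pd.DataFrame(annotations).set_index("cell_id")
    return SingleCellDataset(counts=counts, cells=cells)


def planted_markers(dataset: SingleCellDataset) -> dict[str, list[str]]:
    """Recover the planted marker structure of :func:`generate_synthetic_sc` output."""
    planted: dict[str, list[str]] = {}
    for gene in dataset.genes:
        if str(gene).startswith("mk_"):
            label = str(gene)[3 : str(gene).rfind("_")]
            planted.setdefault(label, []).append(str(gene))
    return planted


@dataclass(eq=False)
class ShuffleDesign:
    """The five-term shuffle: pseudobulk-side Z/s/P versus deconvolution-side Z/s."""

    z_pseudobulk: CellTypeReference
    s_pseudobulk: CellScaleFactors | ScaleFactorTable | Mapping[str, float] | None
    p_pseudobulk: ProportionMatrix
    z_deconvolution: CellTypeReference
    s_deconvolution: CellScaleFactors | ScaleFactorTable | Mapping[str, float] | None
    noise: str = "none"
    dispersion: float | None = None
    seed: int | None = None

    def matched_terms(self) -> dict[str, bool]:
        s_pb = _as_factors(self.s_pseudobulk)
        s_dec = _as_factors(self.s_deconvolution)
        z_matched = self.z_pseudobulk.values.equals(self.z_deconvolution.values)
        if s_pb is None and s_dec is None:
            s_matched = True
        elif s_pb is None or s_dec is None:
            s_matched = False
        else:
            s_matched = s_pb.factors == s_dec.factors
        return {"Z": bool(z_matched), "S": bool(s_matched)}


def run_shuffle_experiment(
    design: ShuffleDesign,
    algorithm: str = "nnls",
    registry: AlgorithmRegistry | None = None,
) -> EvaluationReport:
    """Build Y from the pseudobulk-side terms, deconvolve with the other side.

    The report's single condition is labeled by which terms matched, and the
    predictions are evaluated against the generating proportions.
    """
    pb_types = set(design.z_pseudobulk.cell_types)
    dec_types = set(design.z_deconvolution.cell_types)
    if pb_types != dec_types:
        raise LabelError(
            "incompatible cell-type sets between pseudobulk and deconvolution references: "
            f"{sorted(pb_types)} vs {sorted(dec_types)}"
        )
    bulk = generate_pseudobulk(
        design.z_pseudobulk,
        design.s_pseudobulk,
        design.p_pseudobulk,
        noise=design.noise,
        dispersion=design.dispersion,
        seed=design.seed,
    )
    result = run_deconvolution(
        bulk,
        design.z_deconvolution,
        factors=design.s_deconvolution,
        algorithm=algorithm,
        registry=registry,
    )
    matched = design.matched_terms()
    condition = "+".join(
        f"{term}_{'matched' if ok else 'shuffled'}" for term, ok in matched.items()
    )
    report = evaluate_predictions(
        design.p_pseudobulk,
        {condition: result},
        metadata={
            "experiment": "shuffle",
            "algorithm": algorithm,
            "matched_terms": matched,
            "noise": design.noise,
            "seed": design.seed,
        },
    )
    return report
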