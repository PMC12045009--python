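"""Algorithm registry and solvers estimating proportions P from Y and Z.

Each solver fits one bulk sample at a time: nonnegative least squares on
``min ||Z p - y||`` followed by division by the coefficient sum, which places
the estimate on the probability simplex. Cell-size correction happens
upstream, by rescaling the reference (``Z' = Z @ diag(s)``) before solving;
without it the solution is the RNA fraction ``s*p / sum(s*p)``, not the cell
fraction ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import LabelError, ValidationError
from .io_formats import ScaleFactorTable
from .model import (
    BulkMatrix,
    CellScaleFactors,
    CellTypeReference,
    ProportionMatrix,
    rescale_reference,
)


@dataclass(eq=False)
class DeconvolutionResult:
    """Estimated proportions plus fit provenance for one run."""

    proportions: ProportionMatrix
    algorithm: str
    scaled: bool = False
    factors_used: ScaleFactorTable | None = None
    residual_norm: pd.Series | None = None
    genes_used: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual_norm is not None and (self.residual_norm < 0).any():
            raise ValidationError("residual norms must be nonnegative")


SolverFn = Callable[[BulkMatrix, CellTypeReference, Mapping], DeconvolutionResult]


@dataclass(frozen=True)
class AlgorithmSpec:
    """Registry entry: a named, deterministic solver with an options schema."""

    name: str
    solver: SolverFn
    requires_reference: bool = True
    options_schema: Mapping[str, str] = field(default_factory=dict)


class AlgorithmRegistry:
    """Name-keyed collection of deconvolution algorithms."""

    def __init__(self) -> None:
        self._specs: dict[str, AlgorithmSpec] = {}

    def register(self, spec: AlgorithmSpec) -> "AlgorithmRegistry":
        if spec.name in self._specs:
            raise ValidationError(f"algorithm {spec.name!r} is already registered")
        self._specs[spec.name] = spec
        return self

    def get(self, name: str) -> AlgorithmSpec:
        if name not in self._specs:
            raise LabelError(
                f"unknown algorithm {name!r}; registered: {sorted(self._specs)}"
            )
        return self._specs[name]

    def names(self) -> list[str]:
        return sorted(self._specs)


def register_algorithm(registry: AlgorithmRegistry, spec: AlgorithmSpec) -> AlgorithmRegistry:
    return registry.register(spec)


def list_algorithms(registry: AlgorithmRegistry) -> list[str]:
    return registry.names()


def align_markers(
    bulk: BulkMatrix, reference: CellTypeReference
) -> tuple[BulkMatrix, CellTypeReference, dict]:
    """Restrict both matrices to their gene intersection, in reference order.

    Returns the aligned pair plus a log of how many genes each side dropped.
    """
    shared = [g for g in reference.genes if g in set(bulk.genes)]
    if not shared:
        raise LabelError("bulk and reference share no genes")
    log = {
        "n_shared": len(shared),
        "n_dropped_bulk": int(bulk.shape[0] - len(shared)),
        "n_dropped_reference": int(reference.values.shape[0] - len(shared)),
    }
    aligned_bulk = BulkMatrix(bulk.values.loc[shared])
    aligned_ref = CellTypeReference(reference.values.loc[shared], scaled=reference.scaled)
    return aligned_bulk, aligned_ref, log


def _solve_per_sample(
    bulk: BulkMatrix,
    reference: CellTypeReference,
    design: np.ndarray,
    row_weights: np.ndarray | None,
    algorithm: str,
) -> DeconvolutionResult:
    if not bulk.genes.equals(reference.genes):
        raise LabelError("bulk and reference genes are not aligned; call align_markers first")
    if reference.n_types < 2:
        raise ValidationError("deconvolution requires at least 2 cell types")
    y_all = bulk.values.to_numpy(dtype=float)
    props = np.empty((reference.n_types, bulk.shape[1]))
    residuals = np.empty(bulk.shape[1])
    for j, sample in enumerate(bulk.samples):
        y = y_all[:, j]
        if not (y > 0).any():
            raise ValidationError(f"bulk sample {sample!r} is all zeros")
        if row_weights is not None:
            w = np.sqrt(row_weights)
            coef, resid = scipy.optimize.nnls(design * w[:, None], y * w)
        else:
            coef, resid = scipy.optimize.nnls(design, y)
        total = coef.sum()
        if total <= 0:
            raise ValidationError(
                f"NNLS returned an all-zero solution for sample {sample!r} (degenerate reference)"
            )
        props[:, j] = coef / total
        residuals[j] = resid
    proportions = ProportionMatrix(
        pd.DataFrame(props, index=reference.cell_types, columns=bulk.samples)
    )
    return DeconvolutionResult(
        proportions=proportions,
        algorithm=algorithm,
        scaled=reference.scaled,
        residual_norm=pd.Series(residuals, index=bulk.samples, name="residual_norm"),
        genes_used=[str(g) for g in reference.genes],
    )


def deconvolute_nnls(
    bulk: BulkMatrix, reference: CellTypeReference, options: Mapping | None = None
) -> DeconvolutionResult:
    """Per-sample NNLS fit, then division by the coefficient sum (simplex)."""
    design = reference.values.to_numpy(dtype=float)
    return _solve_per_sample(bulk, reference, design, None, "nnls")


def deconvolute_weighted_nnls(
    bulk: BulkMatrix, reference: CellTypeReference, options: Mapping | None = None
) -> DeconvolutionResult:
    """Weighted NNLS: ``min ||W^{1/2}(Z p - y)||``, then simplex normalization.

    ``options["weights"]`` gives per-gene positive weights aligned to the
    reference gene order. Without it, weights are variance-derived from the
    bulk matrix as ``1 / (var_g + nu)`` with ridge
    ``nu = mean(var) * options.get("ridge_scale", 1e-3)``; when every gene
    variance is zero (e.g. a single sample) weights fall back to uniform.
    With uniform weights the result equals :func:`deconvolute_nnls` exactly.
    """
    options = dict(options or {})
    weights = options.get("weights")
    if weights is None:
        var = bulk.values.to_numpy(dtype=float).var(axis=1, ddof=0)
        nu = var.mean() * float(options.get("ridge_scale", 1e-3))
        if nu <= 0:
            weights = np.ones(bulk.shape[0])
        else:
            weights = 1.0 / (var + nu)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (bulk.shape[0],):
        raise ValidationError(
            f"weights must have one entry per gene ({bulk.shape[0]}), got shape {weights.shape}"
        )
    if (weights <= 0).any() or not np.isfinite(weights).all():
        raise ValidationError("weights must be positive and finite")
    design = reference.values.to_numpy(dtype=float)
    return _solve_per_sample(bulk, reference, design, weights, "wnnls")


def default_registry() -> AlgorithmRegistry:
    """Registry with the built-in solvers ("nnls" default, "wnnls")."""
    registry = AlgorithmRegistry()
    registry.register(AlgorithmSpec(name="nnls", solver=deconvolute_nnls))
    registry.register(
        AlgorithmSpec(
            name="wnnls",
            solver=deconvolute_weighted_nnls,
            options_schema={"weights": "per-gene positive reals", "ridge_scale": "float"},
        )
    )
    return registry


def run_deconvolution(
    bulk: BulkMatrix,
    reference: CellTypeReference,
    factors: ScaleFactorTable | CellScaleFactors | Mapping[str, float] | None = None,
    algorithm: str = "nnls",
    options: Mapping | None = None,
    registry: AlgorithmRegistry | None = None,
) -> DeconvolutionResult:
    """Full pipeline: align genes, optionally rescale the reference, solve.

    With ``factors=None`` (or all-ones) the output is bit-identical to the
    unscaled run; the result records whether scaling was applied and with
    which factors.
    """
    registry = registry or default_registry()
    spec = registry.get(algorithm)
    aligned_bulk, aligned_ref, _ = align_markers(bulk, reference)
    factors_table: ScaleFactorTable | None = None
    if factors is not None:
        if isinstance(factors, ScaleFactorTable):
            factors_table = factors
            cell_factors = factors.to_factors()
        elif isinstance(factors, CellScaleFactors):
            cell_factors = factors
            factors_table = ScaleFactorTable.from_mapping(factors.factors)
        else:
            cell_factors = CellScaleFactors(dict(factors))
            factors_table = ScaleFactorTable.from_mapping(cell_factors.factors)
        aligned_ref = rescale_reference(aligned_ref, cell_factors)
    result = spec.solver(aligned_bulk, aligned_ref, options or {})
    result.scaled = factors is not None
    result.factors_used = factors_table
    return result
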