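"""Error, RMSE, bias, and correlation metrics comparing known and predicted proportions."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import LabelError, ValidationError
from .model import ProportionMatrix

RECORD_COLUMNS = ["condition", "sample", "cell_type", "known", "predicted", "error", "signed_bias"]


def _aligned(known: ProportionMatrix, predicted: ProportionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(known.cell_types) != set(predicted.cell_types):
        raise LabelError(
            f"cell-type label mismatch: known={sorted(known.cell_types)} "
            f"predicted={sorted(predicted.cell_types)}"
        )
    if set(known.samples) != set(predicted.samples):
        raise LabelError(
            f"sample label mismatch: known={sorted(known.samples)} "
            f"predicted={sorted(predicted.samples)}"
        )
    k = known.values
    p = predicted.values.reindex(index=k.index, columns=k.columns)
    return k, p


def per_type_error(known: ProportionMatrix, predicted: ProportionMatrix) -> pd.DataFrame:
    """Entrywise absolute error ``|known - predicted|`` (types x samples)."""
    k, p = _aligned(known, predicted)
    return (k - p).abs()


def rmse(
    known: ProportionMatrix,
    predicted: ProportionMatrix,
    over: str = "sample",
) -> pd.Series | float:
    """Root mean squared error between known and predicted proportions.

    ``over="sample"`` averages squared errors over the K cell types within
    each sample (a Series indexed by sample); ``over="pooled"`` averages over
    all (type, sample) pairs (a float).
    """
    k, p = _aligned(known, predicted)
    if k.shape[0] == 0:
        raise ValidationError("cannot compute RMSE over zero cell types")
    sq = (k - p) ** 2
    if over == "sample":
        return np.sqrt(sq.mean(axis=0))
    if over == "pooled":
        return float(np.sqrt(sq.to_numpy().mean()))
    raise ValidationError(f"unknown RMSE pooling mode: {over!r}")


def combine_types(
    proportions: ProportionMatrix,
    combinations: Mapping[str, list[str]],
    keep_rest: bool = True,
) -> ProportionMatrix:
    """Sum groups of cell-type rows into derived entries (e.g. neuron = Excit + Inhib).

    Combined source rows are removed; with ``keep_rest`` the untouched rows are
    retained, so a full partition stays on the simplex.
    """
    df = proportions.values
    used: set[str] = set()
    rows: dict[str, pd.Series] = {}
    for new_label, members in combinations.items():
        missing = [m for m in members if m not in df.index]
        if missing:
            raise LabelError(f"cannot combine into {new_label!r}: missing rows {missing}")
        rows[new_label] = df.loc[members].sum(axis=0)
        used.update(members)
    if keep_rest:
        for label in df.index:
            if label not in used:
                rows[str(label)] = df.loc[label]
    out = pd.DataFrame(rows).T
    out.columns = df.columns
    return ProportionMatrix(out)


@dataclass(eq=False)
class EvaluationReport:
    """Long-format evaluation of one or more prediction conditions.

    ``records`` has one row per (condition, sample, cell_type) with known,
    predicted, absolute error and signed bias (predicted - known).
    ``sample_rmse`` holds per-sample RMSE over cell types; ``summaries`` one
    row per condition (pooled RMSE, mean per-sample RMSE, mean signed bias);
    ``correlations`` per (condition, cell_type) Pearson r across samples.
    """

    records: pd.DataFrame
    sample_rmse: pd.DataFrame
    summaries: pd.DataFrame
    correlations: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records.empty:
            raise ValidationError("evaluation report has an empty per-sample record section")
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"report records missing columns: {missing}")
        if (self.records["error"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("errors must be nonnegative")

    def to_dict(self) -> dict:
        def frame_records(df: pd.DataFrame) -> list[dict]:
            out = []
            for rec in df.to_dict(orient="records"):
                clean = {}
                for key, value in rec.items():
                    if isinstance(value, float) and math.isnan(value):
                        clean[key] = None
                    elif isinstance(value, (np.integer,)):
                        clean[key] = int(value)
                    elif isinstance(value, (np.floating,)):
                        clean[key] = float(value)
                    else:
                        clean[key] = value
                out.append(clean)
            return out

        return {
            "metadata": self.metadata,
            "records": frame_records(self.records),
            "sample_rmse": frame_records(self.sample_rmse),
            "summaries": frame_records(self.summaries),
            "correlations": frame_records(self.correlations),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "EvaluationReport":
        return cls(
            records=pd.DataFrame(payload["records"]),
            sample_rmse=pd.DataFrame(payload["sample_rmse"]),
            summaries=pd.DataFrame(payload["summaries"]),
            correlations=pd.DataFrame(payload["correlations"]),
            metadata=dict(payload.get("metadata", {})),
        )

    def equals(self, other: "EvaluationReport", rtol: float = 1e-12) -> bool:
        """Structural equality up to floating-point text round trip."""
        try:
            for mine, theirs in (
                (self.records, other.records),
                (self.sample_rmse, other.sample_rmse),
                (self.summaries, other.summaries),
                (self.correlations, other.correlations),
            ):
                mine = mine.reset_index(drop=True)
                theirs = theirs.reset_index(drop=True)
                if list(mine.columns) != list(theirs.columns) or len(mine) != len(theirs):
                    return False
                for col in mine.columns:
                    a, b = mine[col], theirs[col]
                    if pd.api.types.is_numeric_dtype(a) and pd.api.types.is_numeric_dtype(b):
                        av = a.to_numpy(dtype=float)
                        bv = b.to_numpy(dtype=float)
                        both_nan = np.isnan(av) & np.isnan(bv)
                        close = np.isclose(av, bv, rtol=rtol, atol=0.0) | both_nan
                        if not close.all():
                            return False
                    else:
                        if not (a.astype(object).where(a.notna(), None)
                                .equals(b.astype(object).where(b.notna(), None))):
                            return False
        except Exception:
            return False
        return self.metadata == other.metadata


def evaluate_predictions(
    known: ProportionMatrix,
    results: Mapping[str, "ProportionMatrix | object"],
    metadata: Mapping | None = None,
) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` for named prediction conditions.

    ``results`` maps condition name to either a :class:`ProportionMatrix` or a
    deconvolution result object exposing ``.proportions``. Pearson correlation
    between known and predicted across samples is reported per cell type when
    there are >= 3 samples; with fewer samples, or zero variance, it is
    recorded as not available rather than erroring.
    """
    if not results:
        raise ValidationError("no prediction conditions supplied")
    record_rows: list[dict] = []
    rmse_rows: list[dict] = []
    summary_rows: list[dict] = []
    corr_rows: list[dict] = []

    for condition in results:
        predicted = results[condition]
        proportions = getattr(predicted, "proportions", predicted)
        if not isinstance(proportions, ProportionMatrix):
            raise ValidationError(
                f"condition {condition!r} is neither a ProportionMatrix nor a result with .proportions"
            )
        k, p = _aligned(known, proportions)
        for sample in k.columns:
            for cell_type in k.index:
                kv = float(k.at[cell_type, sample])
                pv = float(p.at[cell_type, sample])
                record_rows.append(
                    {
                        "condition": condition,
                        "sample": str(sample),
                        "cell_type": str(cell_type),
                        "known": kv,
                        "predicted": pv,
                        "error": abs(kv - pv),
                        "signed_bias": pv - kv,
                    }
                )
        per_sample = np.sqrt(((k - p) ** 2).mean(axis=0))
        for sample, value in per_sample.items():
            rmse_rows.append({"condition": condition, "sample": str(sample), "rmse": float(value)})
        summary_rows.append(
            {
                "condition": condition,
                "rmse_pooled": float(np.sqrt(((k - p) ** 2).to_numpy().mean())),
                "rmse_mean_per_sample": float(per_sample.mean()),
                "mean_signed_bias": float((p - k).to_numpy().mean()),
            }
        )
        n_samples = k.shape[1]
        for cell_type in k.index:
            kv = k.loc[cell_type].to_numpy(dtype=float)
            pv = p.loc[cell_type].to_numpy(dtype=float)
            if n_samples < 3:
                corr_rows.append(
                    {"condition": condition, "cell_type": str(cell_type),
                     "pearson_r": None, "note": "too few samples"}
                )
            elif np.std(kv) == 0 or np.std(pv) == 0:
                corr_rows.append(
                    {"condition": condition, "cell_type": str(cell_type),
                     "pearson_r": None, "note": "zero variance"}
                )
            else:
                r = float(np.corrcoef(kv, pv)[0, 1])
                corr_rows.append(
                    {"condition": condition, "cell_type": str(cell_type), "pearson_r": r, "note": ""}
                )

    summaries = pd.DataFrame(summary_rows).sort_values("rmse_pooled", kind="stable").reset_index(drop=True)
    return EvaluationReport(
        records=pd.DataFrame(record_rows, columns=RECORD_COLUMNS),
        sample_rmse=pd.DataFrame(rmse_rows, columns=["condition", "sample", "rmse"]),
        summaries=summaries,
        correlations=pd.DataFrame(corr_rows, columns=["condition", "cell_type", "pearson_r", "note"]),
        metadata=dict(metadata or {}),
    )
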