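# scdecon

Reference-based bulk RNA-seq deconvolution with cell-size scale-factor
correction.

Bulk expression is modeled as `Y = Z @ diag(s) @ P`, where `Z` is a cell-type
signature matrix (mean marker-gene expression per type, built from
single-cell/single-nucleus data), `P` holds per-sample cell-type proportions
on the probability simplex, and `s` contains per-type cell-size scale
factors. Solving `Y = Z P` without `s` estimates the fraction of RNA
attributable to each cell type; when cell sizes differ (e.g. neurons are much
larger than glia) this systematically over-predicts the large types.
Rescaling the reference first (`Z' = Z @ diag(s)`) recovers the cell
fraction instead.

## What's inside

| Module | Purpose |
| --- | --- |
| `scdecon.model` | Domain types (`BulkMatrix`, `CellTypeReference`, `CellScaleFactors`, `ProportionMatrix`, `SingleCellDataset`), reference rescaling, label aggregation, known proportions |
| `scdecon.io_formats` | MatrixMarket + TSV annotation readers/writers, dense TSV matrices, scale-factor/measurement tables, JSON evaluation reports |
| `scdecon.markers` | Mean-ratio marker scoring/selection, bulk sample QC filter, exact library-size downsampling |
| `scdecon.reference` | Signature-matrix construction; scale factors from library sizes, imaging measurements (nucleus area / marker copies), or manual tables |
| `scdecon.deconvolution` | Algorithm registry (`nnls` default, `wnnls`), gene alignment, per-sample NNLS solvers with simplex normalization |
| `scdecon.simulate` | Pseudobulk generation (exact or Poisson/negative-binomial noise), synthetic single-cell generator with planted markers and size multipliers, term-shuffle experiments |
| `scdecon.evaluate` | Absolute error, per-sample and pooled RMSE, signed bias, Pearson correlation, report assembly |
| `scdecon.cli` | `scdecon` command-line interface |

## Quick start (Python)

```python
import pandas as pd
import scdecon as sd

# synthetic single-cell data with neurons ~10/3 larger than glia
ds = sd.generate_synthetic_sc(
    n_types=2, n_genes=150, markers_per_type=40, fold_change=8.0,
    size_multipliers=[10.0, 3.0], cells_per_type=300, seed=1,
    type_labels=["neuron", "glial"],
)
markers = sd.select_markers(ds, n_per_type=40)
z = sd.build_reference(ds, markers)
s = sd.manual_scale_factors({"neuron": 10, "glial": 3})

p = sd.ProportionMatrix(pd.DataFrame({"s1": [0.5, 0.5]}, index=["neuron", "glial"]))
y = sd.generate_pseudobulk(z, s, p)

biased = sd.run_deconvolution(y, z)               # RNA fraction: ~ (10/13, 3/13)
corrected = sd.run_deconvolution(y, z, factors=s)  # cell fraction: (0.5, 0.5)
report = sd.evaluate_predictions(p, {"noscale": biased, "withscale": corrected})
print(report.summaries)
```

## Command line

Subcommands mirror the pipeline stages; every run writes its outputs plus a
`run_metadata.json` sidecar into `--out-dir`:

```sh
scdecon markers select   --counts-mtx counts.mtx --genes genes.tsv --cells cells.tsv \
                         --n-per-type 40 --out-dir out/markers
scdecon reference build  --counts-mtx counts.mtx --genes genes.tsv --cells cells.tsv \
                         --markers out/markers/markers.tsv --out-dir out/ref
scdecon sizes estimate   --mode manual --factor neuron=10 --factor glial=3 --out-dir out/sizes
scdecon pseudobulk make  --reference out/ref/reference.tsv --proportions p.tsv \
                         --scale-factors out/sizes/scale_factors.tsv --out-dir out/pb
scdecon deconvolute run  --bulk out/pb/pseudobulk.tsv --reference out/ref/reference.tsv \
                         --scale-factors out/sizes/scale_factors.tsv --out-dir out/decon
scdecon evaluate compare --known p.tsv --pred withscale=out/decon/proportions.tsv \
                         --out-dir out/eval
scdecon shuffle run      --z-pseudobulk z.tsv --s-pseudobulk s1.tsv --p-pseudobulk p.tsv \
                         --z-deconvolution z.tsv --s-deconvolution s2.tsv --out-dir out/shuffle
```

`sizes estimate` also supports `--mode library` (median per-cell marker
counts per type, optionally `--normalize` so the smallest type is 1) and
`--mode measurements` (median nucleus area or marker copies, with an
out-of-focus cutoff `--max-nucleus-area`, default 78).

## File formats

All on-disk formats are plain text: MatrixMarket (`.mtx`) for sparse counts
with TSV gene/cell annotations; dense TSV (first column = row identifier,
header = column labels) for bulk, reference and proportion matrices; TSV for
scale factors (`cell_type`, `factor`, `source`) and marker sets
(`cell_type`, `gene`, `score`, `rank`); JSON for evaluation reports and run
sidecars.
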