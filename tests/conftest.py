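import numpy as np
import pandas as pd
import pytest

import scdecon as sd


@pytest.fixture
def toy_reference() -> sd.CellTypeReference:
    """3 genes x 2 types, full column rank."""
    return sd.CellTypeReference(
        pd.DataFrame(
            [[2.0, 1.0], [4.0, 3.0], [1.0, 5.0]],
            index=["g1", "g2", "g3"],
            columns=["neuron", "glial"],
        )
    )


@pytest.fixture
def toy_proportions() -> sd.ProportionMatrix:
    return sd.ProportionMatrix(
        pd.DataFrame(
            {"s1": [0.5, 0.5], "s2": [0.8, 0.2]},
            index=["neuron", "glial"],
        )
    )


@pytest.fixture
def neuron_glial_factors() -> sd.CellScaleFactors:
    return sd.CellScaleFactors({"neuron": 10.0, "glial": 3.0})


@pytest.fixture
def toy_dataset() -> sd.SingleCellDataset:
    """4 genes x 6 cells, 2 types x 2 samples, hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "c1": [2, 4, 0, 1],
            "c2": [4, 6, 1, 0],
            "c3": [0, 1, 5, 7],
            "c4": [1, 0, 7, 5],
            "c5": [3, 5, 0, 2],
            "c6": [0, 2, 6, 6],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    cells = pd.DataFrame(
        {
            "cell_type": ["A", "A", "B", "B", "A", "B"],
            "sample": ["s1", "s1", "s1", "s1", "s2", "s2"],
        },
        index=["c1", "c2", "c3", "c4", "c5", "c6"],
    )
    return sd.SingleCellDataset(counts=counts, cells=cells)


@pytest.fixture
def synthetic_dataset() -> sd.SingleCellDataset:
    """Mid-size generator output shared by marker/reference tests."""
    return sd.generate_synthetic_sc(
        n_types=3,
        n_genes=220,
        markers_per_type=20,
        fold_change=8.0,
        base_mean=2.0,
        cells_per_type=120,
        n_samples=3,
        seed=20240917,
    )


def random_full_rank_reference(rng: np.random.Generator, n_genes: int, types) -> sd.CellTypeReference:
    """Random strictly positive reference; strictly positive => full column rank a.s."""
    values = rng.lognormal(mean=1.0, sigma=1.0, size=(n_genes, len(types)))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    return sd.CellTypeReference(pd.DataFrame(values, index=genes, columns=list(types)))
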