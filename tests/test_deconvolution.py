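import numpy as np
import pandas as pd
import pytest

import scdecon as sd
from scdecon.errors import LabelError, ValidationError
from conftest import random_full_rank_reference


def grid_search_simplex_k2(z: np.ndarray, y: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Independent oracle: exhaustive search over the K=2 simplex."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    candidates = np.stack([grid, 1.0 - grid])  # 2 x n
    residuals = ((z @ candidates - y[:, None]) ** 2).sum(axis=0)
    best = candidates[:, residuals.argmin()]
    return best


class TestAlignMarkers:
    def test_intersection_in_reference_order(self):
        bulk = sd.BulkMatrix(pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0]}, index=["g1", "g2", "g3"]
        ))
        ref = sd.CellTypeReference(pd.DataFrame(
            {"A": [1.0, 2.0, 3.0], "B": [3.0, 2.0, 1.0]}, index=["g3", "g2", "g4"]
        ))
        ab, ar, log = sd.align_markers(bulk, ref)
        assert list(ab.genes) == ["g3", "g2"]
        assert list(ar.genes) == ["g3", "g2"]
        assert log == {"n_shared": 2, "n_dropped_bulk": 1, "n_dropped_reference": 1}

    def test_identical_sets_unchanged(self, toy_reference):
        bulk = sd.BulkMatrix(toy_reference.values.rename(columns={"neuron": "s1", "glial": "s2"}))
        ab, ar, log = sd.align_markers(bulk, toy_reference)
        assert (ab.values == bulk.values).all().all()
        assert (ar.values == toy_reference.values).all().all()
        assert log["n_dropped_bulk"] == 0

    def test_disjoint_sets_error(self, toy_reference):
        bulk = sd.BulkMatrix(pd.DataFrame({"s1": [1.0]}, index=["other"]))
        with pytest.raises(LabelError, match="no genes"):
            sd.align_markers(bulk, toy_reference)


class TestNnls:
    def test_exact_column_match(self, toy_reference):
        y = sd.BulkMatrix(toy_reference.values[["neuron"]].rename(columns={"neuron": "s1"}))
        result = sd.deconvolute_nnls(y, toy_reference)
        np.testing.assert_allclose(
            result.proportions.values["s1"].to_numpy(), [1.0, 0.0], atol=1e-12
        )
        assert result.residual_norm["s1"] == pytest.approx(0.0, abs=1e-10)

    def test_hand_solved_overdetermined_system(self):
        # DERIVED via normal equations: Z'Z=[[2,1],[1,2]], Z'y=(1.6,1.4)
        # => p=(0.6,0.4); verified below against the grid-search oracle too.
        z = sd.CellTypeReference(pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]], index=["g1", "g2", "g3"], columns=["A", "B"]
        ))
        y = sd.BulkMatrix(pd.DataFrame({"s1": [0.6, 0.4, 1.0]}, index=["g1", "g2", "g3"]))
        result = sd.deconvolute_nnls(y, z)
        np.testing.assert_allclose(result.proportions.values["s1"].to_numpy(), [0.6, 0.4], atol=1e-10)
        oracle = grid_search_simplex_k2(z.values.to_numpy(), y.values["s1"].to_numpy())
        np.testing.assert_allclose(result.proportions.values["s1"].to_numpy(), oracle, atol=2e-4)

    def test_rna_fraction_bias_and_correction(self):
        # DERIVED closed form: solving without scaling returns q = s*p/sum(s*p).
        rng = np.random.default_rng(10)
        z = random_full_rank_reference(rng, 50, ["neuron", "glial"])
        s = sd.CellScaleFactors({"neuron": 10.0, "glial": 3.0})
        p = sd.ProportionMatrix(pd.DataFrame({"s1": [0.5, 0.5]}, index=["neuron", "glial"]))
        y = sd.generate_pseudobulk(z, s, p)
        unscaled = sd.deconvolute_nnls(y, z)
        np.testing.assert_allclose(
            unscaled.proportions.values["s1"].to_numpy(), [10 / 13, 3 / 13], atol=1e-8
        )
        scaled = sd.deconvolute_nnls(y, sd.rescale_reference(z, s))
        np.testing.assert_allclose(scaled.proportions.values["s1"].to_numpy(), [0.5, 0.5], atol=1e-8)

    def test_all_zero_sample_errors(self, toy_reference):
        y = sd.BulkMatrix(pd.DataFrame({"s1": [0.0, 0.0, 0.0]}, index=["g1", "g2", "g3"]))
        with pytest.raises(ValidationError, match="all zeros"):
            sd.deconvolute_nnls(y, toy_reference)

    def test_k1_reference_rejected(self):
        ref = sd.CellTypeReference(pd.DataFrame({"A": [1.0, 2.0]}, index=["g1", "g2"]))
        y = sd.BulkMatrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"]))
        with pytest.raises(ValidationError, match="at least 2"):
            sd.deconvolute_nnls(y, ref)


class TestWeightedNnls:
    def test_uniform_weights_equal_plain_nnls(self, toy_reference, toy_proportions):
        y = sd.generate_pseudobulk(toy_reference, None, toy_proportions)
        plain = sd.deconvolute_nnls(y, toy_reference)
        weighted = sd.deconvolute_weighted_nnls(
            y, toy_reference, {"weights": np.ones(len(toy_reference.genes))}
        )
        np.testing.assert_allclose(
            weighted.proportions.values.to_numpy(),
            plain.proportions.values.to_numpy(),
            atol=1e-12,
        )

    def test_zero_weight_limit_removes_gene(self):
        # DERIVED oracle: weight 1e-12 on a contaminated gene ~= dropping it.
        rng = np.random.default_rng(17)
        z = random_full_rank_reference(rng, 30, ["A", "B"])
        p = sd.ProportionMatrix(pd.DataFrame({"s1": [0.3, 0.7]}, index=["A", "B"]))
        y = sd.generate_pseudobulk(z, None, p)
        contaminated = y.values.copy()
        contaminated.iloc[0, 0] += 500.0  # corrupt first gene
        y_bad = sd.BulkMatrix(contaminated)
        weights = np.ones(30)
        weights[0] = 1e-12
        down_weighted = sd.deconvolute_weighted_nnls(y_bad, z, {"weights": weights})
        removed = sd.deconvolute_nnls(
            sd.BulkMatrix(contaminated.iloc[1:]),
            sd.CellTypeReference(z.values.iloc[1:], scaled=z.scaled),
        )
        np.testing.assert_allclose(
            down_weighted.proportions.values.to_numpy(),
            removed.proportions.values.to_numpy(),
            atol=1e-6,
        )

    def test_variance_weights_help_on_noisy_pseudobulk(self):
        # Soft property: variance-derived weights beat uniform in >=60% of replicates.
        rng = np.random.default_rng(2718)
        z = random_full_rank_reference(rng, 60, ["A", "B"])
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            p = sd.ProportionMatrix(pd.DataFrame(
                {f"s{j}": [q, 1 - q] for j, q in enumerate(rng.uniform(0.2, 0.8, size=4))},
                index=["A", "B"],
            ))
            y_clean = sd.generate_pseudobulk(z, None, p)
            noisy = y_clean.values.to_numpy().copy()
            # heteroscedastic noise concentrated on a fixed subset of genes
            noisy_genes = slice(0, 12)
            noise = rng.normal(0, noisy[noisy_genes].mean() * 0.8, size=noisy[noisy_genes].shape)
            noisy[noisy_genes] = np.clip(noisy[noisy_genes] + noise, 0, None)
            y = sd.BulkMatrix(pd.DataFrame(noisy, index=y_clean.genes, columns=y_clean.samples))
            unweighted = sd.deconvolute_nnls(y, z)
            weighted = sd.deconvolute_weighted_nnls(y, z)
            if sd.rmse(p, weighted.proportions, over="pooled") < sd.rmse(p, unweighted.proportions, over="pooled"):
                wins += 1
        assert wins >= 0.60 * n_rep

    def test_nonpositive_weight_rejected(self, toy_reference, toy_proportions):
        y = sd.generate_pseudobulk(toy_reference, None, toy_proportions)
        with pytest.raises(ValidationError, match="positive"):
            sd.deconvolute_weighted_nnls(y, toy_reference, {"weights": np.array([1.0, -1.0, 1.0])})


class TestRegistry:
    def test_builtins_listed(self):
        registry = sd.default_registry()
        assert sd.list_algorithms(registry) == ["nnls", "wnnls"]

    def test_duplicate_registration_errors(self):
        registry = sd.default_registry()
        with pytest.raises(ValidationError, match="nnls"):
            sd.register_algorithm(
                registry, sd.AlgorithmSpec(name="nnls", solver=sd.deconvolute_nnls)
            )

    def test_user_algorithm_dispatches_end_to_end(self, toy_reference, toy_proportions):
        def uniform_solver(bulk, reference, options):
            k = reference.n_types
            values = np.full((k, bulk.shape[1]), 1.0 / k)
            proportions = sd.ProportionMatrix(
                pd.DataFrame(values, index=reference.cell_types, columns=bulk.samples)
            )
            return sd.DeconvolutionResult(proportions=proportions, algorithm="uniform")

        registry = sd.default_registry()
        sd.register_algorithm(registry, sd.AlgorithmSpec(name="uniform", solver=uniform_solver))
        y = sd.generate_pseudobulk(toy_reference, None, toy_proportions)
        result = sd.run_deconvolution(y, toy_reference, algorithm="uniform", registry=registry)
        assert (result.proportions.values.to_numpy() == 0.5).all()


class TestRunDeconvolution:
    def test_none_vs_all_ones_identical(self, toy_reference, toy_proportions):
        y = sd.generate_pseudobulk(toy_reference, None, toy_proportions)
        none_run = sd.run_deconvolution(y, toy_reference, factors=None)
        ones_run = sd.run_deconvolution(
            y, toy_reference, factors={"neuron": 1.0, "glial": 1.0}
        )
        assert (
            none_run.proportions.values.to_numpy() == ones_run.proportions.values.to_numpy()
        ).all()
        assert none_run.scaled is False and ones_run.scaled is True

    def test_exact_recovery_with_matched_factors(self, neuron_glial_factors):
        rng = np.random.default_rng(31)
        z = random_full_rank_reference(rng, 40, ["neuron", "glial"])
        p = sd.ProportionMatrix(pd.DataFrame(
            {f"s{j}": [q, 1 - q] for j, q in enumerate(np.linspace(0.25, 0.8, 17))},
            index=["neuron", "glial"],
        ))
        y = sd.generate_pseudobulk(z, neuron_glial_factors, p)
        result = sd.run_deconvolution(y, z, factors=neuron_glial_factors)
        assert sd.rmse(p, result.proportions, over="pooled") < 1e-8
        assert result.scaled and result.factors_used is not None

    def test_unknown_algorithm_lists_registered(self, toy_reference, toy_proportions):
        y = sd.generate_pseudobulk(toy_reference, None, toy_proportions)
        with pytest.raises(LabelError, match="nnls"):
            sd.run_deconvolution(y, toy_reference, algorithm="mystery")

    def test_bulk_scale_invariance(self, toy_reference, toy_proportions):
        y = sd.generate_pseudobulk(toy_reference, None, toy_proportions)
        scaled_y = sd.BulkMatrix(y.values * 37.5)
        a = sd.run_deconvolution(y, toy_reference)
        b = sd.run_deconvolution(scaled_y, toy_reference)
        np.testing.assert_allclose(
            a.proportions.values.to_numpy(), b.proportions.values.to_numpy(), atol=1e-10
        )

    def test_simplex_output_columns(self, toy_reference):
        rng = np.random.default_rng(55)
        y = sd.BulkMatrix(pd.DataFrame(
            rng.uniform(0.1, 10, size=(3, 5)), index=toy_reference.genes,
            columns=[f"s{j}" for j in range(5)],
        ))
        result = sd.run_deconvolution(y, toy_reference)
        arr = result.proportions.values.to_numpy()
        assert (arr >= 0).all()
        np.testing.assert_allclose(arr.sum(axis=0), 1.0, atol=1e-9)


class TestOracleEquivalence:
    def test_nnls_matches_grid_search_k2(self):
        # 50 random instances, grid step 1e-4, agreement within 2e-4.
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n_genes = int(rng.integers(5, 25))
            z = rng.uniform(0.1, 10.0, size=(n_genes, 2))
            p_true = rng.uniform(0.0, 1.0)
            # small residuals: with large noise the free-sum NNLS ratio and the
            # sum-constrained minimizer legitimately diverge
            y = z @ np.array([p_true, 1 - p_true]) + rng.normal(0, 1e-3, size=n_genes)
            y = np.clip(y, 0, None)
            ref = sd.CellTypeReference(pd.DataFrame(
                z, index=[f"g{i}" for i in range(n_genes)], columns=["A", "B"]
            ))
            bulk = sd.BulkMatrix(pd.DataFrame({"s1": y}, index=ref.genes))
            estimate = sd.deconvolute_nnls(bulk, ref).proportions.values["s1"].to_numpy()
            oracle = grid_search_simplex_k2(z, y)
            np.testing.assert_allclose(estimate, oracle, atol=2e-4)


class TestMismatchLaw:
    def test_closed_form_for_mismatched_factors(self):
        # For noiseless Y = Z diag(s_pb) P solved with Z diag(s_dec):
        # p_hat proportional to (s_pb/s_dec) * p.
        rng = np.random.default_rng(77)
        z = random_full_rank_reference(rng, 45, ["A", "B", "C"])
        s_pb = sd.CellScaleFactors({"A": 10.0, "B": 3.0, "C": 5.0})
        s_dec = sd.CellScaleFactors({"A": 5.0, "B": 3.0, "C": 2.0})
        p = sd.ProportionMatrix(pd.DataFrame({"s1": [0.2, 0.5, 0.3]}, index=["A", "B", "C"]))
        y = sd.generate_pseudobulk(z, s_pb, p)
        result = sd.run_deconvolution(y, z, factors=s_dec)
        expected = np.array([10 / 5 * 0.2, 3 / 3 * 0.5, 5 / 2 * 0.3])
        expected /= expected.sum()
        np.testing.assert_allclose(
            result.proportions.values["s1"].to_numpy(), expected, atol=1e-8
        )

    def test_proportional_factors_recover_exactly(self):
        rng = np.random.default_rng(78)
        z = random_full_rank_reference(rng, 45, ["A", "B"])
        s_pb = sd.CellScaleFactors({"A": 10.0, "B": 3.0})
        s_dec = sd.CellScaleFactors({"A": 20.0, "B": 6.0})  # = 2 * s_pb
        p = sd.ProportionMatrix(pd.DataFrame({"s1": [0.4, 0.6]}, index=["A", "B"]))
        y = sd.generate_pseudobulk(z, s_pb, p)
        result = sd.run_deconvolution(y, z, factors=s_dec)
        np.testing.assert_allclose(
            result.proportions.values["s1"].to_numpy(), [0.4, 0.6], atol=1e-8
        )
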