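import numpy as np
import pandas as pd
import pytest

from icbnotch.io_formats import ExpressionMatrix, ValidationError
from icbnotch.normalization import (
    NormalizationFactors,
    combine_datasets_zscore,
    compute_cpm,
    tmm_factors,
    zscore_genes,
)

# factors of the seeded composition-bias toy matrix below, computed with
# the reference TMM implementation (edgeR 4.0 calcNormFactors)
EDGER_REFERENCE_FACTORS = np.array([1.814421571061, 0.304789910580, 1.808261405483])


def _counts(arr, samples=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=[f"G{i:03d}" for i in range(arr.shape[0])], columns=samples),
        unit="counts",
    )


def composition_biased_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    X = rng.poisson(100.0, size=(100, 3)).astype(float)
    X[0, 1] = 50000.0  # one dominant gene in sample 2
    return _counts(X, ["S1", "S2", "S3"])


class TestCPM:
    def test_two_count_library(self):
        m = _counts([[1.0], [1.0]])
        cpm = compute_cpm(m)
        np.testing.assert_allclose(cpm.values.to_numpy().ravel(), [5e5, 5e5])
        assert cpm.unit == "CPM"

    def test_depth_scaling_invariance(self, random_counts):
        doubled = ExpressionMatrix(values=random_counts.values * 2, unit="counts")
        np.testing.assert_allclose(
            compute_cpm(doubled).values.to_numpy(),
            compute_cpm(random_counts).values.to_numpy(),
            rtol=1e-12,
        )

    def test_columns_sum_to_1e6(self, random_counts):
        cpm = compute_cpm(random_counts)
        np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6, atol=1e-6)

    def test_against_hand_computation(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 50, size=(5, 3)).astype(float)
        m = _counts(X)
        cpm = compute_cpm(m).values.to_numpy()
        # independent elementwise arithmetic
        for j in range(3):
            lib = X[:, j].sum()
            for i in range(5):
                assert abs(cpm[i, j] - X[i, j] / lib * 1e6) < 1e-9

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError, match="library"):
            compute_cpm(_counts([[0.0, 1.0], [0.0, 1.0]]))

    def test_requires_counts_unit(self, small_matrix):
        with pytest.raises(ValidationError, match="counts"):
            compute_cpm(small_matrix)


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = np.arange(1.0, 41.0)
        m = _counts(np.column_stack([col, col]))
        np.testing.assert_allclose(tmm_factors(m).tmm_factors, [1.0, 1.0], atol=1e-12)

    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(80.0, size=60).astype(float) + 1
        m = _counts(np.column_stack([col, col * 3]))
        np.testing.assert_allclose(tmm_factors(m).tmm_factors, [1.0, 1.0], atol=1e-12)

    def test_matches_reference_implementation(self):
        f = tmm_factors(composition_biased_matrix())
        np.testing.assert_allclose(f.tmm_factors, EDGER_REFERENCE_FACTORS, atol=1e-6)

    def test_factors_invariant_to_depth_rescaling(self):
        # M-values and both trims are exactly depth-invariant; the
        # inverse-variance weights depend weakly on absolute counts, so
        # the unweighted factors are exactly invariant and the weighted
        # ones invariant to ~0.1%
        m = composition_biased_matrix()
        rescaled = ExpressionMatrix(
            values=m.values * np.array([1.0, 5.0, 0.5]), unit="counts"
        )
        np.testing.assert_allclose(
            tmm_factors(rescaled, weighted=False).tmm_factors,
            tmm_factors(m, weighted=False).tmm_factors,
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            tmm_factors(rescaled).tmm_factors,
            tmm_factors(m).tmm_factors,
            rtol=1e-2,
        )

    def test_geometric_mean_is_one(self):
        f = tmm_factors(composition_biased_matrix())
        assert abs(np.exp(np.mean(np.log(f.tmm_factors))) - 1.0) < 1e-12

    def test_disjoint_support_names_sample(self):
        X = np.array([[10.0, 0.0], [20.0, 0.0], [0.0, 10.0], [0.0, 30.0]])
        with pytest.raises(ValidationError, match="S"):
            tmm_factors(_counts(X))

    def test_factor_invariants_enforced(self):
        with pytest.raises(ValidationError, match="geometric mean"):
            NormalizationFactors(
                sample_ids=["a", "b"],
                library_sizes=np.array([10.0, 10.0]),
                tmm_factors=np.array([2.0, 2.0]),
            )


class TestZscore:
    def test_hand_example(self):
        m = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["G"], columns=["a", "b", "c"]),
            unit="CPM",
        )
        z = zscore_genes(m)
        # sample-SD convention: SD of (1,2,3) is 1
        np.testing.assert_allclose(z.values.to_numpy().ravel(), [-1.0, 0.0, 1.0])
        assert z.unit == "zscore"

    def test_constant_row_zeroed_with_warning(self):
        m = ExpressionMatrix(
            values=pd.DataFrame([[5.0, 5.0, 5.0]], index=["G"], columns=list("abc")),
            unit="CPM",
        )
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_genes(m)
        np.testing.assert_allclose(z.values.to_numpy(), 0.0)

    def test_rows_centered_and_scaled(self, random_counts):
        z = zscore_genes(compute_cpm(random_counts))
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(values=pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"]), unit="CPM")
        with pytest.raises(ValidationError, match="2 samples"):
            zscore_genes(m)


class TestCombineDatasets:
    def test_self_combination_doubles_columns_keeps_values(self, random_counts):
        cpm = compute_cpm(random_counts)
        a = ExpressionMatrix(values=cpm.values, unit="CPM", dataset_id="d1")
        b = ExpressionMatrix(values=cpm.values, unit="CPM", dataset_id="d2")
        combined = combine_datasets_zscore([a, b])
        assert combined.n_samples == 2 * cpm.n_samples
        half = combined.values.iloc[:, : cpm.n_samples].to_numpy()
        other = combined.values.iloc[:, cpm.n_samples :].to_numpy()
        np.testing.assert_allclose(half, other, atol=1e-12)

    def test_one_gene_datasets_align_after_combination(self):
        a = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 3.0]], index=["G"], columns=["a1", "a2"]),
            unit="CPM",
            dataset_id="A",
        )
        b = ExpressionMatrix(
            values=pd.DataFrame([[10.0, 30.0]], index=["G"], columns=["b1", "b2"]),
            unit="CPM",
            dataset_id="B",
        )
        combined = combine_datasets_zscore([a, b])
        vals = combined.values.loc["G"].to_numpy()
        # each dataset z-scored within itself -> the two pairs coincide
        np.testing.assert_allclose(vals[:2], vals[2:], atol=1e-12)

    def test_per_dataset_gene_means_are_zero(self):
        rng = np.random.default_rng(2)
        mats = []
        for k, n in enumerate((8, 12)):
            vals = rng.poisson(40.0, size=(30, n)).astype(float)
            mats.append(
                ExpressionMatrix(
                    values=pd.DataFrame(
                        vals,
                        index=[f"G{i}" for i in range(30)],
                        columns=[f"d{k}s{j}" for j in range(n)],
                    ),
                    unit="CPM",
                    dataset_id=f"d{k}",
                )
            )
        combined = combine_datasets_zscore(mats)
        for k in range(2):
            cols = combined.sample_datasets[combined.sample_datasets == f"d{k}"].index
            np.testing.assert_allclose(
                combined.values[cols].mean(axis=1), 0.0, atol=1e-9
            )

    def test_empty_gene_intersection_rejected(self):
        a = ExpressionMatrix(values=pd.DataFrame({"s1": [1.0]}, index=["A"]), unit="CPM")
        b = ExpressionMatrix(values=pd.DataFrame({"s2": [1.0]}, index=["B"]), unit="CPM")
        with pytest.raises(ValidationError, match="intersection"):
            combine_datasets_zscore([a, b])
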