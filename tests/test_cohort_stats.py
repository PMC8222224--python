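import numpy as np
import pandas as pd
import pytest
from oracles import chi2_by_hand, fisher_exact_enumeration, mann_whitney_exact_enumeration

from icbnotch.cohort_stats import (
    TwoByTwoTable,
    bh_fdr,
    chi2_2x2,
    fisher_exact_2x2,
    mann_whitney_cb,
    multivariable_benefit_model,
    pearson_correlation,
)
from icbnotch.io_formats import ValidationError
from icbnotch.synthetic import SyntheticCohortConfig, simulate_expression_cohort
from icbnotch.workflows import benefit_covariates


def _series(cb_vals, ncb_vals):
    vals = list(cb_vals) + list(ncb_vals)
    idx = [f"s{i}" for i in range(len(vals))]
    benefit = ["CB"] * len(cb_vals) + ["NCB"] * len(ncb_vals)
    return pd.Series(vals, index=idx), pd.Series(benefit, index=idx)


class TestMannWhitney:
    def test_exact_hand_example(self):
        values, benefit = _series([5, 6, 7], [1, 2, 3])
        u, p = mann_whitney_cb(values, benefit)
        assert u == 9.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups(self):
        values, benefit = _series([1, 2, 3], [1, 2, 3])
        _, p = mann_whitney_cb(values, benefit)
        assert p == pytest.approx(1.0)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        values, benefit = _series(rng.normal(1, 1, 8), rng.normal(0, 1, 9))
        _, p1 = mann_whitney_cb(values, benefit)
        _, p2 = mann_whitney_cb(np.exp(values / 3.0) + 5.0, benefit)
        assert p1 == pytest.approx(p2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        cb = rng.permutation(24)[:5].astype(float)
        ncb = rng.permutation(40)[:6].astype(float) + 0.5  # no ties with cb
        values, benefit = _series(cb, ncb)
        _, p = mann_whitney_cb(values, benefit)
        assert p == pytest.approx(mann_whitney_exact_enumeration(cb, ncb), abs=1e-12)

    def test_empty_group_rejected(self):
        values, benefit = _series([1, 2], [])
        with pytest.raises(ValidationError, match="non-empty"):
            mann_whitney_cb(values, benefit)


class TestContingency:
    # rows: tumors of the given subtype / all other subtypes; columns CB / NCB
    @pytest.mark.parametrize(
        "table,printed",
        [
            ((2, 22, 6, 17), 0.11),  # ASCL1
            ((3, 9, 5, 30), 0.40),  # NEUROD1
            ((2, 8, 6, 31), 0.78),  # YAP1
        ],
    )
    def test_chi2_subtype_rows_round_to_reported(self, table, printed):
        chi2, p = chi2_2x2(TwoByTwoTable(*table))
        assert p == pytest.approx(printed, abs=0.01)
        assert chi2 == pytest.approx(chi2_by_hand(*table), abs=1e-12)

    def test_chi2_identical_proportions(self):
        chi2, p = chi2_2x2(TwoByTwoTable(10, 20, 5, 10))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            chi2_2x2(TwoByTwoTable(0, 0, 5, 10))

    @pytest.mark.parametrize(
        "table,printed",
        [
            ((3, 2, 5, 22), 0.09),  # cleaved-NOTCH1 positivity vs benefit
            ((1, 0, 7, 39), 0.17),  # POU2F3 subtype row
        ],
    )
    def test_fisher_rows_round_to_reported(self, table, printed):
        p = fisher_exact_2x2(TwoByTwoTable(*table))
        assert round(p, 2) == printed

    def test_fisher_symmetric_table(self):
        assert fisher_exact_2x2(TwoByTwoTable(5, 5, 5, 5)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 11, size=4))
        p = fisher_exact_2x2(TwoByTwoTable(a, b, c, d))
        assert p == pytest.approx(fisher_exact_enumeration(a, b, c, d), abs=1e-9)

    def test_counts_validated(self):
        with pytest.raises(ValidationError, match="non-negative"):
            TwoByTwoTable(-1, 2, 3, 4)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, p = pearson_correlation(x, y)
        # closed-form r and t-distribution p computed independently
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_hand, abs=1e-12)
        from scipy.stats import t as tdist

        t_stat = r_hand * np.sqrt(8 / (1 - r_hand**2))
        assert p == pytest.approx(2 * tdist.sf(abs(t_stat), df=8), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestBHFDR:
    def test_step_up_hand_example(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adj, 0.05)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(6)
        p = rng.random(20)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj <= 1.0).all()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError, match="p-values"):
            bh_fdr([0.5, bad])


class TestMultivariableModel:
    def _covariates(self, n, seed, beta=0.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 5)),
            columns=["Notch", "Immune", "NE", "MYC", "EZH2"],
            index=[f"s{i}" for i in range(n)],
        )
        logits = beta * X["Notch"]
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-logits)), "CB", "NCB")
        return X, pd.Series(y, index=X.index)

    def test_planted_notch_effect_has_smallest_fdr(self):
        cohort = simulate_expression_cohort(SyntheticCohortConfig(n_samples=200, seed=17))
        covariates = benefit_covariates(cohort.expression, cohort.gene_sets)
        result = multivariable_benefit_model(
            covariates, cohort.clinical.benefit_series()
        )
        assert result.converged
        assert result.table["fdr"].idxmin() == "Notch"
        assert result.table.loc["Notch", "estimate"] > 0

    def test_fdr_column_consistent_with_bh(self):
        X, y = self._covariates(100, seed=3, beta=1.0)
        result = multivariable_benefit_model(X, y)
        np.testing.assert_allclose(
            result.table["fdr"].to_numpy(), bh_fdr(result.table["p"].to_numpy())
        )

    def test_ols_invariant_to_sample_duplication(self):
        X, y = self._covariates(50, seed=8, beta=0.5)
        r1 = multivariable_benefit_model(X, y, family="ols")
        X2 = pd.concat([X, X.set_index(X.index + "_dup")])
        y2 = pd.concat([y, y.set_axis(y.index + "_dup")])
        r2 = multivariable_benefit_model(X2, y2, family="ols")
        np.testing.assert_allclose(
            r1.table["estimate"].to_numpy(), r2.table["estimate"].to_numpy(), atol=1e-9
        )

    def test_perfect_separation_flagged_not_raised(self):
        n = 30
        x = np.concatenate([np.ones(15), -np.ones(15)]) + np.linspace(0, 0.1, n)
        X = pd.DataFrame(
            {
                "Notch": x,
                "Immune": np.linspace(-1, 1, n),
                "NE": np.cos(np.arange(n)),
                "MYC": np.sin(np.arange(n)),
                "EZH2": np.linspace(2, 3, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        y = pd.Series(np.where(x > 0, "CB", "NCB"), index=X.index)
        result = multivariable_benefit_model(X, y)
        assert not result.converged
        assert result.table["p"].isna().all()

    def test_too_few_samples_rejected(self):
        X, y = self._covariates(5, seed=1)
        with pytest.raises(ValidationError, match="at least"):
            multivariable_benefit_model(X, y)
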