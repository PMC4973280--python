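"""Moderated differential expression: gene-wise fits, empirical-Bayes
moderation, FDR and DE calling."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from thermoarray import generate_design, simulate_expression
from thermoarray.diffexpr import (
    Contrast,
    DifferentialExpression,
    bh_fdr,
    call_de,
    ebayes_moderate,
    estimate_hyperparameters,
    fit_genewise,
    paper_contrast_registry,
    trigamma_inverse,
)

from conftest import two_group_matrix
from test_synthdata import _null_architecture

CONTRAST = Contrast("ab", "group", "A", "B")


class TestFitGenewise:
    def test_exact_separation(self):
        mat = two_group_matrix(np.array([[1.0, 1, 1]]), np.array([[3.0, 3, 3]]))
        fit = fit_genewise(mat, CONTRAST)
        assert fit.coef[0] == pytest.approx(2.0)
        assert fit.s2[0] == pytest.approx(0.0)
        assert fit.df_residual == 4

    def test_coef_is_difference_of_group_means(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((30, 4)), rng.standard_normal((30, 5))
        fit = fit_genewise(two_group_matrix(a, b), CONTRAST)
        np.testing.assert_allclose(fit.coef, b.mean(axis=1) - a.mean(axis=1))
        assert fit.stdev_unscaled == pytest.approx(np.sqrt(1 / 4 + 1 / 5))

    def test_pooled_variance_matches_ols_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((50, 3)), rng.standard_normal((50, 3))
        fit = fit_genewise(two_group_matrix(a, b), CONTRAST)
        x = sm.add_constant(np.r_[np.zeros(3), np.ones(3)])
        for g in range(50):
            ols = sm.OLS(np.r_[a[g], b[g]], x).fit()
            assert fit.s2[g] == pytest.approx(ols.mse_resid, rel=1e-10)
            assert fit.coef[g] == pytest.approx(ols.params[1], rel=1e-10)

    def test_insufficient_replication_rejected(self):
        mat = two_group_matrix(np.array([[1.0]]), np.array([[3.0, 3, 3]]))
        with pytest.raises(ValueError, match="2 samples per group"):
            fit_genewise(mat, CONTRAST)


class TestEBayes:
    def test_identical_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(2)
        coef = rng.standard_normal(100)
        a = np.tile([0.0, 1.0, 2.0], (100, 1))  # every gene: identical s2
        b = a + coef[:, None]
        fit = fit_genewise(two_group_matrix(a, b), CONTRAST)
        res = ebayes_moderate(fit)
        assert np.isinf(res.params.d0)
        np.testing.assert_allclose(res.posterior_s2, fit.s2, rtol=1e-12)

    def test_hyperparameter_recovery_from_synthetic_variances(self):
        # single-seed version of the 20-seed acceptance suite
        arch = _null_architecture(10_000, np.ones(10_000))
        rng = np.random.default_rng(3)
        arch.true_variances = 4 * 0.05 / rng.chisquare(4, 10_000)
        matrix = simulate_expression(generate_design(3), arch, seed=3)
        contrast = paper_contrast_registry()["mean_temp"][0]
        fit = fit_genewise(matrix, contrast)
        params = estimate_hyperparameters(fit.s2, fit.df_residual)
        assert 3.0 <= params.d0 <= 5.0
        assert params.s0sq == pytest.approx(0.05, rel=0.2)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((200, 3)), rng.standard_normal((200, 3))
        fit = fit_genewise(two_group_matrix(a, b), CONTRAST)
        res = ebayes_moderate(fit, d0_override=0.0)
        np.testing.assert_allclose(res.table["t"], fit.ordinary_t(), rtol=1e-12)

    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(5)
        var = 4 * 0.05 / rng.chisquare(4, 500)
        a = rng.standard_normal((500, 3)) * np.sqrt(var)[:, None]
        b = rng.standard_normal((500, 3)) * np.sqrt(var)[:, None]
        fit = fit_genewise(two_group_matrix(a, b), CONTRAST)
        res = ebayes_moderate(fit)
        lo = np.minimum(fit.s2, res.params.s0sq)
        hi = np.maximum(fit.s2, res.params.s0sq)
        assert np.all(res.posterior_s2 >= lo - 1e-12)
        assert np.all(res.posterior_s2 <= hi + 1e-12)

    def test_type_i_error_on_pure_noise(self):
        arch = _null_architecture(10_000, np.ones(10_000))
        rng = np.random.default_rng(6)
        arch.true_variances = 4 * 0.05 / rng.chisquare(4, 10_000)
        matrix = simulate_expression(generate_design(3), arch, seed=6)
        res = DifferentialExpression(
            matrix, paper_contrast_registry()["ramping"][0]
        ).fit()
        rate = float((res.table["p"] <= 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) < 3 * se

    def test_trigamma_inverse_inverts_trigamma(self):
        for y in (0.1, 1.0, 7.5, 40.0):
            assert trigamma_inverse(float(special.polygamma(1, y))) == pytest.approx(
                y, rel=1e-8
            )

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against the Bioconductor limma implementation."""
        rng = np.random.default_rng(42)
        var = 4 * 0.05 / rng.chisquare(4, 200)
        X = rng.standard_normal((200, 6)) * np.sqrt(var)[:, None]
        X[:20, 3:] += 1.0
        tsv = tmp_path / "expr.tsv"
        pd.DataFrame(
            X, index=[f"g{i}" for i in range(200)], columns=[f"s{j}" for j in range(6)]
        ).to_csv(tsv, sep="\t")
        script = tmp_path / "limma.R"
        out_csv = tmp_path / "limma_out.csv"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.delim('{tsv}', row.names=1))\n"
            "design <- model.matrix(~factor(c('A','A','A','B','B','B')))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n"
            "                  d0=fit$df.prior, s0sq=fit$s2.prior)\n"
            f"write.csv(out, '{out_csv}')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out_csv, index_col=0)

        mat = two_group_matrix(X[:, :3], X[:, 3:])
        res = ebayes_moderate(fit_genewise(mat, CONTRAST))
        np.testing.assert_allclose(res.table["t"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res.table["p"], ref["p"], rtol=1e-8)
        assert res.params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res.params.s0sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-6)


class TestBHFDR:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_in_p_rank_and_permutation_stable(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])


class TestCallDE:
    def test_empty_when_nothing_significant(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal((50, 3)), rng.standard_normal((50, 3))
        res = ebayes_moderate(fit_genewise(two_group_matrix(a, b), CONTRAST))
        up, down = call_de(res, q_threshold=1e-6)
        assert up == [] and down == []

    def test_up_down_partition_is_disjoint(self, small_experiment):
        matrix = small_experiment["matrix"]
        res = DifferentialExpression(
            matrix, paper_contrast_registry()["mean_temp"][0]
        ).fit()
        up, down = res.gene_lists()
        assert not set(up) & set(down)
        assert len(up) + len(down) == int((res.table["q"] <= 0.05).sum())

    def test_power_on_injected_module(self):
        """>=90% of a +2 logFC module recovered at q <= 0.05 (10 seeds)."""
        powers = []
        for seed in range(10):
            arch = _null_architecture(2000, np.ones(2000))
            rng = np.random.default_rng(100 + seed)
            arch.true_variances = 4 * 0.05 / rng.chisquare(4, 2000)
            arch.mean_temp_effect[:100] = 2.0
            matrix = simulate_expression(generate_design(3), arch, seed=seed)
            res = DifferentialExpression(
                matrix, paper_contrast_registry()["mean_temp"][0]
            ).fit()
            up, _ = res.gene_lists()
            powers.append(len(set(up) & set(matrix.gene_ids[:100])) / 100)
        assert np.mean(powers) >= 0.90
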