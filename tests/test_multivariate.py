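"""PCA and the sequential-SS factorial ANOVA engine."""

import numpy as np
import pandas as pd
import pytest

from thermoarray import (
    factorial_anova,
    generate_design,
    pc_anova,
    pca,
    simulate_ctmax,
    simulate_expression,
)
from thermoarray.containers import ExpressionMatrix
from thermoarray.multivariate import EstimabilityError

from conftest import SMALL_ARCH
from test_synthdata import _null_architecture
from thermoarray import generate_architecture, ctmax_group_means


def random_matrix(n_genes, n_samples, seed):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    ann = pd.DataFrame({"dummy": ["x"] * n_samples}, index=values.columns)
    return ExpressionMatrix(values, ann)


class TestPCA:
    def test_rank_one_matrix_has_single_component(self):
        pattern = np.outer(np.arange(1, 6), np.linspace(-1, 1, 10))
        mat = random_matrix(5, 10, 0)
        mat.values.iloc[:, :] = pattern
        res = pca(mat)
        assert res.variance_explained[0] == pytest.approx(1.0)
        assert np.all(res.variance_explained[1:] < 1e-12)

    def test_matches_eigendecomposition_oracle(self):
        mat = random_matrix(20, 10, 1)  # 10 samples x 20 genes
        res = pca(mat)
        X = mat.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)  # gene-space scatter matrix
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = 9  # at most n_samples - 1 informative components
        np.testing.assert_allclose(res.singular_values[:k] ** 2, evals[:k], atol=1e-8)
        scores_oracle = Xc @ evecs[:, :k]
        # align oracle signs to the package's convention before comparing
        flip = np.sign(evecs[np.argmax(np.abs(evecs[:, :k]), axis=0), np.arange(k)])
        np.testing.assert_allclose(
            res.scores.to_numpy()[:, :k], scores_oracle * flip, atol=1e-8
        )
        np.testing.assert_allclose(
            res.variance_explained[:k], evals[:k] / evals.sum(), atol=1e-12
        )

    def test_scale_equivariance(self):
        mat = random_matrix(30, 8, 2)
        res1 = pca(mat)
        scaled = ExpressionMatrix(mat.values * -3.0, mat.annotations)
        res2 = pca(scaled)
        np.testing.assert_allclose(
            res2.singular_values, 3.0 * res1.singular_values, atol=1e-10
        )
        np.testing.assert_allclose(
            res2.variance_explained, res1.variance_explained, atol=1e-12
        )

    def test_constant_matrix_warns_and_is_degenerate(self):
        mat = random_matrix(10, 5, 3)
        mat.values.iloc[:, :] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            res = pca(mat)
        assert np.all(res.variance_explained == 0)

    def test_samples_separate_by_design_factors(self, small_experiment):
        """Mean temperature separates along PC1, assay along PC2."""
        from sklearn.metrics import silhouette_score

        matrix = small_experiment["matrix"]
        res = pca(matrix)
        ann = matrix.annotations
        s_mean = silhouette_score(
            res.scores[["PC1"]].to_numpy(), ann["mean_temp"].to_numpy()
        )
        s_assay = silhouette_score(
            res.scores[["PC2"]].to_numpy(), ann["assay"].to_numpy()
        )
        assert s_mean > 0
        assert s_assay > 0


class TestFactorialAnova:
    def test_full_factorial_df_structure(self):
        """2x2x2 with 3 replicates: every term df 1, residual df 16."""
        design = generate_design(3)
        rng = np.random.default_rng(4)
        table = factorial_anova(
            rng.standard_normal(24), design[["mean_temp", "regime", "assay"]]
        )
        terms = table.table.drop(index="Residual")
        assert len(terms) == 7
        assert (terms["df"] == 1).all()
        assert table.residual_df == 16

    def test_ctmax_two_way_residual_df(self):
        table = simulate_ctmax(seed=0)
        res = factorial_anova(table["ctmax"].to_numpy(), table[["mean_temp", "regime"]])
        assert res.residual_df == 189

    def test_matches_statsmodels_type_i_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        # unbalanced three-factor data
        df = pd.DataFrame(
            {
                "a": rng.choice(["u", "v"], 60),
                "b": rng.choice(["x", "y", "z"], 60),
                "c": rng.choice(["p", "q"], 60),
            }
        )
        df["y"] = rng.standard_normal(60) + (df["a"] == "u") * 0.5
        mine = factorial_anova(df["y"].to_numpy(), df[["a", "b", "c"]])
        ref = sm.stats.anova_lm(
            smf.ols("y ~ C(a) * C(b) * C(c)", data=df).fit(), typ=1
        )
        np.testing.assert_allclose(
            mine.table["sum_sq"].to_numpy(), ref["sum_sq"].to_numpy(), rtol=1e-8
        )
        np.testing.assert_allclose(
            mine.table["df"].to_numpy(), ref["df"].to_numpy()
        )
        np.testing.assert_allclose(
            mine.table["F"].to_numpy()[:-1], ref["F"].to_numpy()[:-1], rtol=1e-8
        )

    def test_balanced_ss_decomposition_and_order_invariance(self):
        design = generate_design(3)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(24)
        factors = design[["mean_temp", "regime", "assay"]]
        t1 = factorial_anova(y, factors)
        total = np.sum((y - y.mean()) ** 2)
        assert t1.table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)
        t2 = factorial_anova(y, factors[["assay", "regime", "mean_temp"]])
        for term in ("mean_temp", "regime", "assay"):
            assert t1.table.loc[term, "sum_sq"] == pytest.approx(
                t2.table.loc[term, "sum_sq"], rel=1e-8
            )

    def test_empty_interaction_cell_rejected(self):
        df = pd.DataFrame({"a": ["u", "u", "v", "v"], "b": ["x", "x", "x", "y"]})
        y = np.arange(4.0)
        with pytest.raises(EstimabilityError):
            factorial_anova(y, df, interactions=[("a", "b")])

    def test_null_rejection_rate_near_alpha(self):
        """Type-I error of the full-factorial F tests at alpha = 0.05."""
        design = generate_design(3)
        factors = design[["mean_temp", "regime", "assay"]]
        rng = np.random.default_rng(7)
        n_rep = 2000
        rejections = 0
        for _ in range(n_rep):
            tab = factorial_anova(rng.standard_normal(24), factors)
            rejections += int(tab.table.loc["mean_temp", "p"] < 0.05)
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se


class TestPCAnova:
    def test_returns_one_table_per_component(self, small_experiment):
        res = pca(small_experiment["matrix"])
        tables = pc_anova(
            res, small_experiment["matrix"].annotations[["mean_temp", "regime", "assay"]]
        )
        assert len(tables) == 4
        assert all(t.residual_df == 16 for t in tables)
        assert tables[0].label.endswith("% of variance")

    def test_too_many_components_rejected(self, small_experiment):
        res = pca(small_experiment["matrix"])
        with pytest.raises(ValueError):
            pc_anova(res, small_experiment["matrix"].annotations, n_components=99)

    def test_fluctuation_effect_detected_in_top_components(self):
        """Injected fluctuation module surfaces as a significant main effect
        in at least one of the first four PCs for most seeds."""
        hits = 0
        for seed in range(10):
            arch = generate_architecture(SMALL_ARCH, seed=seed)
            ctmax = simulate_ctmax(seed=seed)
            matrix = simulate_expression(
                generate_design(3), arch, seed=seed + 50,
                group_ctmax=ctmax_group_means(ctmax),
            )
            tables = pc_anova(
                pca(matrix), matrix.annotations[["mean_temp", "regime", "assay"]]
            )
            hits += any(t.p_value("regime") < 0.05 for t in tables)
        assert hits >= 8

    def test_null_significance_count_matches_alpha(self):
        """With no injected effects the count of significant terms across
        7 terms x 4 PCs stays near alpha * 28."""
        design = generate_design(3)
        counts = []
        for seed in range(20):
            arch = _null_architecture(400, np.ones(400))
            matrix = simulate_expression(design, arch, seed=seed)
            tables = pc_anova(
                pca(matrix), matrix.annotations[["mean_temp", "regime", "assay"]]
            )
            counts.append(
                sum(
                    int(t.table.loc[term, "p"] < 0.05)
                    for t in tables
                    for term in t.table.index
                    if term != "Residual"
                )
            )
        mean_count = np.mean(counts)
        # expectation 1.4; PC scores are not independent responses, so allow
        # a generous Monte-Carlo band
        assert 0.2 <= mean_count <= 4.0
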