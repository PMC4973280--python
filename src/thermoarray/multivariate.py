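"""PCA of expression profiles and the shared factorial ANOVA engine.

The ANOVA engine serves two consumers: the two-way analysis of individual-fly
CTmax (mean temperature x regime, unbalanced group sizes) and the per-PC
three-way analysis of principal-component scores of the 24-sample expression
matrix.  Sums of squares are sequential (Type I) from nested least-squares
fits in the declared term order; for balanced designs this is order-invariant
and decomposes the total sum of squares exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = ["PCAResult", "AnovaTable", "pca", "factorial_anova", "pc_anova"]


@dataclass
class PCAResult:
    """Principal components of a gene-centred expression matrix.

    ``scores`` is samples x components, ``loadings`` genes x components and
    ``variance_explained`` the per-component fraction of total variance.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def summary(self, n: int = 4) -> str:
        lines = ["Principal component analysis of expression profiles"]
        for i in range(min(n, self.n_components)):
            lines.append(
                f"  PC{i + 1}: {100 * self.variance_explained[i]:.1f}% of variance"
            )
        return "\n".join(lines)

    def plot(self, factors: pd.DataFrame | None = None, components=(0, 1), ax=None):
        """Scatter the samples on two PCs, optionally coloured by a factor."""
        import matplotlib.pyplot as plt

        i, j = components
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.scores.iloc[:, i], self.scores.iloc[:, j])
        ax.set_xlabel(f"PC{i + 1} ({100 * self.variance_explained[i]:.1f}%)")
        ax.set_ylabel(f"PC{j + 1} ({100 * self.variance_explained[j]:.1f}%)")
        return ax


def pca(matrix: ExpressionMatrix) -> PCAResult:
    """PCA of samples over gene-centred (not scaled) log2 expression.

    Each gene's mean across samples is subtracted; no unit-variance scaling is
    applied because expression is already on a common log2 scale.  Components
    come from the singular value decomposition of the centred sample-by-gene
    matrix; the sign of each component is fixed by making its
    largest-magnitude gene loading positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    X = matrix.values.to_numpy().T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S**2))
    if total <= 1e-12 * Xc.size:
        warnings.warn("expression matrix is constant; all components are degenerate")
        frac = np.zeros_like(S)
    else:
        frac = S**2 / total
    # deterministic sign: largest-|loading| gene positive per component
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    names = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=matrix.sample_ids, columns=names)
    loadings = pd.DataFrame(Vt.T, index=matrix.gene_ids, columns=names)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=frac,
                     singular_values=S)


class EstimabilityError(ValueError):
    """A requested interaction has empty design cells."""


@dataclass
class AnovaTable:
    """Results object for one factorial ANOVA.

    ``table`` has one row per model term (df, sum_sq, mean_sq, F, p) and a
    final ``Residual`` row.
    """

    table: pd.DataFrame
    response: str = "response"
    label: str | None = None

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "df"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    @staticmethod
    def _stars(p: float) -> str:
        if not np.isfinite(p):
            return ""
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

    def summary(self) -> str:
        """Formatted text block: term, (df1, df2), F with significance stars."""
        head = f"ANOVA of {self.response}"
        if self.label:
            head += f" ({self.label})"
        lines = [head]
        df2 = self.residual_df
        for term, row in self.table.iterrows():
            if term == "Residual":
                continue
            lines.append(
                f"  {term} ({int(row['df'])}, {df2})\tF = {row['F']:.4g}"
                f"{self._stars(row['p'])}"
            )
        lines.append(f"  Residual df = {df2}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="term")


def _term_columns(factors: pd.DataFrame, term: tuple) -> np.ndarray:
    """Drop-first indicator columns for a (possibly interaction) term."""
    blocks = []
    for f in term:
        levels = sorted(pd.unique(factors[f]), key=str)
        cols = np.column_stack(
            [(factors[f] == lev).to_numpy(float) for lev in levels[1:]]
        )
        blocks.append(cols)
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(len(factors), -1)
    return out


def _default_terms(factor_names, interactions):
    names = list(factor_names)
    terms = [(f,) for f in names]
    if interactions == "all":
        for k in range(2, len(names) + 1):
            terms.extend(itertools.combinations(names, k))
    elif interactions:
        terms.extend(tuple(t) for t in interactions)
    return terms


def factorial_anova(
    values,
    factors: pd.DataFrame,
    interactions="all",
    terms=None,
    response: str = "response",
    label: str | None = None,
) -> AnovaTable:
    """Sequential (Type I) factorial ANOVA of ``values`` on categorical factors.

    Parameters
    ----------
    values
        Response vector, one entry per row of ``factors``.
    factors
        DataFrame of categorical columns; every column is used as a factor.
    interactions
        ``"all"`` (default) for the full factorial, ``None``/``[]`` for main
        effects only, or an explicit list of factor-name tuples.
    terms
        Full explicit term order (tuples of factor names), overriding
        ``interactions``.

    Sums of squares come from nested least-squares fits in term order
    (intercept, then each term cumulatively); F compares each term's mean
    square against the residual mean square of the full model.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) != len(factors):
        raise ValueError("values must be a vector matching the factor table rows")
    for f in factors.columns:
        if factors[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    term_list = [tuple(t) for t in terms] if terms is not None else _default_terms(
        factors.columns, interactions
    )
    for term in term_list:
        if len(term) > 1:
            counts = factors.groupby([factors[f] for f in term], observed=False).size()
            full = np.prod([factors[f].nunique() for f in term])
            if (counts == 0).any() or len(counts) < full:
                raise EstimabilityError(
                    f"interaction {' x '.join(term)} has empty design cells"
                )

    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    rank_prev = 1
    rows = []
    for term in term_list:
        X = np.hstack([X, _term_columns(factors, term)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        rows.append((" x ".join(term), rank - rank_prev, rss_prev - rss))
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_prev / df_resid

    records = []
    for name, df, ss in rows:
        ms = ss / df if df > 0 else np.nan
        F = ms / ms_resid if df > 0 else np.nan
        p = float(stats.f.sf(F, df, df_resid)) if df > 0 else np.nan
        records.append((name, df, ss, ms, F, p))
    records.append(("Residual", df_resid, rss_prev, ms_resid, np.nan, np.nan))
    table = pd.DataFrame(
        records, columns=["term", "df", "sum_sq", "mean_sq", "F", "p"]
    ).set_index("term")
    return AnovaTable(table=table, response=response, label=label)


def pc_anova(
    pca_result: PCAResult,
    factors: pd.DataFrame,
    n_components: int = 4,
    interactions="all",
) -> list[AnovaTable]:
    """Full-factorial ANOVA of each of the first ``n_components`` PC scores.

    Each returned table is labelled with the component's variance-explained
    fraction.
    """
    if n_components > pca_result.n_components:
        raise ValueError(
            f"requested {n_components} components but only "
            f"{pca_result.n_components} are available"
        )
    tables = []
    for i in range(n_components):
        name = pca_result.scores.columns[i]
        tables.append(
            factorial_anova(
                pca_result.scores[name].to_numpy(),
                factors.loc[pca_result.scores.index],
                interactions=interactions,
                response=name,
                label=f"{100 * pca_result.variance_explained[i]:.1f}% of variance",
            )
        )
    return tables
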