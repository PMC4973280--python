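"""Gene-wise two-group contrasts with empirical-Bayes variance moderation.

Each contrast compares two sample groups inside one stratum of the factorial
design (e.g. 15 vs 25 °C among constant-regime, 20 °C-assay samples).  Per
gene, an ordinary two-group linear model gives the log2 fold change, pooled
residual variance and residual degrees of freedom; an empirical-Bayes
hierarchical model then shrinks the gene-wise variances toward a common prior
before forming moderated t-statistics.

The moderation follows the standard hierarchical model for gene-wise
variances: s_g^2 | sigma_g^2 ~ sigma_g^2 * chisq(d_g)/d_g with
1/sigma_g^2 ~ chisq(d0)/(d0*s0^2).  The hyper-parameters (d0, s0^2) are
estimated by closed-form method of moments on z_g = log s_g^2:

    e_g = z_g - psi(d_g/2) + log(d_g/2)
    psi'(d0/2) = max(0, var(e) - mean(psi'(d_g/2)))   (d0 = inf if rhs == 0)
    s0^2 = exp(mean(e) + psi(d0/2) - log(d0/2))

and the posterior variance is the precision-weighted blend
s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g), giving a moderated t with
d0 + d_g degrees of freedom (normal in the d0 = inf limit).

Positive logFC always means higher expression in the second-named condition
of the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix

__all__ = [
    "Contrast",
    "GenewiseFit",
    "EBayesParams",
    "ContrastResult",
    "DifferentialExpression",
    "fit_genewise",
    "ebayes_moderate",
    "bh_fdr",
    "call_de",
    "trigamma_inverse",
]


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison within a stratum of the design.

    ``level_ref`` and ``level_alt`` are the two levels of ``factor`` being
    compared; ``strata`` fixes the remaining factors.  The reported logFC is
    ``mean(level_alt) - mean(level_ref)``.
    """

    name: str
    factor: str
    level_ref: object
    level_alt: object
    strata: tuple = ()  # tuple of (factor, level) pairs

    def groups(self, matrix: ExpressionMatrix):
        fixed = dict(self.strata)
        ref = matrix.samples_where(**{self.factor: self.level_ref, **fixed})
        alt = matrix.samples_where(**{self.factor: self.level_alt, **fixed})
        return ref, alt

    def label(self) -> str:
        fixed = ", ".join(f"{k}={v}" for k, v in self.strata)
        core = f"{self.factor}: {self.level_alt} vs {self.level_ref}"
        return f"{core} [{fixed}]" if fixed else core


@dataclass
class GenewiseFit:
    """Per-gene ordinary two-group fit for one contrast."""

    gene_ids: pd.Index
    coef: np.ndarray  # log2 fold change, alt minus ref
    s2: np.ndarray  # pooled residual variance
    df_residual: float  # n1 + n2 - 2, common to all genes
    stdev_unscaled: float  # sqrt(1/n1 + 1/n2)
    contrast: Contrast | None = None

    def ordinary_t(self) -> np.ndarray:
        """Classical two-sample t (no moderation); inf where s2 == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.coef / (np.sqrt(self.s2) * self.stdev_unscaled)
        return np.where(self.s2 > 0, t, np.sign(self.coef) * np.inf)


@dataclass(frozen=True)
class EBayesParams:
    """Estimated variance-prior hyper-parameters."""

    d0: float  # prior degrees of freedom, may be inf
    s0sq: float  # prior variance


@dataclass
class ContrastResult:
    """Moderated per-gene results for one contrast.

    Attributes
    ----------
    table
        DataFrame indexed by gene id with columns ``logFC``, ``t``, ``p``,
        ``q`` and ``direction`` (up / down / ns at the calling threshold).
    """

    table: pd.DataFrame
    params: EBayesParams
    df_total: float
    contrast: Contrast | None = None
    q_threshold: float = 0.05
    posterior_s2: np.ndarray = field(default=None, repr=False)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def gene_lists(self, q_threshold: float | None = None):
        return call_de(self, q_threshold if q_threshold is not None else self.q_threshold)

    def n_significant(self, q_threshold: float | None = None) -> int:
        up, down = self.gene_lists(q_threshold)
        return len(up) + len(down)

    def summary(self) -> str:
        up, down = self.gene_lists()
        name = self.contrast.label() if self.contrast else "contrast"
        d0 = "inf" if np.isinf(self.params.d0) else f"{self.params.d0:.2f}"
        lines = [
            f"Moderated two-group contrast — {name}",
            f"  genes: {len(self.table)}",
            f"  prior df d0 = {d0}, prior variance s0^2 = {self.params.s0sq:.4g}",
            f"  significant at q <= {self.q_threshold:g}: "
            f"{len(up)} up, {len(down)} down",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def fit_genewise(matrix: ExpressionMatrix, contrast: Contrast) -> GenewiseFit:
    """Ordinary per-gene two-group fit for ``contrast``.

    Per gene: coef = mean(alt) - mean(ref), pooled residual variance with
    n1 + n2 - 2 degrees of freedom, unscaled coefficient standard deviation
    sqrt(1/n1 + 1/n2).
    """
    ref_ids, alt_ids = contrast.groups(matrix)
    n1, n2 = len(ref_ids), len(alt_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"contrast {contrast.name!r} needs >= 2 samples per group "
            f"(got {n1} ref, {n2} alt)"
        )
    ref = matrix.values[ref_ids].to_numpy()
    alt = matrix.values[alt_ids].to_numpy()
    coef = alt.mean(axis=1) - ref.mean(axis=1)
    rss = ((ref - ref.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (alt - alt.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    return GenewiseFit(
        gene_ids=matrix.gene_ids,
        coef=coef,
        s2=rss / df,
        df_residual=float(df),
        stdev_unscaled=float(np.sqrt(1.0 / n1 + 1.0 / n2)),
        contrast=contrast,
    )


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration.

    Returns inf for x <= 0 (zero excess dispersion limit).
    """
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    # Newton on the asymptotically linearising scale (as in the classical
    # variance-moderation implementation): y <- y * (1 + trigamma(y)*(...)).
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < tol:
            break
    return float(y)


def estimate_hyperparameters(s2: np.ndarray, df: float) -> EBayesParams:
    """Method-of-moments estimate of (d0, s0^2) from gene-wise variances.

    Genes with s2 == 0 are excluded from estimation (their log-variance is
    undefined); at least 10 positive-variance genes are required.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual variance")
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # Zero excess dispersion: all genes share one variance.  Use the
        # geometric mean of the observed s^2 directly (rather than the
        # bias-corrected exp(mean(e))) so that identical gene variances are
        # returned unchanged by moderation.
        d0 = float("inf")
        s0sq = float(np.exp(np.mean(z)))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesParams(d0=d0, s0sq=s0sq)


def posterior_variances(s2: np.ndarray, df: float, params: EBayesParams) -> np.ndarray:
    """Shrunken variances s~^2 = (d0*s0^2 + d*s^2)/(d0 + d)."""
    if np.isinf(params.d0):
        return np.full_like(np.asarray(s2, dtype=float), params.s0sq)
    return (params.d0 * params.s0sq + df * np.asarray(s2, dtype=float)) / (params.d0 + df)


def ebayes_moderate(
    fit: GenewiseFit,
    q_threshold: float = 0.05,
    d0_override: float | None = None,
) -> ContrastResult:
    """Moderate a gene-wise fit and compute moderated t, p and BH q values.

    ``d0_override`` forces the prior df (0 recovers the ordinary t exactly;
    inf pools all genes to the prior variance).
    """
    s2 = fit.s2
    if not np.any(s2 > 0):
        raise ValueError("all gene-wise residual variances are zero; cannot moderate")
    params = estimate_hyperparameters(s2, fit.df_residual)
    if d0_override is not None:
        params = EBayesParams(d0=float(d0_override), s0sq=params.s0sq)

    if params.d0 == 0:
        s2_post = s2.astype(float)
        df_total = fit.df_residual
    else:
        s2_post = posterior_variances(s2, fit.df_residual, params)
        df_total = fit.df_residual + params.d0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coef / (np.sqrt(s2_post) * fit.stdev_unscaled)
    t = np.where(s2_post > 0, t, np.sign(fit.coef) * np.inf)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_fdr(p)
    direction = np.where(
        (q <= q_threshold) & (fit.coef > 0),
        "up",
        np.where((q <= q_threshold) & (fit.coef < 0), "down", "ns"),
    )
    table = pd.DataFrame(
        {"logFC": fit.coef, "t": t, "p": p, "q": q, "direction": direction},
        index=fit.gene_ids,
    )
    return ContrastResult(
        table=table,
        params=params,
        df_total=df_total,
        contrast=fit.contrast,
        q_threshold=q_threshold,
        posterior_s2=s2_post,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(result: ContrastResult, q_threshold: float = 0.05):
    """Split a contrast result into (up, down) significant gene-id lists."""
    tab = result.table
    sig = tab["q"] <= q_threshold
    up = list(tab.index[sig & (tab["logFC"] > 0)])
    down = list(tab.index[sig & (tab["logFC"] < 0)])
    return up, down


class DifferentialExpression:
    """Model object: moderated differential expression for one contrast.

    Examples
    --------
    >>> model = DifferentialExpression(matrix, contrast)   # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(self, matrix: ExpressionMatrix, contrast: Contrast):
        self.matrix = matrix
        self.contrast = contrast

    def fit(self, q_threshold: float = 0.05, d0_override: float | None = None) -> ContrastResult:
        fit = fit_genewise(self.matrix, self.contrast)
        return ebayes_moderate(fit, q_threshold=q_threshold, d0_override=d0_override)


def paper_contrast_registry() -> dict:
    """The twelve stratified two-group contrasts of the factorial design,
    grouped into three families (mean_temp, regime/fluctuation, assay/ramping).

    Each family compares one factor's two levels within every stratum of the
    other two factors.  A pooled main-effect contrast is deliberately not
    included here; build one explicitly if marginal pooling is wanted.
    """
    registry: dict = {"mean_temp": [], "fluctuation": [], "ramping": []}
    for regime in ("constant", "fluctuating"):
        for assay in (20, 35):
            registry["mean_temp"].append(
                Contrast(
                    name=f"mean_{regime}_{assay}",
                    factor="mean_temp",
                    level_ref=15,
                    level_alt=25,
                    strata=(("regime", regime), ("assay", assay)),
                )
            )
    for mean_temp in (15, 25):
        for assay in (20, 35):
            registry["fluctuation"].append(
                Contrast(
                    name=f"fluct_{mean_temp}_{assay}",
                    factor="regime",
                    level_ref="constant",
                    level_alt="fluctuating",
                    strata=(("mean_temp", mean_temp), ("assay", assay)),
                )
            )
    for mean_temp in (15, 25):
        for regime in ("constant", "fluctuating"):
            registry["ramping"].append(
                Contrast(
                    name=f"ramp_{mean_temp}_{regime}",
                    factor="assay",
                    level_ref=20,
                    level_alt=35,
                    strata=(("mean_temp", mean_temp), ("regime", regime)),
                )
            )
    return registry
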