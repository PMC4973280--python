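"""Expression-phenotype correlation screen and gene classification.

Each sample is assigned the group-mean CTmax of its developmental treatment
(four distinct phenotype values across the 12 samples at one assay
temperature), and every gene's expression is Pearson-correlated with that
phenotype vector separately at the 20 °C control and 35 °C ramped assays.
Genes are then classified by the pattern of significant correlations across
the two assay temperatures, with a strict threshold (default p < 0.001) for
calling a correlation and a relaxed one (default p > 0.05) for calling its
absence.

Caveat: because replicate samples share their group's phenotype value, the
correlation p-values are only nominally calibrated when genes carry no
treatment effects at all; genes that respond to the treatments correlate with
any group-level phenotype through the shared design (pseudo-replication).
Use :func:`phenotype_permutation_null` for an empirically calibrated null
rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "CATEGORIES",
    "correlate_expression_phenotype",
    "classify_genes",
    "PhenoCorrClassification",
    "phenotype_permutation_null",
]

CATEGORIES = (
    "pos_both",
    "neg_both",
    "sign_switch_neg20_pos35",
    "sign_switch_pos20_neg35",
    "only_20",
    "only_35",
    "ambiguous",
    "ns",
)


def _phenotype_vector(annotations: pd.DataFrame, group_ctmax: dict) -> np.ndarray:
    try:
        return np.array(
            [
                group_ctmax[(mt, rg)]
                for mt, rg in zip(annotations["mean_temp"], annotations["regime"])
            ],
            dtype=float,
        )
    except KeyError as exc:
        raise KeyError(
            f"no group-mean CTmax supplied for developmental group {exc.args[0]}"
        ) from exc


def correlate_expression_phenotype(
    matrix: ExpressionMatrix,
    group_ctmax: dict,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-gene correlation between expression and group-mean CTmax.

    Parameters
    ----------
    matrix
        Expression restricted to one assay temperature (all samples are used
        as given; subset with ``matrix.select_samples`` first).
    group_ctmax
        Mapping ``(mean_temp, regime) -> group-mean CTmax``; every sample's
        developmental group must be present.
    method
        ``"pearson"`` (default) or ``"spearman"`` (rank-transformed first).

    Returns a DataFrame indexed by gene id with ``r``, ``p`` (two-sided, from
    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df), ``n`` and a ``degenerate`` flag
    for zero-variance genes (r undefined, p = NaN).
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError(f"need >= 4 samples for the correlation screen, got {n}")
    y = _phenotype_vector(matrix.annotations, group_ctmax)
    X = matrix.values.to_numpy()
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    y_ss = float(np.sum(yc**2))
    if y_ss == 0:
        raise ValueError("phenotype is constant across samples")
    x_ss = np.sum(Xc**2, axis=1)
    degenerate = x_ss == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / np.sqrt(x_ss * y_ss)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    r = np.where(degenerate, np.nan, r)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {"r": r, "p": p, "n": n, "degenerate": degenerate}, index=matrix.gene_ids
    )


@dataclass
class PhenoCorrClassification:
    """Per-gene category assignment across the two assay temperatures."""

    table: pd.DataFrame  # r20, p20, r35, p35, category
    strict: float
    relaxed: float

    @property
    def counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(CATEGORIES, fill_value=0)

    def genes_in(self, category: str) -> list:
        if category not in CATEGORIES:
            raise KeyError(f"unknown category {category!r}")
        return list(self.table.index[self.table["category"] == category])

    def summary(self) -> str:
        lines = [
            "Expression-CTmax correlation screen "
            f"(strict p < {self.strict:g}, relaxed p > {self.relaxed:g})"
        ]
        for cat, count in self.counts.items():
            lines.append(f"  {cat}: {count}")
        n20 = int((self.table["p20"] < self.strict).sum())
        n35 = int((self.table["p35"] < self.strict).sum())
        lines.append(f"  correlated at 20 °C (p < {self.strict:g}): {n20}")
        lines.append(f"  correlated at 35 °C (p < {self.strict:g}): {n35}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def classify_genes(
    res20: pd.DataFrame,
    res35: pd.DataFrame,
    strict: float = 0.001,
    relaxed: float = 0.05,
) -> PhenoCorrClassification:
    """Classify genes by their correlation pattern at the two assay temperatures.

    Rules (mutually exclusive, exhaustive):

    - both p < strict: ``pos_both`` / ``neg_both`` / the two ``sign_switch``
      categories according to the correlation signs;
    - exactly one p < strict: ``only_20`` / ``only_35`` when the other
      temperature is clearly uncorrelated (p > relaxed), else ``ambiguous``;
    - neither p < strict: ``ns`` (including degenerate zero-variance genes).
    """
    if not res20.index.equals(res35.index):
        missing = sorted(map(str, set(res20.index) ^ set(res35.index)))
        raise ValueError(f"gene universes differ between assay temperatures: {missing[:10]}")
    if not 0 < strict <= relaxed < 1:
        raise ValueError("need 0 < strict <= relaxed < 1")

    r20, p20 = res20["r"].to_numpy(), res20["p"].to_numpy()
    r35, p35 = res35["r"].to_numpy(), res35["p"].to_numpy()
    sig20 = p20 < strict
    sig35 = p35 < strict
    clear20 = p20 > relaxed
    clear35 = p35 > relaxed

    category = np.full(len(r20), "ns", dtype=object)
    both = sig20 & sig35
    category[both & (r20 > 0) & (r35 > 0)] = "pos_both"
    category[both & (r20 < 0) & (r35 < 0)] = "neg_both"
    category[both & (r20 < 0) & (r35 > 0)] = "sign_switch_neg20_pos35"
    category[both & (r20 > 0) & (r35 < 0)] = "sign_switch_pos20_neg35"
    category[sig20 & ~sig35 & clear35] = "only_20"
    category[sig35 & ~sig20 & clear20] = "only_35"
    category[sig20 & ~sig35 & ~clear35] = "ambiguous"
    category[sig35 & ~sig20 & ~clear20] = "ambiguous"
    # NaN p-values (degenerate genes) fail every comparison above -> "ns"

    table = pd.DataFrame(
        {"r20": r20, "p20": p20, "r35": r35, "p35": p35, "category": category},
        index=res20.index,
    )
    return PhenoCorrClassification(table=table, strict=strict, relaxed=relaxed)


def phenotype_permutation_null(
    matrix: ExpressionMatrix,
    group_ctmax: dict,
    strict: float = 0.001,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """Empirically calibrated null rate of p < strict under phenotype-label
    permutation.

    The four group-mean CTmax values are randomly reassigned to the four
    developmental groups each round, breaking any true expression-phenotype
    link while preserving the repeated-value (pseudo-replication) structure.
    Returns the mean fraction of genes reaching p < strict across rounds.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(group_ctmax)
    values = np.array([group_ctmax[g] for g in groups])
    rates = []
    for _ in range(n_perm):
        shuffled = dict(zip(groups, values[rng.permutation(len(values))]))
        res = correlate_expression_phenotype(matrix, shuffled)
        rates.append(float((res["p"] < strict).mean()))
    return float(np.mean(rates))
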