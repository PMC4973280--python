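"""Gene-set statistics on per-gene contrast statistics.

Two set-level tests are provided:

- :func:`gage_unpaired` — for each set, a Welch (unequal-variance) two-sample
  t comparing the member genes' statistics against the non-member genes',
  with one-sided p-values for coordinated up- and down-regulation and FDR
  control per direction.  This is a self-contained re-specification of the
  "unpaired" two-sample set test popularised for expression pathway analysis;
  equivalence with any particular external implementation is not claimed.
- :func:`permutation_gsa` — set statistic = mean member gene statistic, with
  a null built from same-size random gene sets and the add-one resampling
  p-value (1 + exceed)/(1 + n_perm).

Sets are filtered to members present in the gene universe and to a size range
(default 10-200 genes) before testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "gage_unpaired",
    "permutation_gsa",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene-id sets with optional per-set descriptions."""

    sets: dict  # name -> set of gene ids
    descriptions: dict = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def filtered(self, universe, min_size: int = 10, max_size: int = 200):
        """Sets intersected with ``universe`` and restricted to the size range.

        Returns ``(kept: dict, skipped: list of (name, reason))``.
        """
        universe = set(universe)
        kept, skipped = {}, []
        for name, members in self.sets.items():
            inter = members & universe
            if len(inter) < min_size:
                skipped.append((name, f"size {len(inter)} < {min_size} after filtering"))
            elif len(inter) > max_size:
                skipped.append((name, f"size {len(inter)} > {max_size} after filtering"))
            else:
                kept[name] = inter
        for name, reason in skipped:
            logger.info("skipping gene set %s: %s", name, reason)
        return kept, skipped


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, member ids...).

    Duplicate members within a line are removed; a malformed line (fewer than
    three fields) raises a parse error naming its line number.
    """
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (needs name, "
                    f"description and >= 1 member, got {len(fields)} fields)"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets")
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(map(str, members))]) + "\n")


def _welch_t(mean1, var1, n1, mean2, var2, n2):
    """Welch t statistic and degrees of freedom (vectorised, guards zero SE)."""
    se2 = var1 / n1 + var2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2**2 / (
            (var1 / n1) ** 2 / np.maximum(n1 - 1, 1)
            + (var2 / n2) ** 2 / np.maximum(n2 - 1, 1)
        )
    t = np.where(se2 > 0, t, 0.0)
    df = np.where(np.isfinite(df) & (df > 0), df, np.maximum(n1 + n2 - 2, 1))
    return t, df


def gage_unpaired(
    gene_stats: pd.Series,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 200,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-sample set-level test of member vs non-member gene statistics.

    Parameters
    ----------
    gene_stats
        Per-gene contrast statistic (e.g. moderated t or logFC) indexed by
        gene id; defines the universe.
    sets
        Gene-set collection; filtered to the universe and size range first.
    q_threshold
        FDR threshold used to set the ``significant`` flag (use 0.01 for
        mean-temperature contrasts, 0.05 for regime and ramping contrasts).

    Returns a DataFrame with one row per (set, direction): ``size``, ``stat``
    (Welch t), one-sided ``p``, ``q`` (BH within direction) and
    ``significant``.
    """
    stats_ser = pd.Series(gene_stats).astype(float)
    universe = stats_ser.index
    kept, _ = sets.filtered(universe, min_size, max_size)
    values = stats_ser.to_numpy()
    pos = {g: i for i, g in enumerate(universe)}

    rows = []
    for name, members in kept.items():
        idx = np.fromiter((pos[g] for g in members), dtype=int)
        mask = np.zeros(len(values), dtype=bool)
        mask[idx] = True
        mem, rest = values[mask], values[~mask]
        t, df = _welch_t(
            mem.mean(), mem.var(ddof=1), len(mem), rest.mean(), rest.var(ddof=1), len(rest)
        )
        p_up = float(stats.t.sf(t, df))  # members greater
        p_down = float(stats.t.cdf(t, df))  # members smaller
        rows.append((name, "up", len(mem), float(t), p_up))
        rows.append((name, "down", len(mem), float(t), p_down))
    result = pd.DataFrame(rows, columns=["set", "direction", "size", "stat", "p"])
    result["q"] = np.nan
    for direction in ("up", "down"):
        mask = result["direction"] == direction
        if mask.any():
            result.loc[mask, "q"] = bh_fdr(result.loc[mask, "p"].to_numpy())
    result["significant"] = result["q"] <= q_threshold
    return result


def permutation_gsa(
    gene_stats: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    min_size: int = 10,
    max_size: int = 200,
    q_threshold: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation gene-set analysis with mean-statistic set scores.

    The set statistic is the mean of its member genes' statistics; the null
    draws same-size uniform random gene sets from the universe ``n_perm``
    times.  One-sided p-values use the add-one resampling convention
    ``p = (1 + #exceed) / (1 + n_perm)``; BH FDR is applied across sets
    within each direction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stats_ser = pd.Series(gene_stats).astype(float)
    values = stats_ser.to_numpy()
    universe = stats_ser.index
    kept, _ = sets.filtered(universe, min_size, max_size)
    pos = {g: i for i, g in enumerate(universe)}
    sizes = sorted({len(m) for m in kept.values()})

    # One shuffled copy of the statistics per permutation serves every set
    # size at once: the first k entries of a random permutation are a uniform
    # size-k subset.
    rng = np.random.default_rng(seed)
    max_k = max(sizes, default=0)
    null_means = {k: np.empty(n_perm) for k in sizes}
    for b in range(n_perm):
        perm = rng.permutation(len(values))[:max_k]
        csum = np.cumsum(values[perm])
        for k in sizes:
            null_means[k][b] = csum[k - 1] / k

    rows = []
    for name, members in kept.items():
        idx = np.fromiter((pos[g] for g in members), dtype=int)
        k = len(idx)
        obs = float(values[idx].mean())
        null = null_means[k]
        p_up = (1 + int(np.sum(null >= obs))) / (1 + n_perm)
        p_down = (1 + int(np.sum(null <= obs))) / (1 + n_perm)
        rows.append((name, "up", k, obs, p_up))
        rows.append((name, "down", k, obs, p_down))
    result = pd.DataFrame(rows, columns=["set", "direction", "size", "stat", "p"])
    result["q"] = np.nan
    for direction in ("up", "down"):
        mask = result["direction"] == direction
        if mask.any():
            result.loc[mask, "q"] = bh_fdr(result.loc[mask, "p"].to_numpy())
    result["significant"] = result["q"] <= q_threshold
    return result
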