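"""Gene-list overlap counts and Monte-Carlo permutation overlap nulls.

The overlap null asks: if each contrast's significant-gene list had been a
uniformly random subset of the gene universe of the same size, how often
would the all-way intersection be at least as large as observed?  Each
permutation redraws every list as an independent same-size random subset
(equivalent to permuting gene labels) and the empirical P is the plain
fraction of permutations whose random overlap reaches the observed one — no
add-one correction, so a P of exactly 0 is possible and is reported together
with the 1/n_perm resolution bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = ["GeneList", "OverlapResult", "venn_counts", "permutation_overlap_p"]


@dataclass(frozen=True)
class GeneList:
    """A labelled set of gene ids (optionally a direction tag)."""

    label: str
    members: frozenset
    direction: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_ids(cls, label, ids, direction=None) -> "GeneList":
        return cls(label=label, members=frozenset(ids), direction=direction)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for gid in sorted(map(str, self.members)):
                fh.write(gid + "\n")

    @classmethod
    def read(cls, path, label=None) -> "GeneList":
        with open(path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        return cls(label=label or str(path), members=frozenset(ids))


@dataclass
class OverlapResult:
    """Observed all-way overlap plus its Monte-Carlo null."""

    observed: int
    n_perm: int
    exceed_count: int
    empirical_p: float
    null_mean: float
    null_sd: float
    venn: dict = field(default_factory=dict)
    list_sizes: tuple = ()
    universe_size: int = 0

    @property
    def p_resolution(self) -> float:
        """Smallest non-zero P representable: 1 / n_perm."""
        return 1.0 / self.n_perm

    def summary(self) -> str:
        p_txt = f"{self.empirical_p:.6g}"
        if self.exceed_count == 0:
            p_txt = f"0 (P < {self.p_resolution:g})"
        return (
            f"Overlap of {len(self.list_sizes)} lists (sizes {self.list_sizes}) "
            f"in a universe of {self.universe_size}: observed {self.observed}, "
            f"null {self.null_mean:.2f} +/- {self.null_sd:.2f} "
            f"({self.n_perm} permutations), empirical P = {p_txt}"
        )


def venn_counts(lists: list[GeneList]) -> dict:
    """Counts of every non-empty membership region among 2-4 lists.

    Keys are tuples of 0/1 flags, one per list in order (e.g. ``(1, 1, 0)``
    is the region of elements in the first two lists only); values are the
    element counts.  Region counts sum to the size of the union.
    """
    k = len(lists)
    if not 2 <= k <= 4:
        raise ValueError("venn_counts supports between 2 and 4 lists")
    union = set().union(*(gl.members for gl in lists))
    counts = {key: 0 for key in product((0, 1), repeat=k) if any(key)}
    for gid in union:
        key = tuple(int(gid in gl.members) for gl in lists)
        counts[key] += 1
    return counts


def _random_overlap_batch(rng, universe_size, sizes, batch):
    """Sizes of the all-way intersection for ``batch`` permutations.

    Each list is redrawn as a uniform same-size subset by shuffling a boolean
    membership row per permutation; the intersection is the AND across lists.
    The joint law of the intersection is invariant under a common relabeling
    of the universe, so the largest list is kept as a fixed prefix and only
    the remaining lists are shuffled.
    """
    order = np.argsort(sizes)[::-1]
    inter = np.zeros((batch, universe_size), dtype=bool)
    inter[:, : sizes[order[0]]] = True
    for s in (sizes[i] for i in order[1:]):
        row = np.zeros(universe_size, dtype=bool)
        row[:s] = True
        members = np.tile(row, (batch, 1))
        rng.permuted(members, axis=1, out=members)
        inter &= members
    return inter.sum(axis=1)


def permutation_overlap_p(
    lists: list[GeneList],
    universe,
    n_perm: int = 100_000,
    seed: int = 0,
    batch_size: int = 2000,
) -> OverlapResult:
    """Monte-Carlo empirical P for the all-way overlap of gene lists.

    Parameters
    ----------
    lists
        Two or more gene lists, all subsets of ``universe``.
    universe
        The gene universe the lists were drawn from (all assayed genes).
    n_perm
        Number of label permutations.
    seed
        Seed for the permutation stream.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = frozenset(universe)
    for gl in lists:
        if not gl.members <= universe:
            extra = sorted(map(str, gl.members - universe))[:5]
            raise ValueError(f"list {gl.label!r} has members outside the universe: {extra}")
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    sizes = tuple(len(gl) for gl in lists)
    observed = len(frozenset.intersection(*(gl.members for gl in lists)))

    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        draws[done : done + b] = _random_overlap_batch(rng, len(universe), sizes, b)
        done += b

    exceed = int(np.sum(draws >= observed))
    venn = venn_counts(lists) if 2 <= len(lists) <= 4 else {}
    return OverlapResult(
        observed=observed,
        n_perm=n_perm,
        exceed_count=exceed,
        empirical_p=exceed / n_perm,
        null_mean=float(draws.mean()),
        null_sd=float(draws.std()),
        venn=venn,
        list_sizes=sizes,
        universe_size=len(universe),
    )
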