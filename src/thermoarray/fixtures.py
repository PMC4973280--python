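"""Toy gene-set collections and a small bundled-style test dataset.

The gene-set fixture mirrors the synthetic effect architecture: a
"phototransduction_like" set equal to the generator's constrained-positive
fluctuation subset, a "chaperone_like" set equal to the ramping module's
constrained subset, an "oxidative_phosphorylation_like" set built from
mean-temperature-module genes that are down-regulated at the warmer mean, and
a configurable number of uniform random decoy sets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geneset import GeneSetCollection, write_gmt
from .synthdata import (
    ArchitectureConfig,
    GeneArchitecture,
    ctmax_group_means,
    generate_architecture,
    generate_design,
    simulate_ctmax,
    simulate_expression,
)

__all__ = ["architecture_gene_sets", "write_fixture_dataset"]


def architecture_gene_sets(
    architecture: GeneArchitecture,
    n_random: int = 40,
    random_size_range: tuple = (10, 100),
    seed: int = 0,
) -> GeneSetCollection:
    """Gene sets wired to the ground-truth modules plus random decoys."""
    rng = np.random.default_rng(seed)
    gene_ids = architecture.gene_ids
    sets: dict = {}
    descriptions: dict = {}

    photo = list(gene_ids[architecture.phototransduction_subset])
    if photo:
        sets["phototransduction_like"] = set(photo)
        descriptions["phototransduction_like"] = (
            "generator genes constrained up-regulated under fluctuating regimes"
        )
    chap = list(gene_ids[architecture.chaperone_subset])
    if chap:
        sets["chaperone_like"] = set(chap)
        descriptions["chaperone_like"] = (
            "generator genes constrained up-regulated under heat ramping"
        )
    down_at_warm = np.where(architecture.mean_temp_effect < 0)[0]
    if len(down_at_warm) >= 10:
        order = np.argsort(architecture.mean_temp_effect[down_at_warm])
        pick = down_at_warm[order[: min(50, len(down_at_warm))]]
        sets["oxidative_phosphorylation_like"] = set(gene_ids[pick])
        descriptions["oxidative_phosphorylation_like"] = (
            "strongest generator genes down-regulated at the warmer mean temperature"
        )

    lo, hi = random_size_range
    hi = min(hi, len(gene_ids))
    for j in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        sets[f"random_{j:03d}"] = set(gene_ids[members])
        descriptions[f"random_{j:03d}"] = "uniform random decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions, source="synthetic")


def write_fixture_dataset(outdir, seed: int = 0, n_genes: int = 500, replicates: int = 3):
    """Write a small synthetic dataset (matrix, annotations, CTmax, GMT).

    Scaled-down module sizes keep the same qualitative architecture as the
    full generator defaults.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = ArchitectureConfig(
        n_genes=n_genes,
        mean_temp_module_size=max(30, n_genes * 3 // 10),
        ramping_module_size=max(20, n_genes * 3 // 20),
        fluctuation_module_size=max(15, n_genes * 3 // 100),
        chaperone_size=10,
        phototransduction_size=10,
    )
    rng_seeds = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng_seeds]
    design = generate_design(replicates)
    arch = generate_architecture(config, seed=seeds[0])
    ctmax = simulate_ctmax(seed=seeds[1])
    matrix = simulate_expression(
        design, arch, seed=seeds[2], group_ctmax=ctmax_group_means(ctmax)
    )
    paths = {
        "matrix": outdir / "expression.tsv",
        "annotations": outdir / "annotations.csv",
        "ctmax": outdir / "ctmax.csv",
        "gmt": outdir / "gene_sets.gmt",
    }
    matrix.write(paths["matrix"], paths["annotations"])
    ctmax.to_csv(paths["ctmax"], index=False)
    write_gmt(architecture_gene_sets(arch, n_random=20, seed=seed), paths["gmt"])
    return paths
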