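"""End-to-end orchestration: simulate -> DE -> overlap -> PCA/ANOVA -> gene
sets -> phenotype correlation, with a machine-readable JSON report.

One global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, so any stage can be re-run in
isolation and the whole run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import ExpressionMatrix
from .diffexpr import DifferentialExpression, paper_contrast_registry
from .fixtures import architecture_gene_sets
from .geneset import gage_unpaired, permutation_gsa, write_gmt
from .listops import GeneList, permutation_overlap_p
from .multivariate import factorial_anova, pc_anova, pca
from .phenocorr import classify_genes, correlate_expression_phenotype
from .synthdata import (
    ArchitectureConfig,
    CTmaxParams,
    ctmax_group_means,
    generate_architecture,
    generate_design,
    simulate_ctmax,
    simulate_expression,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_expression", "stage_seeds"]

logger = logging.getLogger(__name__)

STAGES = ("architecture", "ctmax", "expression", "overlap", "geneset", "fixture_sets")


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage child seeds derived from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Desk-scale pipeline configuration.

    Defaults: 10,000 genes, 3 replicates per factorial cell, 100,000 overlap
    permutations and 10,000 gene-set permutations (raise ``n_perm_gsa`` to
    10**6 for publication-strength set-level resolution).
    """

    seed: int = 0
    replicates: int = 3
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    ctmax: CTmaxParams = field(default_factory=CTmaxParams)
    de_q: float = 0.05
    #: set-level FDR threshold for the mean-temperature contrast family
    gage_q_mean_temp: float = 0.01
    #: set-level FDR threshold for the fluctuation and ramping families
    gage_q_other: float = 0.05
    gsa_q: float = 0.005
    phenocorr_strict: float = 0.001
    phenocorr_relaxed: float = 0.05
    n_perm_overlap: int = 100_000
    n_perm_gsa: int = 10_000
    min_set_size: int = 10
    max_set_size: int = 200
    n_components: int = 4
    n_random_sets: int = 40
    outdir: str = "thermoarray_run"

    def __post_init__(self):
        for name in (
            "de_q",
            "gage_q_mean_temp",
            "gage_q_other",
            "gsa_q",
            "phenocorr_strict",
            "phenocorr_relaxed",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_perm_overlap < 1 or self.n_perm_gsa < 1:
            raise ValueError("permutation counts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "architecture" in data and isinstance(data["architecture"], dict):
            data["architecture"] = ArchitectureConfig(**data["architecture"])
        if "ctmax" in data and isinstance(data["ctmax"], dict):
            data["ctmax"] = CTmaxParams(**data["ctmax"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """Machine-readable per-stage summaries of one pipeline run."""

    data: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2, default=_jsonify) + "\n"

    def __getitem__(self, key):
        return self.data[key]


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_expression(matrix_tsv, annotations_csv) -> ExpressionMatrix:
    """Read and validate a TSV expression matrix with CSV annotations."""
    return ExpressionMatrix.read(matrix_tsv, annotations_csv)


def _family_threshold(config: PipelineConfig, family: str) -> float:
    return config.gage_q_mean_temp if family == "mean_temp" else config.gage_q_other


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute every stage on freshly simulated data and write all outputs.

    Stages: simulate (design, architecture, CTmax, expression), per-contrast
    moderated DE, per-family overlap nulls, PCA with per-PC factorial ANOVA,
    set-level tests per contrast, and the expression-CTmax correlation
    screen.  Returns the :class:`RunReport`; all per-stage tables are written
    under ``outdir``.
    """
    outdir = Path(outdir or config.outdir)
    seeds = stage_seeds(config.seed)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "stage_seeds": seeds,
            "config": config.to_dict(),
            "version": __version__,
        }
    }
    for sub in ("data", "de", "overlap", "pca", "geneset", "phenocorr"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    # --- simulate -------------------------------------------------------
    logger.info("simulating design, architecture, CTmax and expression")
    design = generate_design(config.replicates)
    arch = generate_architecture(config.architecture, seed=seeds["architecture"])
    ctmax = simulate_ctmax(params=config.ctmax, seed=seeds["ctmax"])
    group_means = ctmax_group_means(ctmax)
    matrix = simulate_expression(
        design, arch, seed=seeds["expression"], group_ctmax=group_means
    )
    matrix.write(outdir / "data" / "expression.tsv", outdir / "data" / "annotations.csv")
    ctmax.to_csv(outdir / "data" / "ctmax.csv", index=False)
    sets = architecture_gene_sets(
        arch, n_random=config.n_random_sets, seed=seeds["fixture_sets"]
    )
    write_gmt(sets, outdir / "data" / "gene_sets.gmt")
    report["data"] = {
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "n_flies": int(len(ctmax)),
        "group_ctmax_means": {f"{mt}_{rg}": v for (mt, rg), v in group_means.items()},
    }

    # --- CTmax two-way ANOVA -------------------------------------------
    ctmax_anova = factorial_anova(
        ctmax["ctmax"].to_numpy(),
        ctmax[["mean_temp", "regime"]],
        interactions="all",
        response="CTmax",
    )
    ctmax_anova.to_tsv(outdir / "data" / "ctmax_anova.tsv")
    report["ctmax_anova"] = {
        "residual_df": ctmax_anova.residual_df,
        "p": {
            term: float(ctmax_anova.table.loc[term, "p"])
            for term in ctmax_anova.table.index
            if term != "Residual"
        },
    }

    # --- differential expression ---------------------------------------
    logger.info("fitting moderated contrasts")
    registry = paper_contrast_registry()
    de_results: dict = {}
    de_report: dict = {}
    for family, contrasts in registry.items():
        fam: dict = {}
        for contrast in contrasts:
            res = DifferentialExpression(matrix, contrast).fit(q_threshold=config.de_q)
            de_results[contrast.name] = res
            res.to_tsv(outdir / "de" / f"{contrast.name}.tsv")
            up, down = res.gene_lists()
            GeneList.from_ids(contrast.name + "_up", up).write(
                outdir / "de" / f"{contrast.name}_up.txt"
            )
            GeneList.from_ids(contrast.name + "_down", down).write(
                outdir / "de" / f"{contrast.name}_down.txt"
            )
            fam[contrast.name] = {"up": len(up), "down": len(down)}
        fam_total = sum(v["up"] + v["down"] for v in fam.values())
        de_report[family] = {"contrasts": fam, "total_significant": fam_total}
    report["de"] = de_report
    mean_total = de_report["mean_temp"]["total_significant"]
    fluct_total = de_report["fluctuation"]["total_significant"]
    report["de"]["mean_to_fluctuation_ratio"] = (
        mean_total / fluct_total if fluct_total else float("inf")
    )

    # --- overlap nulls per family --------------------------------------
    logger.info("permutation overlap nulls")
    universe = list(matrix.gene_ids)
    overlap_report: dict = {}
    overlap_seed_root = np.random.SeedSequence(seeds["overlap"]).spawn(len(registry))
    for (family, contrasts), child in zip(registry.items(), overlap_seed_root):
        lists = []
        for contrast in contrasts:
            up, down = de_results[contrast.name].gene_lists()
            lists.append(GeneList.from_ids(contrast.name, set(up) | set(down)))
        if any(len(gl) == 0 for gl in lists):
            overlap_report[family] = {
                "note": "at least one contrast had no significant genes",
                "list_sizes": [len(gl) for gl in lists],
            }
            continue
        res = permutation_overlap_p(
            lists,
            universe,
            n_perm=config.n_perm_overlap,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        overlap_report[family] = {
            "observed": res.observed,
            "empirical_p": res.empirical_p,
            "null_mean": res.null_mean,
            "null_sd": res.null_sd,
            "list_sizes": list(res.list_sizes),
            "venn": {"".join(map(str, k)): v for k, v in res.venn.items()},
        }
        with open(outdir / "overlap" / f"{family}_venn.tsv", "w") as fh:
            fh.write("region\tcount\n")
            for key, count in res.venn.items():
                fh.write("".join(map(str, key)) + f"\t{count}\n")
    report["overlap"] = overlap_report

    # --- PCA + per-PC three-way ANOVA ----------------------------------
    logger.info("PCA and per-component ANOVA")
    pca_res = pca(matrix)
    pca_res.scores.to_csv(outdir / "pca" / "scores.tsv", sep="\t", index_label="sample_id")
    tables = pc_anova(pca_res, matrix.annotations[["mean_temp", "regime", "assay"]],
                      n_components=config.n_components)
    pc_report = {"variance_explained": pca_res.variance_explained[: config.n_components]}
    pc_report["anova_p"] = {}
    with open(outdir / "pca" / "pc_anova.txt", "w") as fh:
        for tab in tables:
            fh.write(tab.summary() + "\n\n")
            pc_report["anova_p"][tab.response] = {
                term: float(tab.table.loc[term, "p"])
                for term in tab.table.index
                if term != "Residual"
            }
    report["pca"] = pc_report

    # --- gene-set statistics per contrast -------------------------------
    logger.info("gene-set statistics")
    gsa_children = np.random.SeedSequence(seeds["geneset"]).spawn(len(de_results))
    geneset_report: dict = {}
    for (family, contrasts) in registry.items():
        for contrast in contrasts:
            stats_ser = de_results[contrast.name].table["t"]
            gage = gage_unpaired(
                stats_ser,
                sets,
                min_size=config.min_set_size,
                max_size=config.max_set_size,
                q_threshold=_family_threshold(config, family),
            )
            gage.to_csv(outdir / "geneset" / f"gage_{contrast.name}.tsv", sep="\t",
                        index=False)
            child = gsa_children[list(de_results).index(contrast.name)]
            gsa = permutation_gsa(
                stats_ser,
                sets,
                n_perm=config.n_perm_gsa,
                min_size=config.min_set_size,
                max_size=config.max_set_size,
                q_threshold=config.gsa_q,
                seed=int(child.generate_state(1)[0] % 2**31),
            )
            gsa.to_csv(outdir / "geneset" / f"gsa_{contrast.name}.tsv", sep="\t",
                       index=False)
            geneset_report[contrast.name] = {
                "gage_significant": int(gage["significant"].sum()),
                "gsa_significant": int(gsa["significant"].sum()),
                "gage_top": (
                    gage.sort_values("q").iloc[0]["set"] if len(gage) else None
                ),
            }
    report["geneset"] = geneset_report

    # --- phenotype correlation screen -----------------------------------
    logger.info("expression-CTmax correlation screen")
    mat20 = matrix.select_samples(matrix.samples_where(assay=20))
    mat35 = matrix.select_samples(matrix.samples_where(assay=35))
    res20 = correlate_expression_phenotype(mat20, group_means)
    res35 = correlate_expression_phenotype(mat35, group_means)
    classification = classify_genes(
        res20, res35, strict=config.phenocorr_strict, relaxed=config.phenocorr_relaxed
    )
    classification.to_tsv(outdir / "phenocorr" / "classification.tsv")
    for cat in ("pos_both", "neg_both", "only_20", "only_35"):
        GeneList.from_ids(cat, classification.genes_in(cat)).write(
            outdir / "phenocorr" / f"{cat}.txt"
        )
    counts = classification.counts
    pheno_report = {
        "counts": {cat: int(n) for cat, n in counts.items()},
        "n_correlated_20": int((classification.table["p20"] < config.phenocorr_strict).sum()),
        "n_correlated_35": int((classification.table["p35"] < config.phenocorr_strict).sum()),
    }
    # enrichment of the fixture phototransduction-like set among pos_both genes
    if "phototransduction_like" in sets.sets:
        indicator = (
            classification.table["category"].eq("pos_both").astype(float)
        )
        indicator.index = classification.table.index
        enrich = gage_unpaired(
            indicator, sets, min_size=config.min_set_size,
            max_size=config.max_set_size, q_threshold=0.05,
        )
        row = enrich[(enrich["set"] == "phototransduction_like") & (enrich["direction"] == "up")]
        if len(row):
            pheno_report["phototransduction_pos_both_enrichment_p"] = float(
                row["p"].iloc[0]
            )
    report["phenocorr"] = pheno_report

    run_report = RunReport(data=report)
    run_report.write(outdir / "report.json")
    return run_report
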