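"""Synthetic factorial experiments with the effect architecture the analysis assumes.

The generator emulates a 2 (developmental mean temperature: 15/25 °C) x
2 (constant/fluctuating regime) x 2 (adult assay: 20 °C control / ramped to
35 °C) factorial array experiment with three biological replicates per cell
(24 samples), plus individual-fly heat-tolerance (CTmax) measurements.

Three nearly-disjoint gene modules carry the treatment effects:

- a large *mean-temperature* module (genes shifted between 15 and 25 °C),
- a *ramping* module (genes responding to the 35 °C heat ramp, including a
  designated "chaperone" subset constrained up-regulated at 35 °C),
- a much smaller *fluctuation* module (genes responding to the fluctuating
  regime, including a designated "phototransduction" subset constrained
  up-regulated under fluctuation).

Gene-wise residual variances are drawn from a scaled inverse-chi-square prior
so that empirical-Bayes variance moderation has a correctly specified target.
A per-gene phenotype-link coefficient ties expression to the group-mean CTmax,
creating true expression-phenotype correlations concentrated in the
fluctuation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "ArchitectureConfig",
    "GeneArchitecture",
    "CTmaxParams",
    "generate_design",
    "generate_architecture",
    "simulate_expression",
    "simulate_ctmax",
    "ctmax_group_means",
    "default_group_sizes",
]

MEAN_LEVELS = (15, 25)
REGIME_LEVELS = ("constant", "fluctuating")
ASSAY_LEVELS = (20, 35)

#: CTmax assay group sizes as published for the four developmental
#: treatments: (constant 15, constant 25, fluctuating 15, fluctuating 25).
DEFAULT_GROUP_SIZES = {
    (15, "constant"): 50,
    (25, "constant"): 48,
    (15, "fluctuating"): 47,
    (25, "fluctuating"): 48,
}


def default_group_sizes() -> dict:
    return dict(DEFAULT_GROUP_SIZES)


def generate_design(replicates: int = 3) -> pd.DataFrame:
    """Full 2x2x2 factorial sample sheet with ``replicates`` per cell.

    Returns a DataFrame indexed by sample id with columns ``mean_temp``,
    ``regime``, ``assay`` and ``replicate`` (8 * replicates rows).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for mean_temp in MEAN_LEVELS:
        for regime in REGIME_LEVELS:
            for assay in ASSAY_LEVELS:
                for rep in range(1, replicates + 1):
                    sid = f"T{mean_temp}_{regime[0]}_{assay}_r{rep}"
                    rows.append((sid, mean_temp, regime, assay, rep))
    design = pd.DataFrame(
        rows, columns=["sample_id", "mean_temp", "regime", "assay", "replicate"]
    ).set_index("sample_id")
    return design


@dataclass(frozen=True)
class ArchitectureConfig:
    """Configuration of the synthetic gene-effect architecture.

    Module sizes default to a 20:1 ratio between the mean-temperature and
    fluctuation responses, mirroring the order-of-magnitude asymmetry the
    factorial design is meant to resolve.  Effect magnitudes (log2 units) are
    gamma-distributed with random signs outside the constrained subsets.
    """

    n_genes: int = 10_000
    mean_temp_module_size: int = 3000
    ramping_module_size: int = 1500
    fluctuation_module_size: int = 150
    chaperone_size: int = 50
    phototransduction_size: int = 30
    #: fraction of each later module drawn from genes already in an earlier
    #: module (pairwise overlap stays below this fraction)
    overlap_fraction: float = 0.02
    effect_shape: float = 2.0
    effect_scale: float = 0.5
    #: extra log2 shift added to chaperone ramping effects ("strongly up")
    chaperone_boost: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    #: scaled inverse-chi-square prior for gene-wise residual variances
    d0_true: float = 4.0
    s0sq_true: float = 0.05
    #: fraction of non-photo fluctuation-module genes given a phenotype link
    pheno_link_fraction: float = 0.5
    #: mean of the Gamma(8, mean/8) phenotype-link coefficient distribution,
    #: log2 units per °C of group-mean CTmax; sized so a linked gene's signal
    #: clears the typical residual noise at 12 samples and p < 0.001
    pheno_coef_mean: float = 2.0
    #: fraction of genes outside the fluctuation module with a (weaker,
    #: random-sign) phenotype link
    pheno_background_fraction: float = 0.002

    def validate(self, ) -> None:
        sizes = (
            self.mean_temp_module_size,
            self.ramping_module_size,
            self.fluctuation_module_size,
        )
        if sum(sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.chaperone_size > self.ramping_module_size:
            raise ValueError("chaperone subset exceeds the ramping module")
        if self.phototransduction_size > self.fluctuation_module_size:
            raise ValueError("phototransduction subset exceeds the fluctuation module")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")


@dataclass
class GeneArchitecture:
    """Ground-truth per-gene effects for one synthetic experiment."""

    gene_ids: pd.Index
    mean_temp_effect: np.ndarray  # log2 shift at 25 vs 15 °C
    fluctuation_effect: np.ndarray  # log2 shift fluctuating vs constant
    ramping_effect: np.ndarray  # log2 shift at 35 vs 20 °C
    baseline_means: np.ndarray
    true_variances: np.ndarray
    pheno_link: np.ndarray  # log2 units per °C of group-mean CTmax
    mean_temp_module: np.ndarray  # gene indices
    ramping_module: np.ndarray
    fluctuation_module: np.ndarray
    chaperone_subset: np.ndarray
    phototransduction_subset: np.ndarray
    config: ArchitectureConfig = field(default_factory=ArchitectureConfig)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def module_gene_ids(self, module: str) -> list:
        idx = getattr(self, module)
        return list(self.gene_ids[idx])


def _draw_module(rng, n_genes, size, used, overlap_fraction):
    """Draw a module of ``size`` gene indices, re-using at most
    ``overlap_fraction * size`` genes already claimed by earlier modules."""
    used_arr = np.fromiter(used, dtype=int) if used else np.empty(0, dtype=int)
    n_overlap = min(int(round(overlap_fraction * size)), len(used_arr))
    free = np.setdiff1d(np.arange(n_genes), used_arr, assume_unique=False)
    if size - n_overlap > len(free):
        raise ValueError("module sizes exceed the available gene universe")
    fresh = rng.choice(free, size=size - n_overlap, replace=False)
    shared = (
        rng.choice(used_arr, size=n_overlap, replace=False)
        if n_overlap
        else np.empty(0, dtype=int)
    )
    return np.sort(np.concatenate([fresh, shared]))


def generate_architecture(
    config: ArchitectureConfig | None = None,
    seed: int = 0,
    n_genes: int | None = None,
) -> GeneArchitecture:
    """Draw a reproducible gene-effect architecture.

    Magnitudes come from ``Gamma(effect_shape, effect_scale)``; signs are
    random except for the phototransduction subset (positive under
    fluctuation) and the chaperone subset (positive, boosted, under ramping).
    """
    config = config or ArchitectureConfig()
    if n_genes is not None:
        config = replace(config, n_genes=n_genes)
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    used: set = set()
    mean_mod = _draw_module(rng, n, config.mean_temp_module_size, used, config.overlap_fraction)
    used.update(mean_mod)
    ramp_mod = _draw_module(rng, n, config.ramping_module_size, used, config.overlap_fraction)
    used.update(ramp_mod)
    fluct_mod = _draw_module(
        rng, n, config.fluctuation_module_size, used, config.overlap_fraction
    )

    chaperone = np.sort(rng.choice(ramp_mod, size=config.chaperone_size, replace=False))
    photo = np.sort(rng.choice(fluct_mod, size=config.phototransduction_size, replace=False))

    def signed_effects(module, positive_subset, boost=0.0):
        eff = np.zeros(n)
        mags = rng.gamma(config.effect_shape, config.effect_scale, size=len(module))
        signs = rng.choice([-1.0, 1.0], size=len(module))
        eff[module] = mags * signs
        if len(positive_subset):
            eff[positive_subset] = np.abs(eff[positive_subset]) + boost
        return eff

    mean_effect = signed_effects(mean_mod, np.empty(0, dtype=int))
    ramp_effect = signed_effects(ramp_mod, chaperone, boost=config.chaperone_boost)
    fluct_effect = signed_effects(fluct_mod, np.empty(0, dtype=int))
    # The phototransduction subset is constrained up-regulated under
    # fluctuation, but only modestly so in the explicit regime term: these
    # genes are phenotype-linked below, and the link term carries most of
    # their fluctuation response (fluctuating groups have higher CTmax).
    fluct_effect[photo] = rng.gamma(2.0, 0.25, size=len(photo))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    # scaled inverse-chi-square: d0 * s0^2 / chisq(d0)
    true_var = config.d0_true * config.s0sq_true / rng.chisquare(config.d0_true, size=n)

    pheno = np.zeros(n)
    non_photo = np.setdiff1d(fluct_mod, photo)
    n_link = int(round(config.pheno_link_fraction * len(non_photo)))
    linked = (
        rng.choice(non_photo, size=n_link, replace=False)
        if n_link
        else np.empty(0, dtype=int)
    )
    coef = lambda size: rng.gamma(8.0, config.pheno_coef_mean / 8.0, size=size)
    pheno[photo] = coef(len(photo))
    pheno[linked] = coef(len(linked))
    # Linked non-photo genes respond to fluctuation through the phenotype
    # link itself (fluctuating groups have higher CTmax); an independent
    # random-sign regime effect on top would mask the linear link at n = 12.
    fluct_effect[linked] = 0.0
    background = np.setdiff1d(np.arange(n), fluct_mod)
    n_bg = int(round(config.pheno_background_fraction * len(background)))
    if n_bg:
        bg = rng.choice(background, size=n_bg, replace=False)
        pheno[bg] = coef(n_bg) * rng.choice([-1.0, 1.0], size=n_bg)

    return GeneArchitecture(
        gene_ids=gene_ids,
        mean_temp_effect=mean_effect,
        fluctuation_effect=fluct_effect,
        ramping_effect=ramp_effect,
        baseline_means=baseline,
        true_variances=true_var,
        pheno_link=pheno,
        mean_temp_module=mean_mod,
        ramping_module=ramp_mod,
        fluctuation_module=fluct_mod,
        chaperone_subset=chaperone,
        phototransduction_subset=photo,
        config=config,
    )


def simulate_expression(
    design: pd.DataFrame,
    architecture: GeneArchitecture,
    seed: int = 0,
    group_ctmax: dict | None = None,
) -> ExpressionMatrix:
    """Simulate a log2 expression matrix for ``design`` under ``architecture``.

    The expected value for gene g in a sample is::

        baseline[g] + b_mean[g]*x_mean + b_fluct[g]*x_fluct + b_ramp[g]*x_ramp

    with indicator coding (reference cell: 15 °C, constant, 20 °C assay) and
    independent Normal(0, true_variances[g]) noise.  When ``group_ctmax`` maps
    ``(mean_temp, regime)`` to a group-mean CTmax, phenotype-linked genes
    additionally receive ``pheno_link[g] * (ctmax_group - mean(ctmax))``.
    """
    rng = np.random.default_rng(seed)
    x_mean = (design["mean_temp"] == 25).to_numpy(float)
    x_fluct = (design["regime"] == "fluctuating").to_numpy(float)
    x_ramp = (design["assay"] == 35).to_numpy(float)

    mu = (
        architecture.baseline_means[:, None]
        + np.outer(architecture.mean_temp_effect, x_mean)
        + np.outer(architecture.fluctuation_effect, x_fluct)
        + np.outer(architecture.ramping_effect, x_ramp)
    )
    if group_ctmax is not None:
        centred = {
            k: v - float(np.mean(list(group_ctmax.values()))) for k, v in group_ctmax.items()
        }
        try:
            pheno_x = np.array(
                [centred[(mt, rg)] for mt, rg in zip(design["mean_temp"], design["regime"])]
            )
        except KeyError as exc:  # pragma: no cover - config error path
            raise KeyError(f"group_ctmax missing developmental group {exc.args[0]}") from exc
        mu = mu + np.outer(architecture.pheno_link, pheno_x)

    noise = rng.standard_normal(mu.shape) * np.sqrt(architecture.true_variances)[:, None]
    values = pd.DataFrame(mu + noise, index=architecture.gene_ids, columns=design.index)
    return ExpressionMatrix(values, design.copy())


@dataclass(frozen=True)
class CTmaxParams:
    """Ground-truth model for individual-fly critical thermal maxima.

    ``ctmax = baseline + slope*(mean_temp - 15) + fluct_effect[mean_temp] *
    1[fluctuating] + Normal(0, sd)``.  The 0.1 °C/°C acclimation slope is the
    canonical figure for drosophilids; the remaining defaults are illustrative
    values chosen to preserve the qualitative ordering (constant-15 lowest,
    fluctuating-25 highest) with a smaller fluctuation benefit at 25 °C.
    """

    baseline: float = 37.5
    slope: float = 0.1
    fluct_effect_15: float = 0.55
    fluct_effect_25: float = 0.25
    sd: float = 0.35

    def fluct_effect(self, mean_temp: int) -> float:
        return self.fluct_effect_15 if mean_temp == 15 else self.fluct_effect_25

    def group_mean(self, mean_temp: int, regime: str) -> float:
        return (
            self.baseline
            + self.slope * (mean_temp - 15)
            + (self.fluct_effect(mean_temp) if regime == "fluctuating" else 0.0)
        )


def simulate_ctmax(
    group_sizes: dict | None = None,
    params: CTmaxParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the individual-fly CTmax table.

    ``group_sizes`` maps ``(mean_temp, regime)`` to a fly count (defaults to
    the published 50/48/47/48).  Returns a DataFrame with columns ``fly_id``,
    ``mean_temp``, ``regime`` and ``ctmax``.
    """
    group_sizes = group_sizes or default_group_sizes()
    params = params or CTmaxParams()
    if params.sd < 0:
        raise ValueError("individual sd must be >= 0")
    if any(n < 1 for n in group_sizes.values()):
        raise ValueError("every developmental group needs at least one fly")
    rng = np.random.default_rng(seed)
    rows = []
    for (mean_temp, regime), n in group_sizes.items():
        mu = params.group_mean(mean_temp, regime)
        vals = mu + rng.normal(0.0, params.sd, size=n)
        for j, v in enumerate(vals, start=1):
            rows.append((f"fly_{mean_temp}_{regime[0]}_{j:03d}", mean_temp, regime, float(v)))
    return pd.DataFrame(rows, columns=["fly_id", "mean_temp", "regime", "ctmax"])


def ctmax_group_means(ctmax_table: pd.DataFrame) -> dict:
    """Group-mean CTmax per developmental treatment (mean_temp, regime)."""
    grouped = ctmax_table.groupby(["mean_temp", "regime"], sort=True)["ctmax"].mean()
    return {key: float(v) for key, v in grouped.items()}
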