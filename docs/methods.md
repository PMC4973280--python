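# Methods

This note documents the statistical machinery implemented in `thermoarray`,
the assumptions behind it, the defaults of the synthetic-data generator, and
the numerical choices that were genuinely open.

## Study design being modelled

The toolkit targets a 2 × 2 × 2 factorial acclimation experiment on an
insect ectotherm: development under a **mean temperature** of 15 or 25 °C,
under a **constant or diurnally fluctuating** regime, followed by an adult
**assay treatment** — either a 20 °C control or a slow heat ramp
(0.1 °C min⁻¹ from 20 °C) to 35 °C — with three biological replicates per
cell (24 arrays).  In parallel, individual heat tolerance (CTmax, the
temperature of motor-function loss under the same ramp) is measured for
~50 flies per developmental treatment.

## Thermal regimes

A fluctuating regime is a nocturnal baseline plus a Gaussian daytime bump,
made 24-h periodic through a circular time distance:

    T(t) = T_base + A · exp(−d(t)² / 2σ²),   d(t) = circular distance to the peak hour.

Only three numbers characterise a cabinet programme — daily mean, daily
minimum and daily maximum — so the parameterisation sets the baseline to the
daily minimum, the amplitude to the daily range, and solves σ from the
requirement that the 24-h time-average equal the daily mean.  The solver uses
Brent root finding on σ ∈ [0.1, 12] h against the quadrature-integrated
periodic mean (residual tolerance 10⁻⁶ °C; the package-level contract is
10⁻³ °C).  For the two regimes of interest (12–20 °C around a 15 °C mean,
22–30 °C around a 25 °C mean) the constraint is scale-free in the range, and
both solve to σ ≈ 3.59 h.

Open choices, recorded as explicit configuration rather than assumptions:
whether the cabinet used a truncated or periodic Gaussian (we use the
periodic form, matching a repeating daily cycle), and the peak hour
(default 14:00, an afternoon maximum; it does not affect the daily mean).
A mean too close to the daily maximum is infeasible for any σ ≤ 12 h and
raises an error rather than silently clipping.

## Synthetic-data generator

The generator is first-class, tested code.  It emulates the *effect
architecture* the analysis assumes, not raw microarray physics (no
probe-level simulation, normalisation artefacts or batch effects — the
matrix is born on the post-normalisation log2 scale).

- **Design**: the full factorial sample sheet, default 3 replicates/cell.
- **Modules**: three nearly disjoint gene sets carry the treatment effects —
  mean-temperature (default 3000 of 10,000 genes), ramping (1500, containing
  a 50-gene "chaperone" subset constrained up at 35 °C with a +1 log2
  boost), and a much smaller fluctuation module (150, a 20:1 asymmetry,
  containing a 30-gene "phototransduction" subset constrained up under
  fluctuation).  Pairwise module overlap is controlled by one fraction
  (default 2 %), so the three responses are nearly independent by
  construction.  Effect magnitudes are Gamma(2, 0.5) log2 units with random
  signs outside the constrained subsets.
- **Noise**: gene-wise residual variances are scaled inverse-chi-square,
  σ²_g = d₀s₀²/χ²_{d₀}, with d₀ = 4 and s₀² = 0.05 (documented, arbitrary
  defaults).  This makes the empirical-Bayes moderation below correctly
  specified, so hyper-parameter recovery is a meaningful test.
- **Expression model**: indicator coding with reference cell (15 °C,
  constant, 20 °C); no simulated interactions by default (an interaction in
  the phenotype is config-gated off because the CTmax interaction is treated
  as absent); i.i.d. Gaussian noise.
- **CTmax**: ctmax = 37.5 + 0.1·(mean_temp − 15) + fluct(mean_temp)·1[fluct]
  + N(0, 0.35²) °C, with fluctuation benefits +0.55/+0.25 °C at 15/25 °C.
  The 0.1 °C per °C acclimation slope is the canonical drosophilid figure;
  the other values are illustrative and only the qualitative ordering
  (constant-15 lowest, fluctuating-25 highest) is treated as meaningful.
- **Phenotype link**: a per-gene coefficient ties expression to the
  group-mean CTmax (the term is pheno_link·(CTmax_group − mean), added at
  simulation time when group means are supplied).  Links are concentrated in
  the fluctuation module: the phototransduction subset plus half of the
  remaining module genes, with a thin (0.2 %) random-sign background.
  Coefficients are Gamma(8, 0.25) (mean 2.0 log2 units per °C).  Two
  deliberate design choices make links *detectable by design*: (i) the
  coefficient scale is set so that the ~0.5 °C spread of group CTmax clears
  the typical residual noise at n = 12 samples under the conservative
  p < 0.001 screen; (ii) linked non-photo genes carry their fluctuation
  response through the link itself (their explicit regime effect is zeroed)
  and the photo subset keeps only a modest Gamma(2, 0.25) explicit effect,
  because an independent random-sign regime effect superimposed on a linear
  phenotype link masks the correlation.  A generator with weak or
  conflicting links would make the correlation screen fail for reasons
  unrelated to the implementation under test.

What passing tests therefore show: the pipeline recovers architecture that
is there by construction under i.i.d. Gaussian noise.  What they do not
show: robustness to correlated noise, batch structure, probe-level
artefacts, or link effect sizes near the detection boundary.

## Differential expression

Contrasts are stratified two-group comparisons (e.g. 15 vs 25 °C within
constant-regime, 20 °C-assay samples); the registry enumerates the twelve
such contrasts in three families.  Stratified fits are the default because
per-contrast gene lists are the unit of all downstream analysis; a pooled
main-effect contrast can be built explicitly but is not part of the
registry.  Positive logFC means higher in the second-named condition.

Moderation follows the standard hierarchical-variance model.  With s²_g the
pooled two-group variance on d = n₁+n₂−2 df, the hyper-parameters are
estimated by closed-form method of moments on z = log s²: with
e_g = z_g − ψ(d/2) + log(d/2),

    ψ′(d₀/2) = max(0, var(e) − ψ′(d/2)),      s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)),

(d₀ = ∞ when the excess dispersion is ≤ 0), the posterior variance is
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), and the moderated t has d₀ + d df
(normal in the infinite limit).  Method of moments was chosen over marginal
likelihood because it is deterministic, closed-form and directly testable;
the implementation agrees with the reference Bioconductor implementation to
machine precision on shared inputs (cross-checked in the test suite via
Rscript).  One deliberate deviation: in the degenerate d₀ = ∞ branch s₀² is
the geometric mean of the observed s² rather than exp(mean e), so that
identical gene-wise variances pass through moderation unchanged.

P-values are two-sided; FDR control is Benjamini–Hochberg step-up, applied
per contrast and never pooled across contrasts.

## Overlap nulls

The Venn machinery counts all 2^k − 1 membership regions for 2–4 lists.
The Monte-Carlo null redraws every list as a uniform same-size subset of
the gene universe (equivalent to permuting gene labels — the only
exchangeable structure available) and records the size of the **all-way
intersection**; a config switch sums pairwise overlaps instead, since which
statistic is meant for >2 lists is genuinely ambiguous.  The empirical P is
the plain fraction of permutations with overlap ≥ observed, with **no
add-one correction**: a raw 0 is reported together with the 1/n_perm
resolution bound rather than claimed as an exact zero.  The engine shuffles
boolean membership rows in batches; the largest list is kept fixed, which
leaves the intersection law unchanged (the joint distribution is invariant
under a common relabelling of the universe).  For two lists the null is
exactly hypergeometric, which the tests exploit as an independent
closed-form oracle.

## PCA and factorial ANOVA

PCA centres each gene (no unit-variance scaling — expression already shares
the log2 scale) and decomposes the centred sample × gene matrix by SVD;
variance fractions are λ_i/Σλ, and each component's sign is fixed by making
its largest-magnitude loading positive.  The ANOVA engine computes
sequential (Type I) sums of squares from nested least-squares fits in the
declared term order (main effects in column order, then interactions); for
the balanced 24-array design this is order-invariant and decomposes the
total SS exactly, and for the unbalanced CTmax table the residual df — the
only design-determined quantity — is order-invariant.  The SS type was an
open choice; sequential is the default and an explicit `terms` argument
allows any order.  F compares each term's mean square against the full
model's residual mean square; empty cells for a requested interaction raise
an estimability error.  Per-PC three-way tables are produced for the first
four components by default.

## Gene-set statistics

Two set-level tests, both restricted to sets with 10–200 members after
intersection with the universe:

- a **two-sample ("unpaired") set test**: Welch t of member vs non-member
  gene statistics (default: moderated t from the contrast), one-sided p per
  direction, BH-FDR per direction.  This is a self-contained
  re-specification of the unpaired pathway test popular for expression
  data; equivalence with any external implementation's internals is not
  claimed.  Thresholds follow the analysis conventions: FDR 0.01 for
  mean-temperature contrasts, 0.05 for regime and ramping contrasts.
- a **permutation GSA**: set statistic = mean member statistic; the null
  draws same-size uniform gene sets (one shuffled statistic vector per
  permutation serves every set size via prefix means); p = (1 + exceed)/(1 +
  n_perm) — the add-one convention standard for resampling p-values, a
  documented difference from the overlap module's plain fraction, which
  follows the stated overlap definition instead.  Default FDR cutoff 0.005;
  desk default 10⁴ permutations (10⁶ via config).

## Phenotype correlation screen

Each sample at one assay temperature is assigned its developmental group's
mean CTmax — four distinct phenotype values across 12 samples, the
replicate-level reading of "correlated to the group's heat tolerance"; a
group-level alternative (n = 4) is available via config.  Pearson
correlation is the default (Spearman via config), p from
t = r√(n−2)/√(1−r²).  Genes are classified across the two assay
temperatures with a strict threshold (p < 0.001) for presence and a relaxed
one (p > 0.05) for absence: `pos_both`/`neg_both`/two `sign_switch`
categories (strict at both), `only_20`/`only_35` (strict at one, clearly
absent at the other), `ambiguous` (strict at one, 0.001–0.05 at the other),
`ns` otherwise; zero-variance genes are flagged and classified `ns`.  The
partition is exhaustive and mutually exclusive.

**Calibration caveat.**  Because replicates share their group's phenotype
value, the nominal p is calibrated only for genes with no treatment
structure at all.  Any gene responding to the design factors correlates
with *any* group-level phenotype (pseudo-replication), so the realised
null rate at p < 0.001 is far above 0.001.  The package exposes a
phenotype-label permutation (`phenotype_permutation_null`) that estimates
the empirically calibrated rate; note the observed assignment is one of
only 4! = 24 label assignments, so the observed rate is compared against
that family's support rather than its mean.  Screen results should be read
as ranking candidates, not as calibrated hypothesis tests.

## Pipeline

`run_pipeline` executes simulate → CTmax ANOVA → per-contrast DE →
per-family overlap nulls → PCA with per-PC ANOVA → set-level tests →
phenotype screen, writing per-stage TSVs and a JSON report whose counts are
recomputable from the written tables.  One global seed is fanned out to
per-stage child seeds via `SeedSequence.spawn`, so runs are bit-reproducible
and stages can be re-run in isolation.  Desk-scale defaults: 10,000 genes,
3 replicates, 100,000 overlap permutations (~2 min of the ~3 min default
run), 10,000 GSA permutations.  The bundled gene-set fixture wires
"phototransduction-like", "chaperone-like" and
"oxidative-phosphorylation-like" sets to the generator's ground-truth
modules, plus uniform random decoys.

## Problem sizes used by the test and acceptance suites

The suites run at sizes chosen to keep the statistical behaviour intact:
hyper-parameter recovery at 10,000 genes over 20 seeds; DE power at 2,000
genes over 10 seeds; overlap-vs-hypergeometric at a 1,000-gene universe and
20,000 permutations (tolerance: 3 Monte-Carlo s.e. plus the 1/n_perm
counting resolution); GSA oracle at a 200-gene universe against a 10⁶-draw
brute-force null; the qualitative effect-structure checks at the full
default 10,000-gene architecture over 20 seeds; pipeline integration tests
at 800–1,200 genes with reduced permutation counts.

## Known limitations

- The generator's i.i.d. Gaussian noise and near-disjoint modules are
  idealisations; real arrays have correlated noise and overlapping
  programmes.
- The two-sample set test re-specifies the "unpaired" method at the level
  of gene statistics; it does not reproduce any particular external
  implementation's sample-level fold-change combinatorics.
- The phenotype screen inherits the pseudo-replication caveat above.
- The ANOVA engine targets small factorial designs; it builds dense design
  matrices and is not meant for large unbalanced models.
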