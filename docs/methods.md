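# Methods

This note documents the statistical models implemented in `epitrain`, the
synthetic cohort the tests run against, the numerical choices that were
genuinely open, and the limits of what a passing test suite demonstrates.

## Measurement model and scales

A CpG probe's methylation is a beta value β ∈ (0,1); all modelling happens
on the M scale, M = log₂(β/(1−β)), where array noise is closer to additive
Gaussian. The transform pair is exact (round trip ≤ 1e-12); exact 0/1
inputs are clamped to ε = 1e-6 with a warning. Extreme outliers are masked
per probe with extended Tukey fences (below Q1 − 3·IQR or above
Q3 + 3·IQR, strict inequalities; quartiles by the linear-interpolation /
type-7 convention, so the hand-checkable vector [1,2,3,4,100] masks only
100). Masking is idempotent; masked entries become NA and all fits are
complete-case per probe.

Genomic coordinates are 1-based inclusive throughout (array-manifest
convention); conversion to BED's 0-based half-open intervals happens only
in the export function. The missing-value token on disk is always `NA`.

## Trained-immunity outcome

For each cytokine (TNF-α, IL-1β, IL-6, IFN-γ) the trained-immunity (TI)
response is built in this order: raw = log₁₀(conc_T90 / conc_T0); batch
correction by additive residualization on the measurement-batch factor
(residual plus grand mean — the simplest faithful reading of "correcting
for batch effect"); inverse-rank normalization. The rank-normal transform
uses the Blom offset, z = Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for
ties — the common EWAS/GWAS convention; the offset is configurable. The
log-ratio makes TI invariant to any common rescaling of a subject's
concentration pair.

## Cell-type deconvolution

Whole-blood composition is estimated by reference-based constrained
projection: each sample's beta profile over marker probes is the convex
combination of cell-type reference profiles that minimises squared error,
solved by non-negative least squares with the sum-to-one constraint
enforced through a heavily weighted augmentation row (weight 1e5, residual
slack ~1e-10, then exact renormalisation). The main panel has 6 leukocyte
types; a 12-type panel for sensitivity analyses is the same solver with a
different reference. Exact mixtures are recovered to 1e-6; with beta noise
of SD 0.02 the mean absolute fraction error stays below 0.05.

## Longitudinal EWAS

Per probe: `M ~ timepoint + age + sex + plate + cell fractions +
(1|subject)`. Timepoint is an unordered factor with T0 as reference
(level-wise contrasts are what the downstream trajectory analysis needs);
the overall time effect is the 2-df joint Wald test of the T14 and T90
terms, and the pairwise models (T14–T0, T90–T0, T90–T14) restrict the data
to two timepoints and report the single contrast coefficient. Sex enters
as a female indicator, plate as drop-first dummies, and cell fractions with
the last column dropped (they sum to one).

The model is fit by a dedicated profiled-REML solver for the
single-random-intercept structure: with V = σₑ²(I + θZZ′), the GLS inner
problem for fixed θ reduces to per-subject aggregation (Woodbury), leaving
a smooth one-dimensional REML criterion in log θ minimised by bounded
search (tolerance 1e-8). This is the same estimator a generic mixed-model
fitter computes, verified against one in the tests to optimizer tolerance,
but ~50× faster — per-probe refitting across thousands of probes is the
pipeline's hot loop. Solutions at the lower θ boundary (variance component
zero, a "singular" fit) fall back to OLS with CR0 cluster-robust standard
errors by subject and are tagged in the output rather than dropped.

Multiplicity is controlled with Benjamini–Hochberg FDR within each
analysis run; q < 0.05 is significant and p < 1e-5 is the suggestive
exploratory threshold. Calibration is monitored with the genomic inflation
factor λ = χ²₁-quantile(1 − median p)/0.4549.

## Robust TI associations

Associations of TI with baseline methylation, and with residualized
methylation *changes* (DNAm-C), use Huber M-estimation (tuning constant
c = 1.345, IRLS to 1e-8 or 50 iterations) with the asymptotic M-estimator
sandwich covariance (including Huber's small-sample correction factor) and
a normal reference. For DNAm-C, cell fractions and plate are first
regressed out of the M values *within each timepoint* (so timepoint-
specific composition cannot masquerade as change), and the per-subject
difference of residuals between two timepoints is the predictor, with age
and sex as covariates.

At the null-calibration scale used in the tests (n = 100 subjects, ~15
covariates) the Huber scan's realised test level is about 0.051–0.056 and
its median-based λ moves within roughly 1.00–1.05 with the cohort
realisation — an intrinsic finite-sample property of M-estimator sandwich
inference in leveraged designs (compositional cell fractions, skewed age),
documented here because the calibration tests run close to the edge of
their bands. Leverage-corrected (HC2/HC3-style) variants were evaluated and
over-correct the bulk of the distribution; the standard sandwich is kept.

## Trajectories, enrichment, replication

Trajectory classes are the sign pairs of the mean beta-value changes at
day 14 and day 90 versus baseline (down_down, down_up, up_down, up_up;
exact zeros are "flat"); classification happens on the beta scale even
though models run on M, because the deltas are the interpretable quantity.
Baseline states are tri-classed at mean β < 0.3 (hypo) and > 0.7 (hyper) —
thresholds are conventional, explicit and configurable. Direction-by-state
enrichment uses the two-sided Fisher exact test (probability-ordering
rule, verified against full hypergeometric enumeration for all tables with
N ≤ 30). Change-vs-change correlations with other layers are Spearman with
exact permutation p for n ≤ 9 and the t approximation otherwise, BH-FDR
across the pair grid. Replication in a small two-timepoint cohort counts
direction-consistent probes and those additionally reaching p < 0.05
("nominal" replication requires both).

## Variance partition

Per layer: candidate features are those with marginal Spearman p < 0.05
against TI (the methylation layer instead takes the externally supplied
EWAS-significant CpG list as-is); collinear pairs with |ρ| > 0.4 are
resolved by dropping the member with the weaker TI association, iterating
from the largest |ρ| downward with lexicographic tie-breaks so the greedy
rule is deterministic. |ρ| rather than signed ρ is used because
anti-correlated duplicates are equally collinear. The surviving features
are fit jointly by OLS and adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) is the
explained-variance measure; the combined model concatenates the per-layer
pruned sets, leaving cross-layer collinearity in place. The randomization
null redraws feature sets of fixed size and repeats the whole
select→prune→fit procedure; the empirical p uses the add-one convention.
Note the marginal-screening step makes layer estimates slightly optimistic
when many null features are screened (selection bias of order +0.05
adjusted R² for ~100 screened features at n = 300); this is a property of
the procedure itself and is visible in the recovery experiments. Polygenic
scores are Σ βⱼ·dosageⱼ with mean imputation of missing dosages; weights
can be derived as marginal OLS betas on a training split.

## QTL scan and mediation

The QTL scan residualizes phenotypes on age and sex first (two-stage), then
computes every SNP × phenotype simple regression via centred cross-products
(t on n−2 df, underflow-safe p); it matches a per-pair OLS oracle to 1e-8.
SNPs with p < 0.05 for both TI and a probe's DNAm-C define candidate
triplets.

Mediation is the linear, no-interaction product-of-coefficients model:
mediator model m = α₀ + a·x + covs, outcome model
y = β₀ + c′·x + b·m + covs, both by OLS, with age and sex included in both
models. Uncertainty is quasi-Bayesian: n_sims (default 1000) parameter
vectors are drawn from each fit's asymptotic normal; ACME draws are
a⁽ˢ⁾·b⁽ˢ⁾, ADE draws c′⁽ˢ⁾, total = ACME + ADE. Point estimates are draw
means, CIs the 2.5/97.5 percentiles, p the two-sided simulation p with the
add-one convention, and the proportion mediated the median over draws of
ACME/total (median for robustness near zero totals; an instability flag is
set when |total| < 2·SE). Direction triage runs the mediation both ways
(D1: DNAm-C mediates the genetic effect on TI; D2: TI mediates the effect
on DNAm-C) and classifies on the two ACME p-values at 0.05.

A structural caveat: in the linear Gaussian model the t statistic of the
mediator term is symmetric between the two directions (partial-correlation
symmetry), so direction triage discriminates through the two exposure
paths (g→mediator vs g→outcome-total). One-way mediation is reliably
classified as D1-unidirectional only when the mediated path is strong
while the total genetic effect on the outcome stays modest; the
direction-triage validation scenario is designed in that regime
(a = 0.15, b = 0.4, c′ = 0, mediator noise 0.5, outcome noise 1.2,
n = 500).

Cis-window extraction takes SNPs on the same chromosome within ±250 kb of
a CpG (inclusive bounds) and compares their cytokine-QTL p-values against a
size-matched random SNP set (seeded) with a two-sample KS test.

## Synthetic cohort

The generator is the test bed for everything above. Defaults mirror the
analysed discovery cohort: 284 subjects (158 F / 126 M), three timepoints,
with probe/SNP dimensions scaled to exercise the analyses (2000 probes,
200 SNPs by default). Methylation is simulated on the M scale — trimodal
baseline means (hypo/intermediate/hyper), cell-composition signal mixed in
through per-probe cell-type loadings and Dirichlet sample fractions
(concentration 50, neutrophil-dominated means, as in whole blood), plate
shifts (SD 0.3), subject random intercepts (SD 0.5), seasonal sinusoids on
selected probes, and residual noise (SD 1.0 M units) — then transformed to
beta, so betas are strictly inside (0,1) and the β↔M transform is exact by
construction. Genotypes are binomial(2, MAF) dosages with MAF ~ U(0.05,
0.5); mediation SNPs are placed in cis (≤200 kb) of their probe.
Collection dates are uniform over a year.

Spiked effects and their ledger: trajectory probes (five per class by
default, 0.6–1.0 M-unit shifts — the study itself reports no effect
magnitudes, so these are free parameters chosen once at the scale of the
power-simulation conditions); sex-specific day-90 effects; seasonal
probes; TI-associated baseline probes; mediation triplets generated as
m_change = a·(g−ḡ) + ε₁ added at T90 and fed into TI as b·m_change +
c′·(g−ḡ). TI(IFN-γ) is a variance-budgeted sum of *observed* standardized
layer signals (methylation 0.30, metabolites 0.10, genetics 0.05 by
default) plus the mediation contribution and residual noise scaled so the
total variance is ≈1 — building the signal from observed features makes
the ledger's variance fractions the population R² of those features, so
variance-partition recovery is well-defined rather than attenuated by an
arbitrary reliability factor. The mediation contribution carries no extra
per-triplet noise; the rest of the TI signal serves as the outcome-model
error.

What the generator does *not* emulate: realistic LD between SNPs, probe
spatial correlation, IDAT-level array artefacts, detection-p filtering,
non-Gaussian technical noise, and cell-composition shifts correlated with
vaccination. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative assumptions, not robustness to
every artefact of real array data.

The replication generator re-uses the ledger's effect directions at n = 17
(T0/T90 only) with independent noise; with default noise the per-probe
replication power at n = 17 is low (direction consistency is high, nominal
significance rare), which is the expected behaviour of a 17-subject arm.

## Problem sizes and determinism

The validation suite runs at deliberately chosen scales: null calibration
pools four spike-free cohorts of 2000 probes × 100 subjects (the
inflation factor λ has sampling SD ≈0.053 at 2000 p-values, so it is
evaluated on the pooled 8000); power checks use 50 seeded replicates at
n = 200 with Δ = 1.0 M units and residual SD 1; mediation type-I error uses
200 replicates; variance recovery uses 20 cohorts at n = 300. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; seeded CLI runs are byte-identical, and the
run log records seed, package version and input hashes.

## Known limitations

- The mixed model supports a single random intercept (subject); random
  slopes or crossed random effects are out of scope.
- Huber-scan p-values are asymptotic; at n ≈ 100 with ~15 covariates the
  realised level is ~0.051–0.056 (see above).
- The mediation model is linear without exposure–mediator interaction, as
  in the analysis it implements; direction triage inherits the structural
  symmetry discussed above.
- The variance-partition procedure's marginal screening is optimistically
  biased for layers with many null features; the randomization null is the
  guard against over-interpretation.
- No surrogate-variable or reference-free cell correction; cell
  composition is handled only through reference-based fractions.
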