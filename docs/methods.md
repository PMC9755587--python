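# Methods

## Scope

`coexq` implements two workflows that together cover a common
expression-profiling study design in plant reproductive biology:

1. **Δsum co-expression ranking** over a gene × tissue TPM matrix, used
   to find genes whose expression *pattern* across tissues matches a
   query gene's, regardless of absolute expression level.
2. **qPCR relative quantification**: standard-curve amplification
   efficiency QC, 2^-ΔΔCt fold changes normalized to three reference
   genes, and control-versus-treatments testing with Dunnett's
   adjustment.

Upstream steps (read trimming, genome mapping, TPM computation,
instrument-level Cq calling) are out of scope; the TPM matrix and the
long-format Cq table are the contract boundaries.

## Co-expression model

For gene *g* with TPM values *x(g, s)* over samples *s* and mean
*m(g) = mean_s x(g, s)*:

- Genes with *m(g) = 0* are expressed nowhere and are eliminated.
  Because TPM is non-negative, *m(g) = 0* iff every value is 0, so the
  filter is exact and needs no tolerance.
- The normalized profile is *z(g, s) = (x(g, s) − m(g)) / m(g)*.  It is
  dimensionless, bounded below by −1, sums to zero across samples, and
  is invariant to rescaling a gene's whole row — which is what makes
  strongly and weakly expressed genes comparable.
- The co-expression statistic is the L1 distance on profiles,
  **Δsum(a, b) = Σ_s |z_a(s) − z_b(s)|**.  It is a metric (symmetric,
  non-negative, triangle inequality), the query's self-Δsum is 0, and
  genes are ranked by it in ascending order.

**Tie-breaking.** Equal Δsums are ordered lexicographically by gene
identifier (with a stable sort), and the query is always pinned first
even when other genes also reach Δsum 0 (e.g. exact scaled copies).
Determinism here is a requirement for reproducible output tables, and
no ordering among exact ties is scientifically more defensible than
another.

**Mean scope.** When ranking is restricted to a sample subset there are
two defensible readings of "the mean": recompute it on the subset
(default, `mean_scope="subset"`) or keep the mean over all samples of
the input matrix and merely restrict the profile columns
(`mean_scope="full"`).  Both are exposed; the default keeps every
operation self-contained (subsetting first, then filtering and
normalization on what remains).  Under `full` scope z-rows no longer
sum to zero over the kept columns; that is expected, not a bug.

**Numerics.** Δsum is accumulated in double precision with
straightforward summation; profiles here have at most ~100 samples, so
compensated summation would add complexity without measurable benefit.
The z-row zero-sum identity holds to ~1e-15 relative in double
precision.

## qPCR model

**Standard curves.** Cq is regressed on log10 dilution by ordinary
least squares (three-point tenfold series, 1:10 / 1:100 / 1:1000, is
the canonical input; any ≥3 distinct dilutions are accepted).  The
amplification efficiency is E = (10^(−1/slope) − 1) × 100 %; a slope of
−1/log10 2 ≈ −3.3219 is perfect doubling (E = 100 %).  QC passes iff
R² > 0.980 and 90 % ≤ E ≤ 110 %, with each violated bound reported.
Measured efficiencies are used for QC only; quantification assumes the
literal 2 in 2^-ΔΔCt.  An efficiency-corrected mode is deliberately not
provided in this version, to keep the quantification model identical
to the standard Livak workflow.

**Replicate flow.** Technical replicates are averaged to one Cq per
(sample, gene, biological replicate) *before* any ΔCt arithmetic.  Per
biological replicate *b* of sample *s*:

    ΔCt(s, b)  = Cq_target(s, b) − mean over references of Cq_ref(s, b)
    ΔΔCt(s, b) = ΔCt(s, b) − mean_b ΔCt(calibrator, b)
    fold(s, b) = 2^(−ΔΔCt(s, b))

The arithmetic mean over reference-gene Cqs equals normalizing to the
geometric mean of reference quantities, the standard multi-reference
reading of the Livak method.  Fold changes are reported as mean ± SEM
over biological replicates (SEM = sd/√n, n = biological replicates),
matching the convention that error bars reflect biological, not
technical, variation.

**Calibrator handling.** The calibrator's per-replicate ΔCt values are
averaged into a single ΔCt_cal used for every sample, including the
calibrator itself.  Biological replicates are not paired across
tissues, so a per-replicate pairing would be arbitrary.  Consequently
the calibrator's mean fold is exactly 1 only in the noiseless limit;
with noise it is 1 in expectation (Jensen's inequality biases it
slightly above 1, negligibly at realistic noise).

**Shift invariance.** Any Cq offset common to all genes of one
(sample, bio rep) — plate effects, cDNA input differences — cancels in
ΔCt.  This is tested end-to-end by injecting large biological offsets
in the simulator and recovering exact folds.

## Statistical testing

One-way ANOVA (scipy) is followed by Dunnett's many-to-one comparison
of every sample against the calibrator.  The k contrast t-statistics
share the control mean and the pooled variance estimate, giving a
k-variate t distribution with product correlation
ρ_ij = λ_i λ_j, λ_i = √(n_i/(n_i+n0)).  The two-sided adjusted p-value
for contrast i is 1 − P(max_j |T_j| ≤ |t_i|).  Exploiting the product
structure, the rectangle probability reduces to a smooth 2-D integral
over the shared Gaussian factor and the pooled chi variable; it is
evaluated by chi-density-weighted Gauss–Legendre × Gauss–Hermite
quadrature with 48 × 48 nodes.  Against the analytically known
single-contrast case the quadrature is accurate to ~1e-14, far inside
the 1e-6 design tolerance, and — unlike randomized quasi-Monte-Carlo
integrators — bit-reproducible.  Unequal group sizes use the exact λ_i,
not an equicorrelation approximation.  With exactly one treatment
group the family degenerates to the ordinary two-sided pooled-variance
t-test and is computed analytically.

Degenerate input: zero pooled variance with unequal means yields
limiting p-values of 0 with a `RuntimeWarning`; with equal means, p = 1.

**Tested statistic.** Dunnett runs on the per-replicate ΔCt values by
default (`test_on="dct"`): ΔCt is on the log scale where qPCR noise is
approximately additive and homoscedastic, which matches the pooled
variance assumption.  `test_on="fold"` tests the fold changes instead,
since general-purpose statistics packages accept either; the choice is
surfaced, not hidden, because the two can disagree near thresholds.

**Star labels.** Adjusted p-values map to labels by the four-star step
function (* p<0.033, ** p<0.002, *** p<0.0002, **** p<0.0001, ns
otherwise), applied to the *adjusted* p — the defensible reading when
a multiplicity correction has been performed.  The calibrator row gets
no p-value (it is the control of its own family).

## Synthetic-data generators

The generators define the study conditions for all tests; they emulate
the *design* of a tissue expression atlas and a qPCR experiment, not
any particular real dataset.

**TPM matrices.** Module genes are a shared archetype profile times a
gene-specific log-normal scale (σ = 1), perturbed by multiplicative
log-normal noise of sd `noise_sd` on the natural-log scale (expression
is non-negative and right-skewed, and the profile transform is
scale-free, so multiplicative noise is the natural perturbation).
Background genes are drawn independently per sample from a log-normal
with location 1.0 and scale 1.0 (per-sample values configurable); an
exact `zero_gene_fraction` of genes is identically zero to exercise the
zero-mean filter.  Archetype shapes (flat, increasing, decreasing,
early-/mid-/stigma-peak) are fixtures mirroring qualitative atlas
patterns, not claims about real data.

**Cq plates.** The default design mirrors the canonical experiment:
five tissues (pistil stages 11/12/14, anther stage 12 as calibrator,
silique stage 17), 3 biological × 3 technical replicates, references
RCE1/TUA2/YLS8 at base Cqs 20/21/22, target base Cq 24.
Cq_target(s,b,t) = base − log2(fold(s)) + bio_offset(s,b) + ε, with
tech noise ε ~ N(0, `cq_noise_sd`²) per well and bio_offset shared by
all genes of one (sample, bio rep) pool.  Defaults `cq_noise_sd = 0.1`
cycles and `bio_noise_sd = 0.3` cycles are typical instrument and
replicate magnitudes for SYBR assays; no source values are prescribed,
so these are package choices, fixed once.

**What passing tests do and do not show.**  Recovery of planted modules
and known folds demonstrates the estimators invert their own generative
model; it does not certify performance on real data, whose noise is
neither exactly log-normal (TPM) nor exactly Gaussian (Cq), and whose
co-expression structure is not a clean archetype-plus-noise module.
In particular the Δsum ranking is sensitive to the sample set chosen
and to genes with tiny means (a small mean inflates |z|); those are
properties of the statistic itself, faithfully reproduced.

## Problem sizes and determinism

Simulation-based checks use sizes that keep the full suite fast while
leaving no statistical ambiguity: 500 × 8 matrices for module recovery,
200 plate simulations for fold-change bias, 10,000 null datasets for
the family-wise error rate of Dunnett at α = 0.05 (Monte-Carlo sd
≈ 0.002 around 0.05).  All randomness flows through
`numpy.random.default_rng` seeds carried in the generator configs; equal
seeds give byte-identical serialized outputs, and `scripts/acceptance.py`
derives every sub-seed from its `--seed` argument.

## Known limitations

- No efficiency-corrected quantification (Pfaffl-type) in this version.
- Δsum offers no secondary similarity measure (correlation etc.) and no
  clustering/enrichment of the co-expressed set; interpretation of top
  lists is left to the analyst.
- The qPCR module assumes a complete design (every reference measured
  for every sample × bio rep that has a target measurement); partial
  plates fail loudly rather than being imputed.
- Star-label thresholds are a convention of a popular statistics
  package; other conventions exist and are not configurable.
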