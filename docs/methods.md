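# Methods

`sexreg` implements a complete analysis of how sex and the X chromosome
shape regulatory variation in a human expression cohort: differential
expression mean and variance between the sexes, cis-eQTL and
genotype-by-sex interaction mapping with hierarchical FDR control, per-sex
cis heritability, sex-interacting allele-specific expression, differential
chromatin accessibility, and a trait-level test of cumulative sex bias in
eQTL effect sizes.  Because the cohorts such analyses are run on are
access-controlled, the package ships a ground-truth synthetic-cohort
generator and validates every stage against it.

## Conventions

Sex is coded male = 0 / female = 1 throughout, so every sex or
genotype-by-sex coefficient is positive when the effect is larger in
females.  VCF and gene coordinates are 1-based inclusive; peak intervals
are 0-based half-open BED.  Missing genotypes are excluded per gene-variant
pair (complete case).

On chromosome X, males are hemizygous.  The default `full_dosage` coding
maps a male alt allele to dosage 2, so one male allele carries the same
regression weight as a female homozygote — the natural choice under
dosage-compensation reasoning, where a single active allele produces a
full expression complement.  A `haploid` coding (male alt = 1) is
selectable everywhere the coding matters.  Heterozygous male X calls are
biologically impossible and are set to missing with a counter.  X minor
allele frequencies count one allele per male and two per female regardless
of the regression coding.

## Models

**cis-eQTL and interaction mapping.** For each gene, variants with
position in [TSS − 1 Mb, TES + 1 Mb] (genomic orientation) are fit by OLS:

    y = mu + b1·g + b2·s + e                 (additive, joint cohort)
    y = mu + b1·g + b2·s + b3·(g·s) + e      (interaction)

with classical standard errors and Wald t p-values (b3's p for the
interaction scan).  Single-sex strata drop the sex column.  The joint scan
requires cohort MAF ≥ 0.05; the interaction scan requires MAF ≥ 0.05 within
each sex separately and excludes variants for which the column set
{1, g, s} has numerical rank < 3 (singular values below 1e-8 of the
largest), i.e. genotype collinear with sex.  Multiple testing is
hierarchical: per gene, Bonferroni on the smallest nominal p by the number
of tests actually fitted (excluded variants do not count), then
Benjamini-Hochberg across genes' adjusted minima.  Ties break
lexicographically on variant id so outputs are order-independent.

**Differential variance (DV).** Three strategies, run on residual-scale
expression with the majority sex subsampled (seeded) to the minority count:

* `A_F` — variance-ratio F test on every gene;
* `B_gated` — Shapiro-Wilk gate on pooled, within-sex mean-centred values
  (`gate_scope="per_sex"` gates each sex separately); F test when normality
  is not rejected at α = 0.05, Brown-Forsythe (ANOVA on absolute deviations
  from group medians) otherwise;
* `C_residual` — values are quantile-normalized to N(0,1)
  (rank r → Φ⁻¹((r − 0.5)/n), midranks for ties), sex is regressed out, and
  the strategy-B gate-and-test is applied to the residuals.  Removing the
  sex mean effect separates genuine DV from DV induced by differential
  expression.

A caveat worth knowing: quantile normalization constrains the pooled
empirical distribution, so under very large mean shifts (≳0.8 SD) the
strategy-C F branch becomes conservative (type-I error ~0.02 at α = 0.05
in 274 + 274 strata).  Under the mixture of shifts the bundled generator
emulates (30% of genes shifted, SD 0.3) the empirical type-I error is
0.044-0.045, indistinguishable from nominal at 2000 genes.

**Per-sex cis PVE.** A local GRM is built from column-standardized cis
dosages (MAF ≥ 0.05 within the stratum), K = Z Zᵀ/m with trace(K) = n, and

    y = g + e,  g ~ N(0, σg² K),  e ~ N(0, σe² I)

is fit by REML: one eigendecomposition of K, then bounded 1-D maximization
of the restricted likelihood over h² = σg²/(σg² + σe²) ∈ [0, 1].  With
trace(K) = n the optimizing h² is the PVE.  A Haseman-Elston regression
(off-diagonal phenotype cross-products on GRM entries, clipped to [0, 1])
is available as `estimator="he"`; the two agree within 0.05 on
well-conditioned simulations.  Sexes are compared by Wilcoxon rank-sum
across genes on matched sample sizes.  Under full-dosage X coding an
additive allelic effect contributes twice the genetic variance in males
(dosage variance 4f(1−f) vs 2f(1−f)), which is exactly the hemizygosity
mechanism the comparison is designed to expose.

**Sex-interacting ASE.** Allelic counts are summed across sites per
(individual, gene); units under 10 reads are dropped (the depth rule is a
package default, config-exposed).  The model is a binomial GLMM,

    alt_i ~ Binomial(n_i, logistic(α + γ·h_i + δ·h_i·s_i + u_i)),
    u_i ~ N(0, τ²),

with h ∈ {−1, 0, +1} the phased regulatory contrast (unphased data can use
a het indicator, with sign aliasing noted).  The sex-interaction test is a
likelihood-ratio test of δ = 0 against χ²₁.  The random intercept is
integrated by adaptive Gauss-Hermite quadrature: per individual the
integrand's mode is found by Newton iteration (it is strictly log-concave),
nodes are centred there and scaled by the curvature, 15 nodes by default
(log-likelihood stable to <1e-4 between 9 and 15 nodes).  τ is estimated
with a lower bound near zero; fixing τ = 0 reduces the fit exactly to
logistic regression.  A beta-binomial kernel (`family="betabinom"`) is
available for allelic ratios overdispersed beyond the random intercept.
Non-converged fits are returned flagged with NaN estimates, never as
silent numbers.

**Differential accessibility.** Counts are normalized by median-of-ratios
size factors (geometric-mean reference over all-positive peaks; library
totals as fallback).  Per-peak NB dispersion is estimated by
method-of-moments within groups, α = max(0, (v − m)/m²) averaged across
groups by degrees of freedom, then a hyperbolic mean-dispersion trend
a₀/m + a₁ is fit across peaks.  The default uses the fitted trend value
per peak: with 10 samples per group the raw per-peak estimates are noisy
enough to make the exact test liberal (measured FPR 0.064 at α = 0.05),
while the max(raw, trend) rule is conservative (0.036); the trend alone is
calibrated (0.044).  Both alternatives remain selectable
(`dispersion_mode`).  The two-group test conditions on the peak's total
count and sums the joint probabilities of all splits no more likely than
the observed one (group sums modelled as NB with matched mean and
variance), computed entirely in log space.  Significance defaults to
FDR 10%.  Peaks link to genes whose strand-oriented 40 kb upstream
promoter window they intersect (genomic-left upstream selectable), and
enrichment against DE or interaction-eQTL gene sets uses Fisher's exact
test, including a directional 2×2 (expression direction × chromatin
direction, one-sided for opposing signs) and an X-inactivation-escape
enrichment among the top decile (floor) of X peaks ranked by p with
|log2 fold| tie-break.

**Trait sex bias.** Per trait, GWAS hits are LD-pruned greedily by
association p (keep iff r² < 0.5 with everything kept; missing r² counts
as independent, with a warning).  Each kept variant passing a joint eQTL
gate (nominal p < 1e-3) is scored in males and in a seeded female
subsample of equal size on its best joint-p cis gene (an `all_genes` mode
scores every cis gene).  A variant is sex-biased when one sex's |effect|
is ≥1.2-fold the other's (boundary inclusive).  Female- vs male-biased
counts are tested by a two-sided exact binomial against 0.5 — the biased
variants only form the denominator, matching the question "which sex has
the greater effects" — with Bonferroni across traits; traits with fewer
than 20 scored variants are excluded.  An `RND` random-variant control
trait can be appended.

## The synthetic cohort

`synthetic.SimConfig` defaults encode the emulated study conditions: 648
females and 274 males for the expression cohort, 10 + 10 for the chromatin
arm, and 30 + 30 informative individuals per gene with Poisson(50) read
depth for the allelic arm.  Genotypes are Hardy-Weinberg at frequencies
uniform on [0.05, 0.5] with no LD (LD proxies by copy-with-mutation are
available for pruning tests); expression follows the interaction model
exactly, with mixture-distributed effects (50% of autosomal genes carry a
cis effect of SD 0.4; the rate is halved on X, emulating eQTL depletion;
10% carry an interaction effect of SD 0.3, tripled on X, emulating
interaction enrichment; 8% of genes have a 2-fold sex-specific noise SD);
20% of X genes escape inactivation, gaining a +0.5 female expression shift
and a female-open promoter peak.  A count-scale matrix passes the linear
predictor through exp into a negative binomial (dispersion 0.15).  The
last autosomal genes are reserved as trait genes — one block with positive
cis and interaction effects (female-biased regulatory effects), one block
of sex-neutral eQTLs — so the GWAS catalog always tags real structure;
effect-size distributions are package choices, not estimates of any real
cohort.  Everything derives from one seeded generator: a fixed seed
reproduces the cohort byte-for-byte.

What the generator does **not** emulate: linkage disequilibrium within cis
windows (beyond optional proxy blocks), population structure, cell-type
mixtures, mapping bias in allelic counts, GC or fragment-length artifacts
in accessibility, and non-Gaussian expression noise outside the designated
DV genes.  Passing tests therefore demonstrate statistical correctness and
calibration of the estimators under the stated generative model — not
robustness to those real-data complications.

## Validation sizes and numerical choices

The test suite validates exactness against independent enumeration oracles
(Fisher/binomial totals ≤ 40, NB totals ≤ 60, agreement to 1e-12; OLS vs
normal equations to 1e-10), type-I calibration on 2000 null units per test
at study-sized strata, parameter recovery (interaction coefficient 0.3
over 500 cohorts of n = 922; cis-PVE 0.3 over 200 runs of n = 500; ASE
interaction 0.8 over 200 genes), directional X biology over 10-seed
batches, hierarchical-FDR control over 50 replicates, end-to-end trait
detection over 15 seeds, and byte-identical re-runs of the full pipeline.
Power-run cohorts use 200-500 samples and a 60 kb cis window that pairs
each gene with its own variants; these sizes are the package's validation
design, chosen to make detection — the property under test — essentially
deterministic while keeping the suite fast.  `scripts/acceptance.py`
recomputes the same quantities from scratch at slightly smaller replicate
counts.

Numerical tie-breaks and degenerate inputs: exact two-sided p-values sum
outcomes with probability ≤ observed (with a 1e-12 relative tolerance in
the oracles); the NB test compares log joint probabilities within 1e-10;
rank tolerance for the collinearity filter is 1e-8; Wilcoxon uses the
exact null for m + n ≤ 30 without ties, else midranks with tie-corrected
variance; an all-constant F-test denominator yields an infinite statistic
with p = 0; degenerate chi-squared margins return p = 1 with a warning;
empty catalogs, zero-discovery FDR thresholds, and genes without passing
cis variants are skipped with log entries rather than errors.

## Known limitations

The GLMM's random-effect structure is this package's interpretation of a
sex-interacting ASE model (one intercept per individual-gene unit); with
multiple genes per individual a shared individual effect would induce
cross-gene correlation the model ignores.  The exact NB test conditions on
totals with a plug-in dispersion, so its calibration inherits the quality
of the trend fit; very few peaks (<10 with positive raw dispersion) fall
back to per-peak estimates.  REML assumes a single cis variance component;
trans effects and multi-component partitions are out of scope.  The trait
analysis does not compute GWAS associations or colocalization — the
catalog is an input.
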