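# Methods

## Ingestion and normalization

Expression is median log2 signal intensity per probe set (probe-level
tables are collapsed by the within-sample median; even-sized sets use the
midpoint of the two central order statistics). Median standardization is
a per-sample **additive** shift on the log2 scale to the global median of
sample medians: a location-only correction preserves within-sample rank
order and, critically, leaves coefficients of variation meaningful.
A multiplicative rescaling would distort every CV downstream.

Background filtering removes transcripts whose per-treatment mean
(pooled over sexes and replicates; configurable to per sex) is below a
quantile of the negative-control intensity distribution in **every**
treatment. The quantile defaults to 0.95 and the threshold actually used
is recorded on the returned matrix.

Sex-centering subtracts, per transcript and sex, the mean of the
treatment means (so each sex's profile averages to zero regardless of
replicate imbalance). It is idempotent and leaves within-sex
between-treatment contrasts untouched; CV computations refuse centered
matrices, since a CV around zero is meaningless.

## Variance partition

Each transcript is fit to `Y = μ + S + E + S×E + ε` by OLS with
sum-to-zero contrasts, vectorized across transcripts (one QR per model,
shared by all transcripts). Term tests drop the term's columns from the
full model (Type III); on balanced designs this reproduces the classical
cell-means decomposition exactly, which the tests verify against a
brute-force sums-of-squares oracle. FDR control is Benjamini–Hochberg,
applied per term across transcripts (the three families are reported
separately). Degenerate zero-residual fits (possible only for noiseless
synthetic fixtures) set p = 0 when the term's SS is positive and p = 1
otherwise, with a warning.

LSD contrasts test each treatment against the standard condition with the
pooled residual mean square and its df; they are deliberately uncorrected
across treatments — that is the LSD convention — while the omnibus
treatment term is FDR-controlled across transcripts. The genetic-variation
input for the Class II filter is the same machinery applied per sex to
the inbred panel with `Y = μ + line + ε`, making the pipeline
self-sufficient rather than importing a companion study's statistics.

## Variability panel

All CVs are `100 · sd / mean` with the sample (n−1) standard deviation,
computed per sex on positive, un-centered log2 values. CVME uses the
vector of treatment means; CVEW averages the within-treatment replicate
CVs (treatments with fewer than two replicates are skipped with a
warning, as are treatment cells whose mean is non-positive — possible
only under the generator's extreme Class II noise); STD_CVEW is the sd of
those within-treatment CVs. CVL and CVE are the same statistics on the
panel's lines.

## Classification cascade

Class I = treatment-significant, interaction-clean. The interaction-
excluded count is reported explicitly rather than assumed, since it is a
count the data determine. The Class II cascade runs per sex: CVME above
the 95th percentile (linear interpolation between order statistics,
configurable) of the Class I CVME distribution for that sex, AND
among-line FDR > 10⁻⁴. A transcript qualifying in either sex becomes
Class II unless it is already Class I; the sex category records which
filters fired. The high/low expression split is the exhaustive optimal
1-D bipartition: for sorted values the optimum is contiguous, so all n−1
contiguous splits are scored by total within-group SS and the global
minimum taken (verified against full 2^(n−1)−1 enumeration); SS ties
assign the boundary value to the low group, making the split
deterministic.

## Covariant modules

Correlations are Pearson, over the stacked female/male sex-centered
treatment-mean profiles (40 points for 20 treatments; configurable to
per-sex). Clustering maximizes weighted modularity on a sharpened
|r| graph with kernel `exp(−(1−|r|)²/(2σ²))`; σ is selected by grid
search (10 points, geometric on [0.05, 1]) to maximize the modularity of
the best partition found by the Leiden algorithm with a fixed seed, so
the result is deterministic given the correlation matrix. The kernel and
search are pluggable strategies: the contract is the planted-partition
behavior (exact recovery of perfect blocks, ARI ≥ 0.9 on noisy planted
blocks, no spurious structure on null matrices), not any particular
reference implementation's numerical output. Modules are ordered by
decreasing mean within-module |r|, with singletons last; diagnostics
report within/cross-module mean |r| and the fraction of negative
within-module correlations.

## Trait association and pleiotropy

Traits with a significant sex-by-treatment interaction (two-way ANOVA on
replicate-level trait values at p < 0.05) are regressed per sex; others
are sex-centered (per-sex means removed from both trait and expression)
and pooled. The slope test is two-sided at p < 0.05; exact fits report
p = 0 as the limiting value. Reverse regressions (expression on trait)
give residuals orthogonal to the trait covariate, whose correlations are
clustered exactly as above. Module overlap between two traits is the
upper hypergeometric tail over a universe defaulting to the Class I
count, Bonferroni-corrected over the pairs actually tested; pairs sharing
fewer than three transcripts are reported but never tested.

## Molecular evolution

α = 1 − (Pn/Ps)(Ds/Dn) per gene, undefined (missing) when Ps or Dn is
zero; the subscript mapping is fixed with the selected class =
nonsynonymous and neutral class = synonymous, the only mapping that
yields the conventional statistic. ω values are consumed as per-gene
tables (alignment and codon-model fitting are out of scope) and binned
into 10 equal-width bins on [0, max] by default. The G-test uses
`G = 2 Σ O ln(O/E)` with independence expectations; bins with expected
count below 1 are pooled with a neighbor first. Per-gene α is the default
reporting unit (pooled per-class counts are a caller-side aggregation).

## Synthetic data: what it emulates and what it does not

The generator reproduces the study geometry — 20 treatments × 2 sexes ×
3 replicates outbred; 40 lines × 2 sexes × 2 replicates inbred — with all
effects Normal on the log2 scale. Defaults (chosen once, as the study
conditions):

* baselines Uniform(4, 14) log2 units, so CVs are positive and
  well-defined; Class II baselines Uniform(8, 14), reflecting that
  macroenvironmental variance tracks mean expression for that class;
* 150 Class I transcripts of 2,000, each with Normal(0, 1) effects on
  3–6 random treatments — several affected treatments keep the weakest
  planted transcripts detectable at the design's power;
* within-treatment noise sd 0.25;
* 100 Class II transcripts with a treatment-redrawn macroenvironmental
  effect (sd 1.0) **plus within-treatment noise inflated to sd 5.0** —
  this is the mechanism that hides Class II from the omnibus treatment
  F test (high CVEW) while leaving CVME far above the Class I threshold,
  reproducing the detection asymmetry between the two classes;
* line effects sd 0.5, scaled ×1.5 for Class I (genetically variable)
  and ×0.1 for Class II (low CVL);
* sex-bias of the mean sd 0.5 (2.0 for Class II); the per-sex Class II
  plasticity amplitude is anti-correlated with the sex bias
  (`exp(∓0.7·bias/2)`, clipped to [0.5, 2] to keep intensities positive),
  planting the inverse mean/plasticity dimorphism relationship;
* traits are sums of **unit-variance** treatment profiles of 2 linked
  Class I transcripts (drawn from the upper half of planted effect
  magnitudes) plus Normal(0, 0.2²) replicate noise. With k linked
  transcripts each contributes r ≈ 1/√k across only 20 treatment points,
  so k = 2 is the largest k at which individual associations remain
  reliably detectable; sexed traits use per-sex link multipliers
  (1.5/0.5), planting a real trait-level S×E interaction;
* MK tables are Poisson with E[Ps] = E[Ds] = E[Dn] = depth and
  E[Pn] = depth·(1−α), so expected counts satisfy the α identity exactly.

Everything is seeded and byte-reproducible. The generator does **not**
emulate probe-level data, array spatial or batch artifacts, correlated
noise across transcripts, non-Normal heavy tails, or linkage between the
planted classes and real functional annotation — so passing tests
demonstrate the statistical machinery recovers structure of the assumed
form, not that the assumed form captures every property of real arrays.

## Problem sizes and numerics

Tests and the acceptance script run the full design at 2,000 transcripts
over 5 seeds (seconds per run, thanks to the vectorized ANOVA), planted
clustering at 100 transcripts in 5 blocks, oracle enumerations at
n ≤ 12, and MK recovery at depth 10⁵ × 200 genes. Quantile convention,
bipartition tie-breaks, degenerate-fit conventions and the CVEW guards
are described above; correlation matrices are symmetrized and clipped to
[−1, 1] before clustering to absorb floating-point asymmetry.

## Known limitations

Mixed models, REML variance components, covariate adjustment and
per-array quality weights are out of scope; the ANOVA treats all effects
as fixed. Module counts on real data depend on the sharpening kernel and
search strategy and are not a stable surface. The Class II filter
consumes a genetic-variation FDR per sex; with very few lines or
replicates its null behavior degrades with the one-way F test's power.
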