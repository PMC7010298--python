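# Methods

## Scope and data model

`ccqtlmed` analyses molecular traits measured once per strain in a panel of
fully inbred 8-founder mosaic genomes. Genetic predictors are founder
haplotype dosages: per strain and locus an 8-vector in [0, 2] summing to 2
(one-hot × 2 for inbred strains, fractional after locus merging). Traits are
a traits × strains matrix anchored to genomic coordinates — a gene's TSS or
a chromatin window's midpoint — with a class label (`gene` / `chromatin`)
that selects filtering thresholds. A 5-level batch factor enters every model
as a fixed categorical covariate.

## Trait preparation

* **TMM normalization.** Scaling factors follow the standard trimmed mean of
  M-values recipe: reference = sample whose upper quartile of library-scaled
  values is closest to the mean upper quartile; per sample, log2 ratios M and
  abundances A are computed over traits nonzero in both sample and reference;
  the top/bottom 30% of M and 5% of A are discarded; the factor is
  2^(weighted mean of M) with inverse asymptotic (delta-method) variance
  weights; factors are renormalized to geometric mean 1. Samples are then
  divided by factor × relative library size, so pure library-depth changes
  cancel. TMM is implemented here directly (no Python implementation is
  otherwise available in the stack); the test suite checks it against a
  literal single-pass evaluation of the formula on toy counts.
* **Low-signal filter.** A trait is removed iff the fraction of samples at or
  below the class threshold (1 for genes, 5 for chromatin windows, applied
  after normalization) is ≥ 0.5. The point is to avoid QTL driven by a few
  non-zero observations.
* **Outlier filter.** Per trait, the exact optimal 1-D two-means partition is
  found by enumerating all splits in sorted order (this attains the K = 2
  optimum in one dimension and removes any dependence on random
  initialization). The trait is removed iff the smaller cluster has exactly
  one member. Constant traits are kept: both clusters are degenerate and no
  single observation is isolated.
* **RINT.** Values map to Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom offset
  c = 3/8 and average ranks for ties; an all-equal vector maps to zeros.
  Filtering happens on the (normalized) raw scale, the transform last, so
  the stated thresholds retain their units.

## Locus merging and variants

Adjacent loci with effectively identical founder mosaics across all strains
are redundant tests. A greedy left-to-right pass merges the next locus into
the current group iff, for every strain, the L2 distance between its
dosage 8-vector and the group's running average is ≤ fraction × max_distance
(defaults 0.1 × 2.0 = 0.2). Merged dosages are element-wise means, the
position is the member mean, and provenance is recorded. The `max_distance`
constant of 2 is exposed as a parameter: dosage vectors summing to 2 admit
distances up to 2√2, and a user may prefer that bound. With fraction 0,
merging is disabled outright (otherwise exactly identical neighbors would
still merge at distance 0).

Variant association imputes per-strain allele dosages as the dot product of
the founder-allele vector with the haplotype dosages at the nearest mapped
locus. Variants with any missing founder call, or with imputed minor allele
frequency ≤ 0.1, are excluded; the association model is the haplotype model
with a single-column QTL term (numerator df = 1).

## Scans and effect estimates

The per-locus model `y = mu + batch + beta' x + eps` is compared to its null
by an F-test. Rank deficiency (the eight dosage columns are collinear with
the intercept, and merged loci can be collinear with conditioned loci) is
handled by pivot-free orthonormal bases with an SVD cutoff scaled to the
*original* block magnitude — so a locus numerically inside the conditioned
space gets numerator df 0 and logP 0 rather than a spurious test. No column
is dropped by name; founder symmetry is preserved.

`ScanEngine` residualizes every locus block against the null-design basis
once and stores per-locus orthonormal bases. A scan of T trait columns is
then one matrix product plus segment sums, and permutation scans reduce the
per-scope maxima over F statistics within (df numerator, df denominator)
groups before evaluating the F tail, which keeps 200–1,000 permutations ×
thousands of loci in the tens of milliseconds. p-values are floored at
1e-320 before log10 so noiseless fits stay finite.

Effect sizes are reported two ways: the fixed-effect R² = 1 − RSS_QTL/RSS_0,
and a more conservative shrunken version. Founder effects at detected QTL
are re-estimated under `beta ~ N(0, I tau^2)` with batch fixed; tau² is
estimated by REML (profiled over the variance ratio with a grid-plus-Brent
search; the boundary tau² = 0 returns zero BLUPs, flagged) and the BLUPs are
equivalent to ridge regression with penalty sigma²/tau² on the residualized
dosage design — an identity the tests verify numerically. Reported vectors
are centered and scaled to unit SD for cross-tissue comparison; the shrunken
effect size is 1 − RSS(shrunken predictions)/RSS_0, an intermediate between
the fixed-effect estimate and the harsher variance-component ratio. On
pure-noise traits the REML estimate sits exactly at the boundary in roughly
half of samples and at a small positive value otherwise; tests assert
smallness, not exact zeros.

## Permutation error control and detection

Permutations shuffle the trait vector against the genotype *and* batch rows
(one shared, seeded list of orderings reused across traits, so cross-trait
results are comparable); the batch–trait association is therefore also
broken under the null. Per permutation the maximum logP within the scope is
recorded, and a GEV is fitted by maximum likelihood to the n_perm maxima;
`permP = 1 − F_GEV(logP)`. If the maxima are degenerate or the MLE fails,
the empirical survival function with +1 smoothing is used and flagged. At
least 100 permutations are required for a GEV fit; defaults use 200 in tests
and simulations (1,000 for production-scale runs), a size at which the
tests show permP is KS-uniform under the null and detection rates at 0.05
stay inside the 99% binomial envelope.

* **Analysis L** evaluates the peak within ±10 Mb (inclusive) of the anchor
  against the chromosome-wide GEV; detection at permP_C < 0.05, permP_G
  reported as annotation. Note the local window is a subset of the
  chromosome scope, so under the null the procedure is conservative unless
  the window covers the chromosome; the calibration tests use 20 Mb
  chromosomes with mid-chromosome anchors so that rate checks are exact.
* **Analysis C** takes the single chromosome-wide peak per trait (a stronger
  distal peak therefore masks a local one), converts to permP_C, and applies
  Benjamini–Hochberg across traits (q ≤ 0.1 by default; 0.2 as a lenient
  tier for cross-tissue pairing).
* **Analysis G** does the same genome-wide, then iterates: every detection
  triggers a new scan *and a new permutation null* with all previously
  detected loci for that trait included in both null and alternative models.
  BH is re-applied across traits within each stage; stages are capped at 3.
  Local/distal status plays no role in detection. With a single trait BH is
  vacuous and the stage-2 false-detection rate is simply the FDR level —
  panels, not single traits, are the intended unit.

## Cross-tissue comparison

QTL for the same trait in two tissues are paired when they co-localize:
local pairs need both peaks within the ±10 Mb anchor window (≤ 20 Mb apart),
distal pairs need peaks within 10 Mb (inclusive) of each other. When several
calls co-localize, the smallest peak distance wins, ties broken by higher
mean logP, one pair per trait/tissue-pair/kind. The Pearson correlation of
the two scaled BLUP 8-vectors is tested exactly: t = r√6/√(1−r²) against
t with 6 df, one-sided in both directions. The two one-sided p-value
families are BH-adjusted *separately* (this matches reporting two q-values
per pair); q ≤ 0.1 classifies correlated/anticorrelated. The paired table
also carries both fixed effect sizes and their panel-level correlation as a
summary.

## Mediation

For a detected eQTL (X → Y established), the scan conditions the eQTL
association on each candidate mediator in turn — alternative
`y = mu + QTL + m + batch (+ conditioned)` vs null `y = mu + m + batch
(+ conditioned)` — across all candidates genome-wide; most candidates are
irrelevant and define the background. Significance comes from permuting the
mediator matrix rows jointly (one ordering per permutation; per-mediator
independent shuffles are exposed as an option through the scanner API),
recording the *minimum* mediated logP, fitting a GEV to the minima, and
reporting the lower tail permP^m = F_GEV(logP). A mediator that absorbs
numerically all outcome variance (a perfect mediator) makes the comparison
0/0; the scanner reports mediated logP = 0, since nothing remains for the
QTL to explain.

A mediator is *called* only if all of: (i) permP^m below the threshold
(0.05 at the applicable scope); (ii) it has a detected QTL whose peak lies
within 10 Mb of X; (iii) that QTL is stronger than the outcome's eQTL in
both logP and fixed effect size. These criteria are consistent with the
causal chain X → M → Y but cannot prove directionality: noise asymmetry
between M and Y can flip the apparent ordering, and an unmeasured true
mediator can elect a correlated proxy. Partial vs full mediation is not
distinguished.

## Synthetic data generator

The generator defines the study conditions: 47 strains (one animal each),
five batches, 8-founder mosaics with block lengths drawn
Exponential(16.3 Mb) and block founders uniform over eight, loci evenly
spaced on 20 × 100 Mb chromosomes (~2,000 loci). The 16.3 Mb figure is the
canonical CC haplotype block size; realized (chromosome-censored) block
means run ~14 Mb on a 100 Mb chromosome, which the tests bound within 20% of
the process mean. Planted QTL are rescaled against the realized sample so
the QTL term explains *exactly* the requested variance fraction: planted
terms are Gram-Schmidt orthogonalized in order and the batch-plus-noise
remainder is orthogonalized against all of them, making the decomposition
additive and seeds fully reproducible (all randomness flows from one integer
seed through named seed-sequence streams; truth is recorded in a JSON-able
table). Mediation trios set mediator = QTL effect + noise and outcome =
chain_strength × standardized mediator + orthogonalized noise, so
QTL → mediator is stronger than QTL → outcome by construction and
chain_strength 1 yields a perfect mediator. Batch effects default to
SD 0.5 per level against unit residual noise — visible but not dominant,
as expected of sequencing batches.

What the generator does *not* emulate: realistic recombination maps or CC
funnel ancestry (no linkage between chromosomes, no founder imbalance beyond
sampling), heterozygosity (DO-like genomes), sex effects, count-level
measurement noise, or correlated mediator panels. Passing tests therefore
demonstrate correctness of the statistical machinery under its own model
assumptions, not robustness to every pathology of real RNA-seq/ATAC-seq
data.

## Problem sizes and numerical choices

Simulation-based tests use genomes from 100 to 2,000 loci, 120–300
permutations, and 20–500 replicate traits, chosen so the full suite runs in
a few minutes while leaving binomial margins wide enough for the asserted
rates. Rank cutoffs use a relative SVD tolerance of 1e-10 anchored to the
original block scale; GEV fits fall back to empirical tails when degenerate;
BH goes through `statsmodels.stats.multitest`; F/t/GEV distributions through
scipy. The power simulation (one QTL at 55% variance, 47 strains, 200-perm
GEV nulls, detection within 5 Mb at permP_G < 0.05) estimates ~80% power,
matching the expectation for panels of this size.

## Known limitations

No kinship/polygenic random-background term (the scan assumes exchangeable
strains, which permutation thresholds also require); no dominance; detection
protocols evaluate only scan peaks, so two QTL closer than the locus spacing
merge; cross-stage FDR bookkeeping in Analysis G is per-stage, which does
not control a single global FDR across stages; mediation calling inherits
the directionality caveats above.
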