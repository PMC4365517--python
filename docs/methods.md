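# Methods

## Scope and model

`relkit` estimates pairwise additive genetic relationships and individual
inbreeding coefficients for a genotyped cohort from three kinds of
information — pedigree records, chip-like genotype panels and
sequence-like genotype panels — and quantifies how the estimates change
when rare alleles (MAF below 5%) are included, excluded, or used alone.
All genotypes are diploid, biallelic, coded 0/1/2 as copies of the coded
allele (the VCF ALT allele for VCF input; the estimators are proven
orientation-invariant, so this is a convention, not a result-changer).

### Pedigree relationships

The numerator relationship matrix **A** uses the tabular recursion over a
parents-before-offspring ordering; unknown parents are treated as
unrelated, non-inbred founders, which defines the identity-by-descent
base population as the recorded founders. Inbreeding is computed
independently as the coancestry of each individual's parents via a
memoised kinship recursion; an invariant test enforces exact equality
with `diag(A) − 1`. Pedigree depth is counted as complete generations:
the largest g such that every one of the 2^k ancestors at each generation
k ≤ g is recorded — one missing grandparent caps the depth at 1
regardless of deeper records on the other side.

### Genomic relationships

Two estimators, both plain per-locus averages and therefore computed in
streaming variant chunks (default 20,000) so sequence-scale panels never
hold a standardised genotype matrix in memory:

* the frequency-weighted estimator (off-diagonal
  (x_j−2p)(x_k−2p)/(2p(1−p)) averaged over loci, with the distinct
  diagonal form 1 + (x²−(1+2p)x+2p²)/(2p(1−p))), which up-weights rare
  alleles and approximates IBD relative to the population whose
  frequencies are used; frequencies default to the current-sample
  estimate, with user-supplied (e.g. true founder) frequencies accepted
  for validation work;
* the similarity (allele-sharing) estimator (M−1)(M−1)′/(N/2), bounded in
  [−2, 2], equivalent to fixing all frequencies at 0.5 and hence to a
  base population much older than the pedigree founders — its inbreeding
  values run far above the pedigree scale by construction.

Variants monomorphic in the analysed sample are removed before either
estimator (mandatory for the weighted one — the weight diverges; by
default for similarity, "segregating variants", overridable). MAF
scenarios are half-open intervals [low, high) with the folded spectrum's
top (maf = 0.5) included, which makes the 1+ set exactly the disjoint
union of 5+ and 1_5 — an invariant the tests assert as set equality.
Within a 118-diploid sample, the 1% rule is equivalent to requiring at
least 3 copies of the minor allele.

### Hardy–Weinberg screen

Departure from Hardy–Weinberg proportions is tested per variant with the
exact conditional test: given n individuals and the minor-allele count,
the heterozygote count has probability proportional to
n!/(n_aa! n_het! n_AA!)·2^n_het, and the p-value sums all configurations
no more probable than the observed one (ties included). This is the
appropriate construction at low MAF, where chi-square approximations
break; the mid-p variant is deliberately not the default. The
distribution is cached per (n, minor count), so screening a
sequence-scale panel over a fixed cohort costs little more than genotype
counting. The test is conservative-to-nominal by discreteness; the null
calibration test bounds the rejection rate at alpha = 0.05 by 0.06.

### Comparison machinery

Pairs are grouped by the pedigree value: first degree [0.5, 1), second
degree [0.25, 0.5), less related [0, 0.25); the diagonal feeds the
inbreeding analysis. Descriptive statistics use the n−1 variance. Pearson
correlations are tested against 0 with the usual two-sided t-test; a test
directly against rho = 1 degenerates under the Fisher transform, so
"not different from 1" is operationalised as the 95% Fisher-z confidence
interval reaching 1 − ε, with ε = 1e-3 chosen so that r = 0.999 with
several thousand pairs (CI upper bound ≈ 0.9990) is not flagged while
r ≤ 0.998 at the same n is; the method note is recorded in every result.
Scenario differences use the paired Wilcoxon signed-rank test on the
pooled off-diagonal estimates (exact null for ≤ 25 non-zero differences,
normal approximation with continuity correction above; zero differences
dropped). Two correlations from different depth groups are compared with
the independent-samples Fisher-z test even though the groups are nested;
the result carries an explicit independence note, as no dependent-samples
procedure is defined for this design.

## Synthetic cohort

The simulator provides ground truth, not a fit to any real dataset. Its
default configuration emulates a sequenced key-ancestor bull cohort:

* 40 founders, 5 generations of 60 offspring, and a genotyped cohort of
  118 = 78 final-generation individuals + 40 of their sires/grandsires,
  giving genotyped parent-offspring and grandsire pairs alongside
  half-sib families (up to 4 offspring per sire; 5% full-sib repeats);
* founder allele frequencies from either a uniform folded spectrum
  (chip-like: ascertainment makes all MAF classes equally common) or an
  L-shaped 1/p spectrum (sequence-like), truncated at MAF 1% to match
  the global exclusion rule;
* gene dropping at unlinked loci: founder alleles are Bernoulli draws,
  each child inherits one uniformly chosen allele per parent per variant.
  With tracking on, founder alleles carry unique labels and the exact
  IBD matrix is returned on the additive scale (expectation = **A**);
* pedigree-record censoring: a fraction of each ancestor generation loses
  its parent links in the *recorded* pedigree (defaults 0.05/0.02/0.04/
  0.70/0 from oldest to youngest; genotyped cohort members always keep
  their own parent records). Concentrating the loss one generation back —
  the undocumented dam lines — reproduces the nested depth structure of
  real cohorts (all 118 with parents recorded, roughly half with two and
  a third with four complete generations) and is what drives the
  depth-stratified inbreeding results;
* the frequency-sensitivity simulation redraws each variant's frequency
  from a normal centred on the observed value with binomial sd
  sqrt(p(1−p)/(2n)), truncated by clipping to at least one allele copy,
  then recomputes the weighted GRM and correlates all diagonal-plus-upper
  entries with the baseline. Per-variant resampling (rather than one
  global normal over the frequency distribution) is the reading that
  models estimation error from finite sample size; a different
  interpretation would need only a different replicate-frequency matrix.

Every generator takes a mandatory integer seed and is bit-reproducible.

### What the simulator does not model

Loci are unlinked — none of the implemented estimators uses linkage, but
this means realised relationship variation from Mendelian sampling is
much smaller than in a real genome at equal marker counts, and LD-driven
phenomena are absent. There is no mutation, selection, genotyping error,
imputation error or coverage model. Passing tests therefore demonstrate
the correctness and internal consistency of the estimators and the
qualitative data-source contrasts, not quantitative agreement with any
particular real cohort.

## Problem sizes and numerical choices

The validation analyses use sizes chosen to make Monte-Carlo error small
relative to the effects under test: parameter recovery gene-drops a
20-member pedigree at 100,000 variants for 200 replicates; the
frequency-sensitivity emulation uses 118 individuals × 100,000 L-shaped
variants × 20 replicates; the cross-scenario study runs the default
cohort at 50,000 sequence-like variants thinned to a 6,000-variant
uniform chip. Unbiasedness is asserted family-wise over the 210 distinct
matrix entries — no deviation beyond 4.5 Monte-Carlo SEs and at most 4
entries beyond 3 SEs, the 99.9% envelope of the expected chance
exceedances — because a literal per-entry 3-SE rule rejects a true null
in a sizeable fraction of runs, while any real bias at this marker
density would show up as deviations of tens of SEs.

Accumulations are double precision; genomic matrices are symmetrised by
averaging with their transpose after chunked accumulation; relationship
containers check symmetry on construction (1e-8 tolerance). Tabular-A and
oracle comparisons are exact to 1e-12. Tie handling in the exact HWE
p-value uses a 1e-9 relative tolerance when grouping equal-probability
configurations. Chip thinning stratifies over 1%-wide MAF bins with
equal quotas, topping up from the leftover pool when a bin runs short.

## Known limitations

* The exact test behind "significantly different from 1" in published
  tables of this kind is typically unstated; the Fisher-z boundary
  approach here is one defensible choice and is labelled in every output.
* Depth-group correlation comparisons assume independence between nested
  groups.
* Half-open MAF intervals are an inference from the exact variant-count
  partition such studies report; a strictly-greater-than reading of
  "MAF higher than 5%" would shift boundary variants between scenarios.
* Multi-allelic VCF records are skipped, not split; dosage genotypes are
  out of scope.
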