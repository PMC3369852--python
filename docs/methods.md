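# Methods

This note documents the statistical procedures the package implements, the
choices made where the published description leaves the design open, and
what the synthetic-data tests do and do not establish.

## Response classification

`das28_crp4` implements the 4-variable DAS28-CRP:
`0.56·√TJC28 + 0.28·√SJC28 + 0.36·ln(CRP+1) + 0.014·PGA + 0.96`, with
TJC28/SJC28 the 28-joint tender/swollen counts (0–28), PGA the patient
global VAS in mm (0–100) and CRP in mg/L (≥ 0). Clinical tables may also
carry a precomputed `das28` column, which is accepted verbatim; which exact
calculator produced a historic registry score is generally not
recoverable, and only the resulting labels matter downstream.

`eular_classify(baseline, week26)` applies the standard EULAR matrix with
improvement Δ = baseline − week26: **good** iff Δ > 1.2 and week26 ≤ 3.2;
**none** iff Δ ≤ 0.6, or Δ ≤ 1.2 with week26 > 5.1; **moderate**
otherwise. Boundaries are exactly as written (a tie at Δ = 1.2 falls to
the lower category). The three regions partition the non-negative
quadrant, and lowering the attained score never demotes the category —
both are property-tested.

## Dichotomy enumeration

For an amplicon with sorted alleles a₁ < … < a_k, two grouping kinds are
enumerated: *threshold* groups {a : a ≤ c} for each observed cut c < a_k,
and *singleton* groups {a} for each allele. Each grouping crossed with the
dominant (≥ 1 allele in group) or recessive (both alleles) model induces a
binary patient feature.

Deduplication rules, chosen to reproduce the published 8-test catalogue of
the 7-allele microsatellite exactly and exposed as a `dedupe` switch
(`within_kind` default, `none`, `full`):

- Groupings inducing the same allele bipartition are emitted once; a
  threshold coinciding with a singleton (the cut after the smallest
  allele; the cut just below the largest) is emitted as the singleton.
  For a bi-allelic locus the two singletons coincide and the **longer**
  allele is kept as focal: for an INDEL the long allele is the insertion,
  and tests read "carries the insertion", giving odds ratios in the
  orientation practitioners expect.
- At the test level, threshold tests inducing identical patient
  partitions are merged (smallest cut kept), but identical partitions
  arising across kinds (a threshold test and a singleton test) are kept
  as two tests, each counting toward `N_test`. This asymmetric rule is an
  inference — it is the unique rule consistent with the published
  catalogue, which keeps a duplicated threshold/singleton pair but no
  within-threshold duplicates — and is therefore configurable.

The 10% admissibility rule removes tests whose smaller genotype group
holds fewer than `0.10 × n` patients, compared real-valued (17 of 156
passes, since 17 ≥ 15.6). `n` is the size of the *analysis set* — the
patients of the active contrast with a non-missing genotype at this
amplicon — not the whole cohort; the published per-test counts use the
156-patient good/none set. Missing genotypes are dropped pairwise, per
amplicon and contrast.

## Exact tests, odds ratios and intervals

The two-sided Fisher p-value follows the point-probability convention
(the default of R's `fisher.test` and `scipy.stats.fisher_exact`):
conditioning on both margins, sum the hypergeometric probabilities of all
tables no more likely than the observed one, with a 1e-7 relative tie
tolerance. The core routine `fisher_pvalues_by_count(K, n1, n2)` returns
the p-value for *every* feasible count at fixed margins at once, because
two loops depend on it heavily:

- permutation rounds never change a column's margins, only the count of
  feature-positives among relabelled responders, so each column costs one
  lookup per round;
- power simulations revisit the same (k₁, k₂) pairs, cached by pair.

The routine is validated against `scipy.stats.fisher_exact` and against an
exhaustive fixed-margin oracle in exact rational arithmetic, at 1e-12
relative tolerance.

The odds ratio is the cross-product `ad/bc` (matching the published
estimates; the conditional MLE does not), with `+∞` when `bc = 0`. The
95% CI inverts the exact conditional (noncentral hypergeometric) test via
`scipy.stats.contingency.odds_ratio(kind="conditional")`; this choice was
validated by reproducing both published intervals (1.99–10.09 and
2.29–8.99) to the printed precision.

## Multiplicity and permutation calibration

With `N_marker` amplicons having at least one admissible test and
`N_test` tests at the amplicon under study, the per-test threshold is
`0.05/(N_marker × N_test)`. `N_marker` is configuration (202 for the
packaged study setting): it cannot be recomputed without the full panel's
raw data. The pipeline can also multiply in a contrast-family factor
(e.g. 3 when one test is evaluated under three contrasts), exposed as
`contrast_multiplier` rather than hard-wired, since the interaction of
the two multipliers in a single family threshold is a design choice.

Nested threshold groups and duplicated partitions make the `N_test`
dichotomies strongly dependent, so plain Bonferroni over-corrects. The
calibration permutes the response labels uniformly within the analysis
set (group sizes fixed), records the minimum two-sided Fisher p across
the test columns per round, and estimates
`N_eff = [#(min p ≤ p_ref)/rounds]/p_ref` at a reference value `p_ref`,
normally the observed minimum p. The estimator reports the binomial
standard error of the tail count and warns (not errors) when fewer than
20 tail events were seen. Rounds default to 600,000; the vectorized
implementation (batched label draws, count-indexed p lookups) does about
1M rounds/s for 8 columns × 156 patients on one CPU and was cross-checked
against a naive per-round loop.

Two numerical caveats discovered in development, both documented here
because they materially move the estimate:

- **Reference precision.** The observed minimum p is an *attained* value
  of a discrete statistic, so `min p ≤ p_ref` at full floating-point
  precision includes the sizeable point mass of permutations that tie the
  observed table exactly; rounding `p_ref` to its reported 4-significant-
  figure precision (5.067e-5, slightly below the attained 5.06706e-5)
  excludes those ties. The two conventions converge to effective counts
  of about 3.40 and 3.03 respectively for the packaged 8-test set. The
  published tail count (83 of 600,000) is consistent with the
  tie-excluding convention, which the examples and acceptance script
  therefore use; the library takes `p_ref` as an explicit argument.
- **Tail noise.** A 600,000-round run yields a tail of only ~90 events,
  i.e. a ~11% standard error on the effective count; the published 2.73
  and this package's converged 3.03 agree within that error. Runs meant
  to be compared against a fixed target should use millions of rounds.

## Power

`power_fisher` draws feature-positive counts independently,
k₁ ~ Bin(n₁, p₁) and k₂ ~ Bin(n₂, p₂) with the group sizes fixed, and
reports the fraction of simulated tables with two-sided Fisher
p ≤ α, with its Monte-Carlo standard error. Using the observed per-group
proportions as (p₁, p₂) treats the observed effect as the truth — a
post-hoc detectability number, not a design calculation. The sampling
model is an inference (the published description names no model); it
reproduces two of the three published figures within Monte-Carlo error
(74.5% and 55%), but its exact power for the third scenario is 62.5%
where 59% was published, a gap no resampling variant we examined
(multinomial whole-table, genotype-margin-fixed, Yates chi-square)
closes without breaking the other two figures; the conditional
fixed-margins model gives 59% there but 80% and 58% elsewhere. The
binomial model is retained and the discrepancy reported rather than
papered over.

## Hardy–Weinberg screen

For every binary subdivision of the allele set (all 2^(k−1) − 1
bipartitions for ≤ 8 alleles; thresholds + singletons beyond), genotypes
are collapsed to a bi-allelic system and the observed homozygote/
heterozygote/homozygote counts are compared with Hardy–Weinberg
expectation from the collapsed allele frequency by a 1-df chi-square
without continuity correction; the screen reports the minimum p and its
subdivision (stored as the allele tuple of the group, since an arbitrary
bipartition is neither a threshold nor a singleton). Taking a minimum
over subdivisions deflates p relative to uniform by construction — the
screen is a deliberately aggressive QC flag, not a calibrated test — and
the tests only assert it is not anti-conservative beyond that deflation.

## Synthetic cohorts

The generator draws, per amplicon, two alleles independently from the
configured spectrum (Hardy–Weinberg), masks calls at the per-amplicon
missing rate (capped at 0.28, the worst observed rate), and assigns
labels from the cohort probabilities (defaults 68/237, 81/237, 88/237).
A planted effect rescales the good-vs-none odds of feature-positive
patients by the target odds ratio while preserving the moderate share;
parameter-recovery tests confirm the cross-product OR is recovered within
10% over 500 replicates at the study size. DAS28 pairs are sampled with
baseline uniform on [3.1, 7.4] (the observed good-responder baseline
range) and week-26 uniform inside the label's region, resampling on the
rare mismatch — any distribution is admissible as long as
`eular_classify` round-trips the drawn label, which is asserted. Defaults
mirror the study conditions (237 patients, the 160/56/21 drug mix).

What the generator does *not* emulate: genotyping error and allele
dropout, linkage between amplicons (independent by default), covariate
structure (age, sex, concomitant therapy) and any drug-specific response
mechanism. Passing tests on synthetic cohorts therefore establish the
statistical machinery — enumeration, exact tests, calibration, error
control — not the clinical generalizability of any finding.

## Problem sizes in routine runs

The default test suite runs in well under a minute: permutation tests use
30,000–120,000 rounds, power checks 10,000 simulations, and
replicate-based properties 60–500 cohorts — sizes chosen so the
Monte-Carlo error, which every assertion carries explicitly, stays small
relative to the asserted tolerance. The acceptance script uses 10 million
permutation rounds so the effective-test-count estimate sits at its
converged value (≈ 2.5% standard error).
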