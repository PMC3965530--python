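# Methods

## The calling problem

Deep targeted-panel sequencing of a tumor and the patient's matched
normal (lymphocyte) DNA yields, after upstream trimming and alignment,
a per-locus pileup: read depth and per-base alternate counts. The task
is to decide which loci carry *somatic* variants — present in the
tumor, absent from the germline — against three confounders: ordinary
sequencing error, inherited (germline) variants present in both
samples, and locus-specific systematic artifacts that recur in both
samples of a pair. At panel depths (hundreds to thousands of reads) a
simple allele-fraction threshold is sensitive but unspecific; the
cascade below restores specificity.

## The filter cascade

For a matched pair over one panel, with configuration defaults in
parentheses:

1. **Coverage gate.** A locus is retained only if, in *both* samples,
   depth > `median_fraction` (2%) × that sample's median depth **and**
   depth > `min_reads` (100). Both comparisons strict. The median of an
   even-length depth vector is the mean of the middle two order
   statistics.
2. **Candidate nomination.** The candidate alternate at a locus is the
   most frequent non-reference base in the tumor (ties broken
   alphabetically, A<C<G<T). Loci with tumor VAF ≥ `nomination_vaf_min`
   (2%) are nominated. Nomination is deliberately *below* the call
   threshold: every near-threshold locus is returned with explicit
   filter flags rather than silently dropped, so per-filter attrition
   is auditable and the flag vocabulary (`low_coverage`, `low_vaf`,
   `blacklist`, `germline`, `systematic`) is fully reachable. A
   candidate below `tumor_vaf_min` (6%, inclusive ≥ — a variant exactly
   at the threshold is callable) is flagged `low_vaf`; one failing the
   coverage gate in either sample is flagged `low_coverage`.
3. **Blacklist.** Loci known a priori to generate recurrent systematic
   positives are flagged `blacklist`.
4. **Germline subtraction.** A candidate whose matched normal shows
   strictly more than `normal_vaf_max` (1%) variant reads is flagged
   `germline`. Zero normal depth flags conservatively: germline status
   cannot be excluded without normal coverage.
5. **Systematic-error percentile filter.** Define the variant score

   s(d, a; p) = −10 · log10 P[X ≥ a],  X ~ Binomial(d, p),

   the Phred-scaled upper-tail probability of the observed alternate
   count `a` at depth `d` under a background error rate `p`
   (`background_error`, 0.5%). s is 0 at a=0 and monotone
   non-decreasing in a. For every retained locus that is neither a
   candidate nor blacklisted (the *background*), compute the signed
   score difference s_tumor − s_normal at the locus's top tumor
   alternate base. A candidate is flagged `systematic` unless its own
   score difference strictly exceeds the `diff_percentile` (99.5th)
   percentile of that background distribution; percentiles use linear
   interpolation between closest order statistics (inclusive), and
   ties at the cutoff are flagged (conservative). Fewer than 200
   background loci make the extreme percentile unstable and are an
   error.

A call is **accepted** iff its flag set is empty. The exact score
definition is this package's own (the binomial tail against a
configurable error floor); it was chosen for being depth-aware,
monotone in the alternate count, and reproducible without any
assay-specific calibration. Signed (tumor − normal), not absolute,
differences are used throughout.

Numerics: the binomial tail is computed through the survival function
where it does not underflow and otherwise through a `logpmf`-anchored
series over the decaying term ratios, so scores at deep, high-count
loci (e.g. a germline heterozygote at depth 1000) remain finite and
differences well-defined.

## Effect classification

Accepted substitutions are classified from their codon change under
the standard genetic code: alternate codon a stop and reference not →
STOP_GAINED; equal amino acids → SILENT; otherwise NON_SYNONYMOUS.
SPLICE_SITE is part of the closed vocabulary but derives from locus
annotation, never codon content, and is only carried through.
Stop-loss (reference codon a stop) is classified NON_SYNONYMOUS with a
warning; read-through effects are outside the four-class vocabulary.
The compact CDS-change dialect (`aTc/aCc`: one uppercase letter per
codon marking the substituted position, same index in both) is parsed
strictly — wrong length, uppercase count ≠ 1, disagreeing positions or
identical codons are rejected. Protein changes render as
`p.<ref><number><alt>` with `*` for stop.

## Landscape statistics

Per gene, two counts are kept distinct: `mutation_count` (table rows;
a double-hit patient contributes 2) and `patients_mutated` (distinct
samples; contributes 1). The per-gene rate is
100 × patients_mutated / n_patients, rounded to one decimal half away
from zero. The gene×patient matrix is ranked by rate descending with
alphabetical tie-break (the oncoprint ordering) and exported with a
per-patient totals row. Cohort denominators always include unmutated
patients; patients with unknown covariates are excluded from that
comparison only.

Group comparisons report per-group mean burden, fold = larger/smaller
mean (infinite when the smaller is 0 and the larger is not; 1.0 when
both are 0), and a two-sided Fisher exact p on the 2×2 table
(any mutation vs none) × group. The two-sided p sums hypergeometric
probabilities of all margin-fixed tables at most as probable as the
observed one (probability-mass method, not tail doubling), with a
1e-9 relative tie guard against float round-off. No multiple-testing
correction is applied by default (single planned tests); a Bonferroni
adjustment can be applied downstream if many genes are scanned.

One orientation note: the HPV-stratified TP53 rates this package's
cohort generator plants (0.43 per sample HPV-negative, 0.11
HPV-positive) put the *higher* rate in the HPV-negative group, a
~3.9-fold difference; prose describing that contrast as a "lower" rate
in HPV-negatives contradicts the rates themselves, so the comparison
functions always report which group is higher explicitly.

## The synthetic pair generator

No distributional description of real panel read data accompanies the
calling rules, so the generator is a declared stand-in that reproduces
the *structure* the cascade assumes, not a reconstruction of any
particular run:

* **Coverage**: negative binomial with mean `median_coverage` (1000)
  and size `coverage_dispersion` (10), independently per locus and per
  sample — targeted amplicon coverage is strongly overdispersed
  relative to Poisson (dispersion 10 at mean 1000 gives SD ≈ 320,
  a realistic amplicon-to-amplicon spread).
* **Noise floor**: each locus has one designated alternate base
  (multi-allelic planting is out of scope); its count is
  Binomial(depth, `base_error_rate` = 0.2%), a typical post-q20 error
  rate.
* **Germline heterozygotes** (20/pair): Binomial(depth, 0.5) in both
  samples. Homozygous planting (VAF 1.0) exists behind the same code
  path but defaults off; the germline filter treats both identically.
* **Somatic variants** (5/pair): tumor only, VAF ~ Uniform[0.08, 0.50]
  — comfortably above the 6% call threshold and spanning validated
  orthogonal-assay read frequencies (~14–46%).
* **Artifact loci** (10/pair): Binomial(depth, `artifact_error_rate` =
  2%) in *both* samples, emulating shared systematic positives.
* Optionally a fraction of loci is forced to depths of 5–60 reads,
  below both coverage-gate floors.

Planted classes are disjoint per locus and every event is recorded in
a truth table, enabling sensitivity/PPV/specificity scoring. Identical
parameters and seed give bitwise-identical outputs.

What the generator does **not** model — and hence what a passing
benchmark does not certify on real data: read-level effects (mapping
artifacts, strand bias, position-in-read error structure), FFPE
deamination damage, indels, copy-number-driven allele-fraction
distortion, tumor purity and subclonality below the planted VAF range,
and error rates that vary per locus rather than sitting at a fixed
floor. The 100% benchmark PPV reflects a clean separation between the
planted somatic VAF range and the artifact/noise rates; real pairs sit
closer to the boundary.

## The cohort generator

Per-patient total burden ~ Poisson(0.25) for non-smokers and
Poisson(0.25 × 3.2) for smokers (smoker fraction 0.65); TP53 count ~
Poisson(0.43) for HPV-negative and Poisson(0.11) for HPV-positive
patients (HPV-positive fraction 0.24). Totals and TP53 counts are
drawn independently — the generator targets recovery of the two group
contrasts, not a joint per-gene model. At n = 5000 the estimated
burden fold and TP53 rate ratio recover the planted 3.2 and ~3.91
within 10% and 15% respectively (law-of-large-numbers tolerances used
by the tests).

## Problem sizes and design choices of record

* The calling benchmark is 50 pairs × 2000 single-base loci at median
  depth 1000 (5 somatic, 20 germline, 10 artifact loci per pair),
  pooled over pair seeds — large enough that pooled PPV has ~250
  accepted calls behind it, small enough to run in seconds.
* Cohort recovery uses n = 5000 patients, where Poisson-mean relative
  error is ≈ 2–5% for these rates.
* The panel carries no strand; CDS changes are assumed coding-strand
  oriented as printed. Positions are treated as opaque 1-based keys —
  no reference genome is required or consulted.
* BED is 0-based half-open; pileups, VCF and mutation tables 1-based.
* The worked-example mutation table lists 18 distinct mutated samples
  while the accompanying narrative counts 17; `verify_mutation_table`
  and the landscape driver surface the discrepancy without resolving
  it, and all statistics are computed from the rows as printed.

## Known limitations

Single-alternate-base loci only; no indels, no joint multi-sample
calling, no contamination or purity estimation, no base-quality
modelling (quality trimming is assumed upstream). The systematic
filter needs ≥200 background loci and so is unsuitable for very small
panels. Fisher tests are exact but the burden comparison dichotomizes
(any mutation vs none); a count model (e.g. Poisson regression) would
use more information on larger cohorts.
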