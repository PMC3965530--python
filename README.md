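# oncopanel

Somatic mutation calling for matched tumor/normal pairs on deep
targeted cancer-gene panels, plus the downstream mutation-landscape
statistics, built for reproducing and stress-testing a published
head-and-neck squamous cell carcinoma (HNSCC) cohort analysis design:
51 cancer genes, 37 tumor/lymphocyte pairs, 26 accepted point
mutations.

It is aimed at analysts who have per-locus pileup counts (depth and
per-base alternate counts) from a targeted panel and need a
transparent, fully testable filter cascade rather than a black-box
caller — and at anyone who wants to benchmark such a cascade against
simulated pairs with known ground truth.

## The method

A candidate variant at a locus survives five rules before acceptance:

1. **Coverage gate** — depth > 2% of the sample median **and** > 100
   reads, in both samples.
2. **Call threshold** — tumor variant allele fraction
   VAF = alt/depth ≥ 6% at the locus's most frequent non-reference
   base.
3. **Blacklist** — known recurrent systematic-positive loci are
   flagged.
4. **Germline subtraction** — matched-normal VAF > 1% flags the
   candidate as germline.
5. **Systematic-error percentile filter** — with the Phred-scaled
   binomial-tail score s(d, a) = −10·log10 P[Binomial(d, p₀) ≥ a]
   (background error p₀ = 0.5%), the tumor−normal score difference
   must exceed the 99.5th percentile of score differences over
   variant-free background loci of the same pair.

Candidates are returned with explicit filter flags (`low_coverage`,
`low_vaf`, `blacklist`, `germline`, `systematic`); accepted = no
flags. Accepted substitutions are classified from their codon change
under the standard genetic code (NON_SYNONYMOUS / STOP_GAINED /
SILENT, with SPLICE_SITE carried from locus annotation), and
cohort-level statistics (per-gene patient rates, per-patient burden,
gene×patient oncoprint matrix, Fisher exact group comparisons) follow.
A seeded simulator generates matched pileup pairs with planted
somatic, germline and artifact loci for sensitivity/PPV benchmarks.
See `docs/methods.md` for the full model and its assumptions.

## Worked example

The package ships a 26-row mutation table from a 37-patient HNSCC
cohort. Running

```
python analysis/01_mutation_landscape.py
```

prints:

```
26 mutations across 11 genes, 18 distinct mutated samples of 37
codon re-classification: 21 non-synonymous, 5 stop-gained; 26/26 rows consistent with printed annotations
  TP53: 13.0 mutations in 11.0 patients (29.7%)
  NOTCH1: 3.0 mutations in 3.0 patients (8.1%)
  FGFR3: 2.0 mutations in 2.0 patients (5.4%)
matrix written, grand total 26
```

Every effect class and protein change is re-derived from the printed
CDS change (e.g. `aTc/aCc` → I→T → NON_SYNONYMOUS, `p.I96T`) and all
26 agree with the printed annotations. TP53 is mutated 13 times in 11
of 37 patients (29.7%), including two patients with double hits, and
heads the rate-ranked oncoprint matrix written to
`results/landscape/matrix.tsv`. The scripts
`analysis/02_calling_benchmark.py` (50 simulated pairs: pooled PPV
100.0%, sensitivity 100.0% at the 6% threshold) and
`analysis/03_clinical_associations.py` (n=5000 cohort: smoker burden
fold 3.00 recovered vs 3.2 planted, Fisher p ≈ 2×10⁻¹⁰⁸; TP53
HPV-negative/HPV-positive rate ratio 3.87 vs 3.91 planted) complete
the analysis sequence.

There is also a CLI for the individual steps:

```
oncopanel simulate --seed 3 --outdir simdir
oncopanel call --tumor simdir/tumor.pileup.tsv --normal simdir/normal.pileup.tsv \
    --panel simdir/panel.bed --out-vcf calls.vcf --out-table calls.tsv
oncopanel annotate --table muts.tsv --report report.tsv
oncopanel landscape --table muts.tsv --n-patients 37 --outdir out
```

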