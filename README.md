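# promscope

Quantitative analysis of the transcriptional output of a two-promoter locus,
modelled on the human **FOXP3** gene in regulatory T cells. The locus carries
a sharp canonical promoter and, ~1.8 kb transcription-upstream of it, a broad
T<sub>REG</sub>-restricted alternative promoter whose products include a
poly(A)+ mRNA-like isoform with a long 5′-UTR extension (*longFOXP3*), short
poly(A)+ RNAs, and — inferred from short-read coverage — abundant short
non-adenylated RNAs. `promscope` re-implements the full quantitative chain
needed to characterise such a locus from four kinds of evidence:

1. **Long-read (direct RNA) classification** — rule-based filtering of aligned
   nanopore reads (neighbour-promoter contamination, 5′ decay products,
   truncated 3′-UTRs, aberrant splicing) and assignment of each surviving read
   to a promoter and isoform class, with abundance ratios, splice-variant
   fractions, cleavage-site offsets and poly(A)-tail statistics.
2. **Dual-modality estimation** — the ratio of non-adenylated to adenylated
   output of the alternative promoter from DRS read counts plus short-read
   coverage:

   *f* = n<sub>intact&nbsp;long</sub> / (n<sub>canonical</sub> + n<sub>intact&nbsp;long</sub> + n<sub>degraded&nbsp;long</sub>),  
   *R* = (C<sub>alt</sub> − *f*·C<sub>canon</sub>) / (*f*·C<sub>canon</sub>),

   where C<sub>canon</sub>, C<sub>alt</sub> are short-read coverages over the
   two CAGE-anchored *regions of probable transcription initiation*
   (peak summit ± 5σ, shifted 10 nt 3′-ward for the sequencer's 5′ loss).
3. **Coding-potential scanning** — AUG/CUG ORF discovery (first in-frame stop,
   ≥150 nt), Kozak-context scoring with an internal position-weight model,
   enumeration of main / N-terminally-extended proteoforms and uORFs, and
   average-mass molecular weights.
4. **smFISH speckle quantification** — nuclei → 3 µm-expanded cells →
   cytoplasm segmentation, per-channel diffraction-limited spot detection,
   fractional-overlap (≥0.3) co-localization of a 5′-extension (UPA) probe
   with a total-mRNA probe, per-culture summaries, and logistic-regression
   prevalence tests with a donor covariate and Bonferroni correction.

Everything is testable without downloads: the `simulate` module generates a
minus-strand 12-exon toy locus, seeded long-read sets with decay and poly(A)
tails, short-read coverage including non-adenylated species, microscopy fields
with planted spots, and presence/absence tables — each with a ground-truth
table.

## Worked example

Simulate a study, classify the reads and report abundances:

```bash
promscope simulate --seed 11 --out demo --n-reads 2000 --n-replicates 4 --skip-images
promscope classify --locus demo/locus.yaml --reads demo/reads.tsv --out demo/classified.csv
promscope abundance --classified demo/classified.csv --out demo/abundance
```

The classifier log shows the filter/assignment tally over the 8 000 reads:

```
reads in: 8000
excluded (outside_init_region): 2225
classified canonical_d2: 2117
classified canonical_fl: 1709
classified novel_canonical: 661
classified longFOXP3_d2: 582
classified longFOXP3_fl: 401
classified short_upstream: 228
classified longFOXP3_minor: 77
```

About 28 % of reads are excluded as 5′ decay products (the simulated decay
fraction is 0.30), and `demo/abundance/abundance_summary.json` holds the
cross-replicate median abundance ratios:

```json
"medians": {
  "canonical_to_long": 3.65,
  "canonical_to_novel": 6.18,
  "canonical_to_short": 16.82
},
"promoter_output_ratio": 3.48
```

i.e. canonical transcripts are ~6× the novel canonical-promoter isoforms,
~4× longFOXP3 and ~17× the short upstream transcripts, and the canonical
promoter's pooled poly(A)+ output is ~3.5× the alternative promoter's —
matching the mixture the simulation planted.

The dual-modality estimator on the shipped published counts:

```bash
promscope dual-modality --reference --out dual.json
```

```json
{"f": 0.117, "nonadenylated_to_adenylated_ratio": 4.13, "ratio_rounded": 4}
```

With *f* = 39/332 ≈ 0.12 and coverages 463 (canonical region) and 279
(alternative region), the alternative promoter's non-adenylated output is
estimated at ≈4× its adenylated output.

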