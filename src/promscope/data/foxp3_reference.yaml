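# Reference fixture for the human FOXP3 locus (hg38, minus strand).
#
# Contents: the robust FANTOM5 CAGE peaks associated to the locus, the two
# published regions of probable transcription initiation with their short-read
# coverages, the dual-modality worked example counts, the exon-11
# cross-technology coverage anchor, the 3'-UTR filter threshold, and the
# per-donor speckle count totals from the RNAscope analysis.
#
# All spans and positions are 1-based inclusive (converted on load).
strand: "-"

cage_peaks:
  - {promoter: canonical,   peak: 1, cluster: "chrX:49264704-49264717", tss: "chrX:49264710", score: 18671}
  - {promoter: canonical,   peak: 2, cluster: "chrX:49264549-49264582", tss: "chrX:49264567", score: 315}
  - {promoter: alternative, peak: 1, cluster: "chrX:49266299-49266300", tss: "chrX:49266300", score: 396}
  - {promoter: alternative, peak: 2, cluster: "chrX:49266450-49266454", tss: "chrX:49266452", score: 195}
  - {promoter: alternative, peak: 3, cluster: "chrX:49266491-49266500", tss: "chrX:49266496", score: 453}
  - {promoter: alternative, peak: 4, cluster: "chrX:49266722-49266750", tss: "chrX:49266729", score: 261}

# Published regions of probable transcription initiation (shipped verbatim:
# the per-peak sigma/asymmetry used to derive them is not public), with the
# short-read coverage measured over each.
initiation_regions:
  canonical_peak1:   {span: "chrX:49264670-49264735", ngs_coverage: 463}
  alternative_peak1: {span: "chrX:49266233-49266279", ngs_coverage: 272}

# Worked example of the non-adenylated:adenylated estimator.  The coverage
# over the alternative region is printed as 272 in the prose but 279 in the
# equation chain; the equation's value is the one used.
dual_modality:
  n_canonical_output: 206
  n_intact_longFOXP3: 39
  n_degraded_longFOXP3: 87
  alt_polya_output: {longFOXP3: 126, special_splice: 4, short_upstream: 3}
  coverage_canonical_region: 463
  coverage_alternative_region: 279

exon11_anchor: {ngs_max: 894, drs_max: 912}

# Reads whose 3'-most nucleotide maps transcription-upstream of this position
# carry a 3'-UTR at least 50 nt shorter than annotated (filter iii).
pas_filter: {min_three_prime: "chrX:49250487"}

# Per-donor totals of co-localization (longFOXP3) and UPA-only events.
speckle_counts:
  - {donor: HD45, coloc: 850, upa_only: 1713}
  - {donor: HD46, coloc: 737, upa_only: 1347}
  - {donor: HD49, coloc: 122, upa_only: 647}
  - {donor: HD50, coloc: 391, upa_only: 1151}

# Start-context scores reported by an external predictor for the main starts;
# kept as reference annotations only (not comparable to the internal scorer).
kozak_reference: {canonical_AUG: 0.57, extended_AUG: 0.49, extended_CUG: 0.56}
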