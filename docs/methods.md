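# Methods

## Coordinate model and regions of probable transcription initiation

All internal coordinates are 0-based half-open; BED/bedGraph are read
natively, while GTF-style records and `chr:start-end` spans are 1-based
inclusive and converted at the I/O boundary. The locus is fully strand-aware:
"upstream/downstream" always means the direction of transcription, and every
coordinate operation satisfies a mirror-symmetry property (reflecting all
positions through a constant and flipping the strand leaves widths,
memberships and classification outcomes unchanged). The default synthetic
locus is minus-strand, like FOXP3, with the alternative promoter at higher
coordinates than the canonical one.

A read's 5′ end is ascribed to a promoter only if it falls inside a *region of
probable transcription initiation* built from a CAGE peak: the summit is
broadened by `broaden_factor` (default 5) times the peak's positional standard
deviation on each side, then the region is translated `tech_shift_nt` (default
10) bases toward the 3′ direction of transcription, because direct RNA
sequencing misses the terminal 5–15 nt of each molecule. Asymmetric
broadening is accepted as separate transcription-upstream/downstream sigmas.
When a source publishes no per-peak σ, it defaults to a quarter of the cluster
width (the cluster treated as ≈±2σ). The two *published* FOXP3 regions are
shipped verbatim in the reference fixture (`promscope/data/foxp3_reference.yaml`)
rather than re-derived, because the σ and asymmetry values behind them are not
public; the builder itself is exercised on synthetic peaks with known σ.

## Read filtering and classification

Four ordered rules are applied, and the first violated rule is the one
recorded:

(i) 5′ end in the neighbouring gene's promoter; (ii) 5′ end outside every
initiation region (decay products/aborted sequencing); (iii) 3′-most
nucleotide stopping transcription-side of a single threshold position 50 nt
short of the PAS (equivalent to "3′-UTR ≥50 nt shorter than annotated", one
comparison); (iv) splice-junction chain matching no whitelisted transcript
structure. Junction matching is exact by default (`junction_slack` in nt is
configurable) against the chains generated by {first-exon structure} ×
{allowed skip signature}, restricted to the read's span so 5′-truncated reads
are judged only on the junctions they cover.

Short upstream transcripts — alternative-promoter reads whose 3′ end never
reaches the first coding exon — are exempt from (iii)/(iv), which they violate
by definition, but remain subject to (i)/(ii). Minor skip signatures ({7},
{2,7}) are admitted only for the extended (longFOXP3) structure; the canonical
promoter's whitelist is {∅, {2}}, since minor skipping is described only for
the alternative promoter's long transcripts. Novel canonical-promoter
isoforms are recognised by a 5′ block whose splice donor departs from the
annotated exon −1 and that overlaps an annotated alternate first-exon variant
by ≥50 % of the block (configurable).

Abundance ratios use canonical (fl + d2) reads as the numerator; novel
canonical-promoter isoforms are reported separately and are *not* pooled into
that numerator (the source material leaves this open). A replicate with zero
canonical reads has undefined (NaN, flagged) ratios — never infinities. The
cross-replicate median of an even number of ratios is the mean of the central
pair. The promoter-output ratio pools canonical + novel reads over longFOXP3 +
short-upstream reads. Poly(A) statistics report mean, median and the mode of
integer-rounded tail lengths (ties to the smallest); two-group comparisons use
the two-sided Mann–Whitney U, exact for combined n ≤ 20 without ties,
tie-corrected normal approximation otherwise.

## Dual-modality estimator

The estimator assumes (a) coverage over the canonical initiation region stems
from canonical-promoter transcripts plus longFOXP3 molecules (intact or
5′-degraded) passing through it; (b) the alternative promoter's poly(A)+
output is ≈ its intact longFOXP3 reads (adenylated short upstream RNAs are
rare); (c) per-copy short-read coverage is comparable between the two regions.
"Degraded longFOXP3" is operationalised as reads excluded by rule (ii) whose
5′ end lies between the alternative regions and the canonical region and whose
alignment still spans the canonical region. Region coverage uses the mean for
promoter regions and the max for the exon-11 cross-technology anchor (the
published anchor is a coverage range); both are configurable. R is reported
unrounded with a rounded convenience field; a negative R is flagged as "no
detectable non-adenylated excess", and zero denominators yield explicit
undefined flags rather than infinities.

Because of assumption (c), the synthetic short-read generator defaults to
per-base molecule pileup (every molecule adds one count to each base it spans
— the infinite-fragmentation limit). Finite-fragment sampling is available
(`ngs_mode="sample"`), but a fixed fragment length creates a 5′ coverage ramp
at a TSS-anchored region that violates (c) for any estimator, which would make
recovery tests measure the assumption rather than the implementation. For the
same reason the end-to-end ρ-recovery experiment uses the pooled-sample class
mixture in which adenylated short upstream transcripts are ~2 % of the
alternative promoter's poly(A)+ output, matching assumption (b); under the
survey-style mixture (shorts ≈23 % of longFOXP3) the estimator is biased
upward by exactly that share, which is a property of the method, not a defect
of the code.

## Coding-potential scanning

ORFs start at AUG or CUG, run to the first in-frame stop, and must reach
150 nt including the stop codon (both configurable); ORFs without an in-frame
stop are discarded. A 150-nt ORF encodes 49 residues
(`length_aa = length_nt/3 − 1`). The Kozak scorer is an internal
position-weight model of the vertebrate consensus (gccRccAUGG): seven flank
positions (−6…−1 and +4) carry per-base preferences normalised so the
consensus context scores exactly 1.0 and an all-N or out-of-sequence context
0.0, with the −3 purine (weight 3) and +4 G (weight 2) dominant. Scores from
external web predictors are shipped as reference annotations only; they are
not comparable to this scale. Proteoform enumeration reports the main ORF,
every in-frame upstream AUG/CUG reaching the main stop without an intervening
stop (N-terminally extended proteoforms), and all uORFs whose start lies in
the 5′-UTR, including uORFs overlapping the main start. Molecular weights use
average residue masses plus one water, in kDa; near-cognate CUG starts are
translated with an initiator methionine, as in vivo initiation uses
Met-tRNA<sub>i</sub>.

## smFISH quantification

Nuclei are segmented from DAPI by Gaussian smoothing (σ = 2 px), a global Otsu
threshold, size filtering (diameter 10–60 px) and a distance-transform
watershed to split touching nuclei. Cells are each nucleus dilated by
`round(radius_um·1000/pixel_size_nm)` pixels (3 µm ≙ 29 px at 104 nm/px) with
collisions resolved by nearest nucleus; cytoplasm is cell minus nucleus.
Spots are enhanced with a white top-hat (structuring radius ≈ the expected
spot radius, 3 px), then thresholded at the larger of Otsu and a robust noise
floor (median + 4 MAD-sigmas of the enhanced image) so blank or pure-noise
images yield no spots; each connected component counts as one transcript, so
merged agglomerates count once. A UPA spot co-localizes when ≥ `min_overlap`
(default 0.3) of *its own* area overlaps the union of mRNA spots; normalising
by the mRNA spot instead is a config option, and the interpretation is
recorded in the output metadata.

Compartment assignment is centroid-in-nucleus on the 2-D projection. As in
any projected analysis of cells with a high nuclear:cytoplasmic ratio this
overestimates nuclear localization, so the nuclear fractions are
semi-quantitative outputs. Spots outside every cell mask are dropped from
summaries. Because it is ambiguous whether a published co-localization
percentage is pooled or a per-cell median, the culture summary emits both
(`pct_upa_colocalized_pooled`, `pct_upa_colocalized_cell_median`).

## Prevalence statistics

Speckle prevalence between two cell types is tested with a binomial GLM on the
long-format per-cell table (donor, cell type, presence): response = presence,
predictors = a cell-type indicator plus reference-coded donor indicators
(fixed effects; no random effects). The reported p-value is the Wald test on
the cell-type coefficient (IRLS to tolerance 1e-8); complete or
quasi-separation (|coefficient| > 15 or non-convergence) is flagged in the
result, never silently reported. P-values across all pairwise tests are
Bonferroni-multiplied and clipped at 1. The reporter-normalised fold change
for over-expression readouts is the double ratio
(target<sub>treated</sub>/target<sub>control</sub>) /
(reporter<sub>treated</sub>/reporter<sub>control</sub>), NaN on zero
denominators.

## Synthetic data: what it emulates, and what it does not

The default locus is a 30 kb minus-strand chromosome with exon −1 at
[20000, 20200), exons 1–11 descending to a 594-nt terminal exon containing the
PAS, a canonical promoter of two peaks (score ratio ≈59), a four-peak
alternative promoter whose transcripts carry a 1 800-nt first-exon extension,
an alternate exon −1 variant (novel canonical isoforms) and a neighbouring
promoter further upstream. The full-length extended transcript is 3 903 nt —
a 1 800-nt extension with four planted uORFs and two in-frame upstream starts,
a 300-nt canonical UTR with a fifth uORF, a 1 296-nt main ORF (431 aa) and a
507-nt 3′-UTR; outside the planted elements the UTRs contain no AUG/CUG, so
scans recover exactly the planted structure.

Long-read generation draws molecule classes from configurable mixture weights
(default ≈ canonical 6 : novel 1 : longFOXP3 1.5 : short 0.35, with longFOXP3
split 37/56/7 % fl/d2/minor), TSS jitter (σ = 2 nt) within score-weighted CAGE
peaks, ±2 nt cleavage scatter at the PAS, log-normal poly(A) tails
(log-σ 0.35) with modes 89 nt (FOXP3-like) and 53 nt (short upstream), a
uniform 5–15 nt 5′ sequencing loss, and geometric (memoryless) 5′→3′ decay
(default fraction 0.3, mean 800 nt) applied in spliced-transcript coordinates.
Short-read coverage is the per-base pileup of the same molecule population
plus non-adenylated upstream transcripts at ρ× the adenylated
alternative-promoter molecules, ending between the promoters short of the
canonical region. Imaging fields place nuclei (radius ≈18 px) on a jittered
grid whose spacing keeps expanded cells disjoint, draw per-cell spot counts
from zero-inflated Poisson (or negative-binomial) laws, place spots with a
minimum separation — dropping, not misplacing, spots when a compartment
saturates, so the truth table stays exact — plant the co-localized fraction by
putting UPA spots within ±0.7 px of an mRNA spot, and add Poisson shot noise
plus Gaussian read noise with the spot amplitude set by the configured SNR.
Presence tables are Bernoulli draws from a planted logistic model with
cell-type logits (defaults at the reported medians 88/18/11/6 %) and additive
donor effects.

Not emulated: sequencing errors and basecalling signal, realistic cell
morphology or 3-D imaging, intensity variation within spot agglomerates,
overlapping cells, and batch effects beyond additive donor shifts. Passing
recovery tests therefore demonstrates correctness of the measurement chain
under the stated statistical structure, not robustness to every artefact of
real data.

## Numerical choices and problem sizes

Undefined statistics are NaN plus an explicit flag, never raised or infinite,
except where an input violates a precondition (validation errors). Modal
tail-length ties break to the smallest value; even-count medians average the
central pair; Bonferroni clips at 1. All generators consume a single integer
seed through `numpy.random.default_rng`; identical seeds give byte-identical
artifacts. Test and acceptance problem sizes — 4 replicates × 4 000–10 000
reads, 4 fields × 100 cells, 100–500 GLM simulations — are the smallest at
which the stated statistical tolerances (3 multinomial SEs, ±5 percentage
points, ±30 % on ρ, ≤7 % type-I) are meaningful for the planted effects.

## Known limitations

The initiation-region builder cannot reproduce the two published FOXP3
regions because their σ/asymmetry inputs are unpublished; they ship as
fixtures. The dual-modality estimator inherits the assumptions listed above
and degrades gracefully (negative R is flagged) when C_alt falls below
f·C_canon. Kozak scores are internally consistent but on a different scale
from external predictors. The FISH pipeline is 2-D and semi-quantitative for
subcellular localization; per-spot intensity is not used to split
agglomerates.
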