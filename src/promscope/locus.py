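"""Locus annotation model, CAGE peaks and regions of probable transcription initiation.

The locus model is strand-aware and mirrors the organisation of the human
FOXP3 gene: a minus-strand gene of 12 exons numbered -1 and 1..11, a canonical
promoter at the 5' end of exon -1, a broad alternative promoter further
upstream (higher coordinates on a minus-strand gene), a neighbouring gene
promoter (PPP1R3F-like) upstream of that, and a single cleavage/polyadenylation
site (PAS) inside the terminal exon.

A read's 5' end is ascribed to a promoter only if it falls inside a *region of
probable transcription initiation*: a CAGE peak summit broadened by a multiple
of the peak's positional standard deviation and translated a few bases in the
direction of transcription to absorb the 5' truncation inherent to direct RNA
sequencing (the sequencer misses the terminal 5-15 nt of each molecule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import (
    GenomicInterval,
    ValidationError,
    is_transcription_upstream,
)

CANONICAL = "canonical"
ALTERNATIVE = "alternative"
PROMOTERS = (CANONICAL, ALTERNATIVE)


class ConfigError(ValueError):
    """Raised when configuration-level invariants are violated (e.g. overlapping regions)."""


@dataclass(frozen=True)
class CagePeak:
    """A scored CAGE TSS cluster.

    ``sigma`` is the positional standard deviation of the peak in nt; when the
    source does not publish one it defaults to a quarter of the cluster width
    (the cluster treated as an approximate +/-2 sigma span).
    """

    cluster: GenomicInterval
    summit: int
    score: float
    promoter_id: str
    peak_number: int
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.cluster.contains(self.summit):
            raise ValidationError(
                f"summit {self.summit} outside cluster {self.cluster}"
            )
        if self.score < 0:
            raise ValidationError("CAGE score must be non-negative")
        if self.sigma is not None and self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if self.promoter_id not in PROMOTERS:
            raise ValidationError(f"unknown promoter_id {self.promoter_id!r}")

    @property
    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        return self.cluster.width / 4.0


@dataclass(frozen=True)
class InitiationRegion:
    interval: GenomicInterval
    source_peak: Optional[CagePeak]
    promoter_id: str

    def __post_init__(self) -> None:
        if self.interval.width < 1:
            raise ValidationError("initiation region must have width >= 1")

    def contains(self, pos: int) -> bool:
        return self.interval.contains(pos)


def build_initiation_region(
    peak: CagePeak,
    strand: str,
    broaden_factor: float = 5.0,
    tech_shift_nt: int = 10,
    sigma_upstream: Optional[float] = None,
    sigma_downstream: Optional[float] = None,
    chrom_length: Optional[int] = None,
) -> InitiationRegion:
    """Broaden a CAGE peak and shift it in the direction of transcription.

    The summit is extended by ``broaden_factor * sigma`` on each side
    (asymmetric broadening via separate upstream/downstream sigmas, measured
    relative to the direction of transcription), then the whole interval is
    translated ``tech_shift_nt`` bases toward the 3' direction of
    transcription, and finally clipped to chromosome bounds.
    """
    if tech_shift_nt < 0:
        raise ValidationError("tech_shift_nt must be non-negative")
    if broaden_factor < 0:
        raise ValidationError("broaden_factor must be non-negative")
    sig_up = peak.resolved_sigma if sigma_upstream is None else float(sigma_upstream)
    sig_down = (
        peak.resolved_sigma if sigma_downstream is None else float(sigma_downstream)
    )
    if sig_up < 0 or sig_down < 0:
        raise ValidationError("sigma must be non-negative")

    up = int(round(broaden_factor * sig_up))
    down = int(round(broaden_factor * sig_down))
    shift = -tech_shift_nt if strand == "-" else tech_shift_nt
    center = peak.summit + shift
    if strand == "-":
        # transcription-upstream is the higher-coordinate side
        lo, hi = center - down, center + up
    else:
        lo, hi = center - up, center + down
    start, end = lo, hi + 1  # inclusive bounds -> half-open
    if chrom_length is not None:
        start = max(0, start)
        end = min(chrom_length, end)
        if start >= end:
            raise ValidationError("initiation region falls outside the chromosome")
    elif start < 0:
        raise ValidationError("initiation region falls outside the chromosome")
    interval = GenomicInterval(peak.cluster.chrom, start, end, strand)
    return InitiationRegion(interval, peak, peak.promoter_id)


def validate_regions(regions: Sequence[InitiationRegion]) -> None:
    """Initiation regions must be pairwise non-overlapping (configuration error)."""
    ordered = sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.interval.overlaps(b.interval):
            raise ConfigError(
                f"overlapping initiation regions {a.interval} / {b.interval}"
            )


def assign_five_prime(
    pos: int, regions: Sequence[InitiationRegion]
) -> Optional[str]:
    """Promoter of the unique initiation region containing ``pos``, else None."""
    for region in regions:
        if region.contains(pos):
            return region.promoter_id
    return None


@dataclass
class LocusAnnotation:
    """Strand-aware exon/PAS/promoter model of a FOXP3-like gene.

    ``exons`` are listed in the direction of transcription (exon -1 first) and
    must be non-overlapping.  ``extended_first_exon`` is the 5'-extended first
    exon used by transcripts initiating at the alternative promoter (it shares
    its splice donor with exon -1).  ``pas_min_3prime`` is the threshold of
    read filter (iii): reads whose 3'-most nucleotide maps transcription-side
    (upstream) of it carry a 3'-UTR at least 50 nt shorter than annotated.
    """

    chrom: str
    strand: str
    chrom_length: int
    gene_interval: GenomicInterval
    exons: list[tuple[int, GenomicInterval]]
    cds_exons: set[int]
    pas_position: int
    pas_min_3prime: int
    canonical_peaks: list[CagePeak]
    alternative_peaks: list[CagePeak]
    neighbor_promoter: GenomicInterval
    allowed_splice_patterns: set[frozenset[int]] = field(
        default_factory=lambda: {
            frozenset(),
            frozenset({2}),
            frozenset({7}),
            frozenset({2, 7}),
        }
    )
    alt_first_exon_variants: list[GenomicInterval] = field(default_factory=list)
    extended_first_exon: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        ivs = [iv for _, iv in self.exons]
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValidationError(f"overlapping exons {a} / {b}")
            if not is_transcription_upstream(a.start, b.start, self.strand):
                raise ValidationError(
                    "exons must be ordered along the direction of transcription"
                )
        terminal = self.exon(self.exons[-1][0])
        if not terminal.contains(self.pas_position):
            raise ValidationError("pas_position must lie within the terminal exon")
        regions = self.initiation_regions()
        for region in regions:
            if region.interval.overlaps(self.neighbor_promoter):
                raise ValidationError(
                    "neighbor promoter overlaps an initiation region"
                )

    # -- accessors ----------------------------------------------------------
    def exon(self, number: int) -> GenomicInterval:
        for num, iv in self.exons:
            if num == number:
                return iv
        raise KeyError(f"no exon {number}")

    @property
    def exon_numbers(self) -> list[int]:
        return [num for num, _ in self.exons]

    @property
    def all_peaks(self) -> list[CagePeak]:
        return list(self.canonical_peaks) + list(self.alternative_peaks)

    def initiation_regions(
        self,
        broaden_factor: float = 5.0,
        tech_shift_nt: int = 10,
    ) -> list[InitiationRegion]:
        regions = [
            build_initiation_region(
                peak,
                self.strand,
                broaden_factor=broaden_factor,
                tech_shift_nt=tech_shift_nt,
                chrom_length=self.chrom_length,
            )
            for peak in self.all_peaks
        ]
        validate_regions(regions)
        return regions

    def upstream_of(self, a: int, b: int) -> bool:
        return is_transcription_upstream(a, b, self.strand)

    # -- mirroring ----------------------------------------------------------
    def mirrored(self, constant: Optional[int] = None) -> "LocusAnnotation":
        """The coordinate-reflected, strand-flipped locus (mirror symmetry checks)."""
        c = self.chrom_length if constant is None else constant

        def miv(iv: GenomicInterval) -> GenomicInterval:
            return iv.mirrored(c)

        def mpeak(p: CagePeak) -> CagePeak:
            return CagePeak(
                cluster=miv(p.cluster),
                summit=c - p.summit,
                score=p.score,
                promoter_id=p.promoter_id,
                peak_number=p.peak_number,
                sigma=p.sigma,
            )

        return LocusAnnotation(
            chrom=self.chrom,
            strand="+" if self.strand == "-" else "-",
            chrom_length=max(self.chrom_length, c),
            gene_interval=miv(self.gene_interval),
            exons=[(num, miv(iv)) for num, iv in self.exons],
            cds_exons=set(self.cds_exons),
            pas_position=c - self.pas_position,
            pas_min_3prime=c - self.pas_min_3prime,
            canonical_peaks=[mpeak(p) for p in self.canonical_peaks],
            alternative_peaks=[mpeak(p) for p in self.alternative_peaks],
            neighbor_promoter=miv(self.neighbor_promoter),
            allowed_splice_patterns=set(self.allowed_splice_patterns),
            alt_first_exon_variants=[miv(iv) for iv in self.alt_first_exon_variants],
            extended_first_exon=(
                miv(self.extended_first_exon)
                if self.extended_first_exon is not None
                else None
            ),
        )
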