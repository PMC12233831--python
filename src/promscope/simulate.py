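"""Synthetic-data generators for every pipeline input.

The default locus template mirrors the organisation of the human FOXP3 gene
on a small synthetic chromosome: a minus-strand gene of 12 exons (numbered -1,
1..11), a sharply peaked canonical promoter at the 5' end of exon -1, a broad
four-peak alternative promoter ~1.8 kb transcription-upstream whose transcripts
carry a 5'-extended first exon, a neighbouring gene promoter further upstream,
and a single PAS in the terminal exon.

Generators are deterministic given a seed and every stochastic entity is
accompanied by a ground-truth record, so downstream operations can be scored
without re-reading the generator's internals.  Emulated features of real
direct-RNA data: mixed promoter usage at stated class proportions, TSS jitter
within CAGE peaks, the 5-15 nt 5' loss of the sequencing chemistry, geometric
(memoryless) 5'->3' decay producing truncated reads, +/-2 nt cleavage-site
scatter, and log-normal poly(A) tail lengths with distinct modes (89 nt for
FOXP3-like transcripts, 53 nt for the short upstream RNAs).  Short-read
coverage is modelled as a per-base pileup of the molecule population,
including non-adenylated upstream transcripts invisible to DRS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dualmod import CoverageTrack
from .fishquant import FishImage
from .intervals import GenomicInterval, ValidationError
from .locus import ALTERNATIVE, CANONICAL, CagePeak, LocusAnnotation
from .orfscan import TranscriptSequence
from .prevalence import presence_records
from .reads import (
    CANONICAL_D2,
    CANONICAL_FL,
    LONG_CLASSES,
    LONG_D2,
    LONG_FL,
    LONG_MINOR,
    NOVEL_CANONICAL,
    SHORT_UPSTREAM,
    LongRead,
)

NONADENYLATED_SHORT = "short_upstream_nonpolya"

# classes whose poly(A) tails follow the FOXP3-like mode
_FOXP3_LIKE = {CANONICAL_FL, CANONICAL_D2, NOVEL_CANONICAL, *LONG_CLASSES}

# Fig-1B-median-style default mixture: canonical : novel : longFOXP3 : short
# at roughly 6 : 1 : 1.5 : 0.35, with the within-promoter splice splits at the
# reported averages (fl 37% / d2 56% / minor 7% of longFOXP3).
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    CANONICAL_FL: 2.64,
    CANONICAL_D2: 3.36,
    NOVEL_CANONICAL: 1.0,
    LONG_FL: 0.555,
    LONG_D2: 0.84,
    LONG_MINOR: 0.105,
    SHORT_UPSTREAM: 0.35,
}

# pooled-sample mixture for the dual-modality experiment: adenylated short
# upstream transcripts are a negligible share of the alternative promoter's
# poly(A)+ output, matching the estimator's own assumption.
DUALMOD_CLASS_WEIGHTS: dict[str, float] = {
    CANONICAL_FL: 0.27,
    CANONICAL_D2: 0.33,
    NOVEL_CANONICAL: 0.02,
    LONG_FL: 0.14,
    LONG_D2: 0.21,
    LONG_MINOR: 0.02,
    SHORT_UPSTREAM: 0.01,
}


@dataclass
class SimulationConfig:
    """Study conditions for all generators (units in nt/px where applicable)."""

    # long-read experiment
    n_reads: int = 4000
    n_replicates: int = 4
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    decay_fraction: float = 0.3
    decay_mean_nt: float = 800.0
    tss_jitter_sd: float = 2.0
    tech_shift_range: tuple[int, int] = (5, 15)  # 5' nt lost by the sequencer
    pas_jitter: tuple[int, int] = (-2, 2)  # cleavage-site scatter (inclusive)
    short_len_range: tuple[int, int] = (200, 1200)
    polya_mode_foxp3: float = 89.0
    polya_mode_background: float = 53.0
    polya_log_sigma: float = 0.35

    # short-read experiment
    ngs_molecules: int = 2000
    nonadenylated_ratio: float = 4.0  # rho: non-poly(A) per poly(A)+ alt molecule
    ngs_mode: str = "tile"  # "tile" (per-base pileup) or "sample" (fragments)
    ngs_fragment_length: int = 150
    ngs_fragments_per_kb: float = 20.0

    # imaging experiment
    n_fields: int = 4
    n_cells_per_field: int = 100
    field_shape: tuple[int, int] = (1152, 1152)
    pixel_size_nm: float = 104.0
    nucleus_radius_px: float = 18.0
    nucleus_radius_sd: float = 1.0
    cell_expand_um: float = 3.0
    spot_sigma_px: float = 1.3
    snr: float = 8.0
    background: float = 20.0
    noise_sd: float = 10.0
    count_law: str = "poisson"  # or "negbin"
    negbin_n: float = 5.0
    mrna_positive_prob: float = 0.9
    mrna_mean: float = 6.0
    upa_positive_prob: float = 0.88
    upa_mean: float = 4.0
    coloc_fraction: float = 0.22
    nuclear_fraction: float = 0.85
    min_spot_separation_px: float = 5.0

    # presence/absence experiment
    donors: tuple[str, ...] = ("HD1", "HD2", "HD3", "HD4")
    cell_type_logits: dict[str, float] = field(
        default_factory=lambda: {
            "naive_treg": math.log(0.88 / 0.12),
            "memory_treg": math.log(0.18 / 0.82),
            "memory_tconv": math.log(0.11 / 0.89),
            "naive_tconv": math.log(0.06 / 0.94),
        }
    )
    donor_effects: dict[str, float] = field(
        default_factory=lambda: {"HD1": 0.2, "HD2": -0.2, "HD3": 0.1, "HD4": -0.1}
    )
    n_cells_per_group: int = 200

    def __post_init__(self) -> None:
        weights = np.array(list(self.class_weights.values()), dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValidationError("class weights must be non-negative and sum > 0")
        for p in (
            self.decay_fraction,
            self.mrna_positive_prob,
            self.upa_positive_prob,
            self.coloc_fraction,
            self.nuclear_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValidationError(f"probability {p} outside [0, 1]")


# ---------------------------------------------------------------------------
# locus template and transcript sequences
# ---------------------------------------------------------------------------


def default_locus(mirror: bool = False) -> LocusAnnotation:
    """The default minus-strand FOXP3-like locus on a 30 kb synthetic chromosome."""
    chrom = "chrS"

    def iv(start: int, end: int) -> GenomicInterval:
        return GenomicInterval(chrom, start, end, "-")

    exon_spans = [
        (-1, 20000, 20200),
        (1, 19550, 19800),
        (2, 19300, 19399),
        (3, 19050, 19170),
        (4, 18800, 18920),
        (5, 18550, 18670),
        (6, 18300, 18420),
        (7, 18050, 18170),
        (8, 17800, 17920),
        (9, 17550, 17670),
        (10, 17300, 17420),
        (11, 16000, 16594),
    ]

    def peak(promoter: str, number: int, summit: int, score: float, sigma: float) -> CagePeak:
        half = int(2 * sigma)
        return CagePeak(
            cluster=iv(summit - half, summit + half + 1),
            summit=summit,
            score=score,
            promoter_id=promoter,
            peak_number=number,
            sigma=sigma,
        )

    ann = LocusAnnotation(
        chrom=chrom,
        strand="-",
        chrom_length=30000,
        gene_interval=iv(15900, 22100),
        exons=[(num, iv(s, e)) for num, s, e in exon_spans],
        cds_exons=set(range(1, 12)),
        pas_position=16000,
        pas_min_3prime=16050,
        canonical_peaks=[
            peak(CANONICAL, 1, 20190, 18671.0, 3.0),
            peak(CANONICAL, 2, 20150, 315.0, 3.0),
        ],
        alternative_peaks=[
            peak(ALTERNATIVE, 1, 21820, 396.0, 4.0),
            peak(ALTERNATIVE, 2, 21890, 195.0, 4.0),
            peak(ALTERNATIVE, 3, 21940, 453.0, 4.0),
            peak(ALTERNATIVE, 4, 21995, 261.0, 4.0),
        ],
        neighbor_promoter=iv(22500, 22900),
        alt_first_exon_variants=[iv(20080, 20200)],
        extended_first_exon=iv(20000, 22050),
    )
    return ann.mirrored() if mirror else ann


_SAFE_BODY_CODON = "CAC"  # G-free, stop-free filler codon for planted ORFs
_STOP = "UAA"


def _planted_orf(start_codon: str, length_nt: int) -> str:
    """An ORF of exact total length with no internal starts or stops."""
    n_body = length_nt // 3 - 2
    return start_codon + _SAFE_BODY_CODON * n_body + _STOP


def default_transcripts(seed: int = 0) -> dict[str, TranscriptSequence]:
    """Transcript sequences of the default locus's main isoforms.

    The longFOXP3-like transcript carries a 1800-nt 5' extension with five
    planted uORFs (>= 150 nt, CUG/CUG/CUG/AUG starts) and two in-frame
    upstream starts (CUG then AUG) that share the main stop, one further
    CUG uORF inside the canonical 5'-UTR, a 1296-nt main ORF and a 507-nt
    3'-UTR - 3903 nt in total for the full-length variant.  Outside the
    planted elements the 5'-UTRs contain no AUG/CUG at all, so coding-potential
    scans recover exactly the planted structure.
    """
    rng = np.random.default_rng(seed)
    uorfs = [
        _planted_orf("CUG", 156),
        _planted_orf("CUG", 150),
        _planted_orf("CUG", 216),
        _planted_orf("AUG", 285),
    ]
    extension = ""
    for orf in uorfs:
        extension += "C" * 30 + orf
    extension += "C" * (1746 - len(extension))
    extension += "CUG" + "CCC" * 5 + "AUG" + "C" * 33
    assert len(extension) == 1800

    canonical_utr = "C" * 61 + _planted_orf("CUG", 150) + "C" * 89
    assert len(canonical_utr) == 300

    codons = [
        a + b + c
        for a in "ACGU"
        for b in "ACGU"
        for c in "ACGU"
        if a + b + c not in ("UAA", "UAG", "UGA")
    ]
    cds = "AUG" + "".join(rng.choice(codons, size=430)) + _STOP
    assert len(cds) == 1296
    utr3 = "".join(rng.choice(list("ACGU"), size=507))

    long_fl = extension + canonical_utr + cds + utr3
    canonical_fl = long_fl[1800:]
    # delta-2: the 99-nt exon-2 segment sits at canonical offsets [450, 549)
    canonical_d2 = canonical_fl[:450] + canonical_fl[549:]
    long_d2 = long_fl[:2250] + long_fl[2349:]
    return {
        "longFOXP3_fl": TranscriptSequence(
            "longFOXP3_fl", long_fl, main_start=2100, utr5_end=2100, splice_signature="fl"
        ),
        "longFOXP3_d2": TranscriptSequence(
            "longFOXP3_d2", long_d2, main_start=2100, utr5_end=2100, splice_signature="d2"
        ),
        "canonical_fl": TranscriptSequence(
            "canonical_fl", canonical_fl, main_start=300, utr5_end=300, splice_signature="fl"
        ),
        "canonical_d2": TranscriptSequence(
            "canonical_d2", canonical_d2, main_start=300, utr5_end=300, splice_signature="d2"
        ),
    }


def simulate_locus(
    seed: int = 0, mirror: bool = False
) -> tuple[LocusAnnotation, dict[str, TranscriptSequence]]:
    """Deterministic locus annotation plus its transcript sequences."""
    return default_locus(mirror=mirror), default_transcripts(seed)


# ---------------------------------------------------------------------------
# molecule machinery (shared by the DRS and NGS generators)
# ---------------------------------------------------------------------------


def _downstream(pos: int, k: int, strand: str) -> int:
    """Move k nt in the direction of transcription."""
    return pos - k if strand == "-" else pos + k


def _class_chain(ann: LocusAnnotation, cls: str) -> list[GenomicInterval]:
    """Exon chain (transcription order) of a transcript class."""
    body = [(num, iv) for num, iv in ann.exons if num != -1]
    if cls in (SHORT_UPSTREAM, NONADENYLATED_SHORT):
        ext = ann.extended_first_exon
        exon1 = ann.exon(1)
        # unspliced: the extended first exon plus the first intron
        if ann.strand == "-":
            return [GenomicInterval(ann.chrom, exon1.end, ext.end, ann.strand)]
        return [GenomicInterval(ann.chrom, ext.start, exon1.start, ann.strand)]
    if cls in (CANONICAL_FL, CANONICAL_D2):
        first, skip = ann.exon(-1), ({2} if cls == CANONICAL_D2 else set())
    elif cls == NOVEL_CANONICAL:
        first, skip = ann.alt_first_exon_variants[0], set()
    elif cls == LONG_FL:
        first, skip = ann.extended_first_exon, set()
    elif cls == LONG_D2:
        first, skip = ann.extended_first_exon, {2}
    elif cls == LONG_MINOR:
        first, skip = ann.extended_first_exon, {7}
    else:
        raise ValidationError(f"unknown class {cls!r}")
    return [first] + [iv for num, iv in body if num not in skip]


def _clip_chain(
    chain: Sequence[GenomicInterval], five: int, three: int, strand: str
) -> list[GenomicInterval]:
    """Genomic blocks of a molecule with the given 5'/3' terminal bases.

    The terminal chain intervals are extended when a jittered end runs a base
    or two past the annotated exon boundary (cleavage-site scatter).
    """
    lo, hi = (three, five) if strand == "-" else (five, three)
    work = [replace(iv) for iv in chain]
    if strand == "-":
        if lo < work[-1].start:
            work[-1] = replace(work[-1], start=lo)
        if hi >= work[0].end:
            work[0] = replace(work[0], end=hi + 1)
    else:
        if lo < work[0].start:
            work[0] = replace(work[0], start=lo)
        if hi >= work[-1].end:
            work[-1] = replace(work[-1], end=hi + 1)
    blocks = []
    for iv in work:
        s, e = max(iv.start, lo), min(iv.end, hi + 1)
        if s < e:
            blocks.append(GenomicInterval(iv.chrom, s, e, strand))
    blocks.sort(key=lambda b: b.start)
    return blocks


def _advance_five(
    chain: Sequence[GenomicInterval], five: int, d: int, three: int, strand: str
) -> int:
    """Move the 5' end ``d`` transcript-nt toward the 3' end (spliced walk),
    clamping so that at least 20 nt of molecule remain."""
    blocks = _clip_chain(chain, five, three, strand)
    # transcript-ordered blocks from the 5' side
    ordered = blocks[::-1] if strand == "-" else blocks
    positions_left = sum(b.width for b in ordered)
    d = min(d, max(positions_left - 20, 0))
    for b in ordered:
        if d < b.width:
            return b.end - 1 - d if strand == "-" else b.start + d
        d -= b.width
    return three


def _sample_polya(rng: np.random.Generator, mode: float, log_sigma: float) -> float:
    mu = math.log(mode) + log_sigma**2
    return float(rng.lognormal(mu, log_sigma))


def _promoter_peaks(ann: LocusAnnotation, cls: str) -> list[CagePeak]:
    if cls in (CANONICAL_FL, CANONICAL_D2, NOVEL_CANONICAL):
        return ann.canonical_peaks
    return ann.alternative_peaks


def simulate_molecules(
    ann: LocusAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
    include_nonadenylated: bool = False,
) -> pd.DataFrame:
    """Draw a molecule population: class, TSS, 3' end, decay truncation, tail.

    Returns one row per molecule with the geometry needed to derive both DRS
    reads (adenylated molecules) and short-read coverage (all molecules).
    """
    if n <= 0:
        raise ValidationError("number of molecules must be positive")
    classes = list(config.class_weights)
    weights = np.array([config.class_weights[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    chains = {c: _class_chain(ann, c) for c in set(classes) | {NONADENYLATED_SHORT}}

    draws = list(rng.choice(len(classes), size=n, p=weights))
    specs = [(classes[i], True) for i in draws]
    if include_nonadenylated:
        n_alt_polya = sum(
            1 for cls, _ in specs if cls in (*LONG_CLASSES, SHORT_UPSTREAM)
        )
        n_nonpolya = int(round(config.nonadenylated_ratio * n_alt_polya))
        specs += [(NONADENYLATED_SHORT, False) for _ in range(n_nonpolya)]

    exon1 = ann.exon(1)
    rows = []
    for i, (cls, adenylated) in enumerate(specs):
        chain = chains[cls]
        peaks = _promoter_peaks(ann, cls)
        scores = np.array([p.score for p in peaks], dtype=float)
        peak = peaks[rng.choice(len(peaks), p=scores / scores.sum())]
        tss = peak.summit + int(round(rng.normal(0.0, config.tss_jitter_sd)))
        first = chain[0]
        tss = min(max(tss, first.start), first.end - 1)

        if cls == SHORT_UPSTREAM:
            length = int(rng.integers(*config.short_len_range))
            three = _downstream(tss, length, ann.strand)
            floor = exon1.end if ann.strand == "-" else exon1.start - 1
            three = max(three, floor + 1) if ann.strand == "-" else min(three, floor)
        elif cls == NONADENYLATED_SHORT:
            # ends between the promoters, short of the canonical region
            exon_m1 = ann.exon(-1)
            if ann.strand == "-":
                hi = tss - 100
                lo = exon_m1.end + 10
                three = int(rng.integers(lo, max(hi, lo + 1)))
            else:
                lo = tss + 100
                hi = exon_m1.start - 10
                three = int(rng.integers(min(lo, hi - 1), hi))
        else:
            offset = int(rng.integers(config.pas_jitter[0], config.pas_jitter[1] + 1))
            three = _downstream(ann.pas_position, offset, ann.strand)

        decayed = bool(rng.random() < config.decay_fraction)
        truncation = 0
        five = tss
        if decayed:
            truncation = int(rng.geometric(1.0 / config.decay_mean_nt))
            five = _advance_five(chain, tss, truncation, three, ann.strand)

        polya = (
            _sample_polya(
                rng,
                config.polya_mode_foxp3
                if cls in _FOXP3_LIKE
                else config.polya_mode_background,
                config.polya_log_sigma,
            )
            if adenylated
            else None
        )
        rows.append(
            {
                "molecule_id": i,
                "true_class": cls,
                "adenylated": adenylated,
                "peak_number": peak.peak_number,
                "tss": tss,
                "decayed": decayed,
                "truncation_nt": truncation,
                "five_prime": five,
                "three_prime": three,
                "polya_len": polya,
            }
        )
    return pd.DataFrame(rows)


def _molecule_blocks(
    ann: LocusAnnotation, row: pd.Series, five: Optional[int] = None
) -> list[GenomicInterval]:
    chain = _class_chain(ann, row["true_class"])
    return _clip_chain(
        chain,
        int(row["five_prime"] if five is None else five),
        int(row["three_prime"]),
        ann.strand,
    )


def reads_from_molecules(
    ann: LocusAnnotation,
    molecules: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    replicate_id: str = "rep1",
) -> tuple[list[LongRead], pd.DataFrame]:
    """DRS reads from the adenylated molecules: the sequencer drops the first
    5-15 transcript nt of each molecule's 5' end."""
    reads = []
    truth_rows = []
    lo, hi = config.tech_shift_range
    for _, row in molecules[molecules["adenylated"]].iterrows():
        chain = _class_chain(ann, row["true_class"])
        shift = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        five = _advance_five(
            chain, int(row["five_prime"]), shift, int(row["three_prime"]), ann.strand
        )
        blocks = _clip_chain(chain, five, int(row["three_prime"]), ann.strand)
        read_id = f"{replicate_id}_read{int(row['molecule_id'])}"
        reads.append(
            LongRead(
                read_id=read_id,
                strand=ann.strand,
                blocks=tuple(blocks),
                polya_len=row["polya_len"],
                replicate_id=replicate_id,
            )
        )
        truth = row.to_dict()
        truth.update(read_id=read_id, replicate_id=replicate_id, tech_shift=shift,
                     read_five_prime=five)
        truth_rows.append(truth)
    return reads, pd.DataFrame(truth_rows)


def simulate_drs_reads(
    ann: LocusAnnotation,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[list[LongRead], pd.DataFrame]:
    """A multi-replicate DRS read set plus its ground-truth table."""
    rng = np.random.default_rng(seed)
    all_reads: list[LongRead] = []
    truths = []
    for rep in range(1, config.n_replicates + 1):
        molecules = simulate_molecules(ann, config, rng, config.n_reads)
        reads, truth = reads_from_molecules(
            ann, molecules, config, rng, replicate_id=f"rep{rep}"
        )
        all_reads.extend(reads)
        truths.append(truth)
    return all_reads, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# short-read coverage
# ---------------------------------------------------------------------------


def coverage_from_molecules(
    ann: LocusAnnotation,
    molecules: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    span: Optional[GenomicInterval] = None,
) -> CoverageTrack:
    """Per-base coverage of the molecule population over the gene interval.

    ``tile`` mode: every molecule adds one count to each base it spans (the
    infinite-fragmentation limit).  ``sample`` mode draws finite fragments of
    fixed length uniformly along each molecule.
    """
    span = span or ann.gene_interval
    values = np.zeros(span.width, dtype=float)

    def add(s: int, e: int, w: float = 1.0) -> None:
        s, e = max(s, span.start), min(e, span.end)
        if s < e:
            values[s - span.start : e - span.start] += w

    if config.ngs_mode == "tile":
        for _, row in molecules.iterrows():
            for b in _molecule_blocks(ann, row):
                add(b.start, b.end)
    elif config.ngs_mode == "sample":
        if rng is None:
            raise ValidationError("sample mode requires an rng")
        frag = config.ngs_fragment_length
        for _, row in molecules.iterrows():
            blocks = _molecule_blocks(ann, row)
            tlen = sum(b.width for b in blocks)
            n_frags = rng.poisson(config.ngs_fragments_per_kb * tlen / 1000.0)
            if tlen <= frag:
                for _ in range(n_frags):
                    for b in blocks:
                        add(b.start, b.end)
                continue
            starts = rng.integers(0, tlen - frag + 1, size=n_frags)
            ordered = blocks[::-1] if ann.strand == "-" else blocks
            for t0 in starts:
                remaining, offset = frag, int(t0)
                for b in ordered:
                    if offset >= b.width:
                        offset -= b.width
                        continue
                    take = min(b.width - offset, remaining)
                    if ann.strand == "-":
                        add(b.end - offset - take, b.end - offset)
                    else:
                        add(b.start + offset, b.start + offset + take)
                    remaining -= take
                    offset = 0
                    if remaining == 0:
                        break
    else:
        raise ValidationError(f"unknown ngs_mode {config.ngs_mode!r}")
    return CoverageTrack(ann.chrom, span.start, values)


def simulate_ngs_coverage(
    ann: LocusAnnotation,
    config: SimulationConfig,
    seed: int = 0,
    molecules: Optional[pd.DataFrame] = None,
) -> tuple[CoverageTrack, pd.DataFrame]:
    """Short-read coverage of the full molecule population (poly(A)+ and
    non-adenylated upstream species at the configured ratio rho)."""
    rng = np.random.default_rng(seed)
    if molecules is None:
        molecules = simulate_molecules(
            ann, config, rng, config.ngs_molecules, include_nonadenylated=True
        )
    track = coverage_from_molecules(ann, molecules, config, rng)
    return track, molecules


def drs_coverage_from_reads(
    reads: Sequence[LongRead], span: GenomicInterval
) -> CoverageTrack:
    """Per-base pileup of aligned read blocks (for cross-technology anchors)."""
    values = np.zeros(span.width, dtype=float)
    for read in reads:
        for b in read.blocks:
            s, e = max(b.start, span.start), min(b.end, span.end)
            if s < e:
                values[s - span.start : e - span.start] += 1
    return CoverageTrack(span.chrom, span.start, values)


def simulate_dual_modality(
    ann: LocusAnnotation,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> dict:
    """One RNA sample measured with both technologies.

    A single molecule population (pooled-sample mixture, non-adenylated
    upstream species at rho) yields the DRS reads (adenylated molecules, with
    the 5' sequencing loss) and the short-read coverage track (all molecules).
    """
    if config is None:
        config = SimulationConfig(class_weights=dict(DUALMOD_CLASS_WEIGHTS))
    rng = np.random.default_rng(seed)
    molecules = simulate_molecules(
        ann, config, rng, config.ngs_molecules, include_nonadenylated=True
    )
    reads, truth = reads_from_molecules(ann, molecules, config, rng)
    track = coverage_from_molecules(ann, molecules, config, rng)
    return {
        "molecules": molecules,
        "reads": reads,
        "read_truth": truth,
        "ngs_track": track,
    }


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


@dataclass
class SimulatedField:
    image: FishImage
    cells: pd.DataFrame  # ground truth per cell
    spots: pd.DataFrame  # ground truth per planted spot


def _positive_count(rng: np.random.Generator, config: SimulationConfig, mean: float) -> int:
    extra = max(mean - 1.0, 0.0)
    if config.count_law == "poisson":
        return 1 + int(rng.poisson(extra))
    if config.count_law == "negbin":
        n = config.negbin_n
        p = n / (n + extra) if extra > 0 else 1.0
        return 1 + int(rng.negative_binomial(n, p))
    raise ValidationError(f"unknown count law {config.count_law!r}")


def _place_in_cell(
    rng: np.random.Generator,
    center: tuple[float, float],
    nucleus_r: float,
    expand_px: float,
    nuclear: bool,
    existing: list[tuple[float, float]],
    min_sep: float,
    shape: tuple[int, int],
) -> Optional[tuple[float, float]]:
    """A position in the nucleus disk or the cytoplasm ring respecting the
    minimum separation from existing spots, or None when the compartment is
    saturated - the spot is then not planted, keeping the truth table exact."""
    for _ in range(100):
        if nuclear:
            radius = (nucleus_r - 2.0) * math.sqrt(rng.random())
        else:
            r_in, r_out = nucleus_r + 3.0, nucleus_r + expand_px - 4.0
            radius = math.sqrt(rng.uniform(r_in**2, r_out**2))
        theta = rng.uniform(0, 2 * math.pi)
        r = center[0] + radius * math.sin(theta)
        c = center[1] + radius * math.cos(theta)
        if not (2 <= r < shape[0] - 2 and 2 <= c < shape[1] - 2):
            continue
        if all((r - er) ** 2 + (c - ec) ** 2 >= min_sep**2 for er, ec in existing):
            return (r, c)
    return None


def simulate_fish_images(
    config: SimulationConfig, seed: int = 0
) -> list[SimulatedField]:
    """Fields of cells with planted nuclei and per-channel diffraction-limited
    spots, plus full ground truth.

    Nuclei sit on a jittered grid whose spacing keeps expanded cells disjoint.
    Spots are Gaussian point-spread blobs; images carry Poisson shot noise
    plus Gaussian read noise, with the spot amplitude set by the configured
    SNR relative to the total background noise.
    """
    if config.n_cells_per_field <= 0:
        raise ValidationError("n_cells_per_field must be positive")
    rng = np.random.default_rng(seed)
    expand_px = round(config.cell_expand_um * 1000.0 / config.pixel_size_nm)
    spacing = int(2 * (config.nucleus_radius_px + 3 * config.nucleus_radius_sd + expand_px) + 5)
    margin = spacing // 2 + 2
    H, W = config.field_shape
    grid = [
        (float(r), float(c))
        for r in range(margin, H - margin, spacing)
        for c in range(margin, W - margin, spacing)
    ]
    if len(grid) < config.n_cells_per_field:
        raise ValidationError(
            f"field {config.field_shape} too small for {config.n_cells_per_field} cells"
        )

    amplitude = config.snr * math.sqrt(config.background + config.noise_sd**2)
    fields = []
    for field_idx in range(config.n_fields):
        order = rng.permutation(len(grid))[: config.n_cells_per_field]
        centers = [
            (
                grid[i][0] + rng.uniform(-4, 4),
                grid[i][1] + rng.uniform(-4, 4),
            )
            for i in order
        ]
        dapi = np.zeros((H, W))
        mrna_img = np.zeros((H, W))
        upa_img = np.zeros((H, W))
        cell_rows, spot_rows = [], []
        for cell_idx, center in enumerate(centers, start=1):
            nucleus_r = max(
                5.0, rng.normal(config.nucleus_radius_px, config.nucleus_radius_sd)
            )
            half = int(nucleus_r) + 3
            r0 = max(int(center[0]) - half, 0)
            r1 = min(int(center[0]) + half + 1, H)
            c0 = max(int(center[1]) - half, 0)
            c1 = min(int(center[1]) + half + 1, W)
            sub_r, sub_c = np.mgrid[r0:r1, c0:c1]
            dist2 = (sub_r - center[0]) ** 2 + (sub_c - center[1]) ** 2
            dapi[r0:r1, c0:c1][dist2 <= nucleus_r**2] += 180.0

            mrna_pts: list[tuple[float, float]] = []
            upa_pts: list[tuple[float, float]] = []
            n_mrna_wanted = (
                _positive_count(rng, config, config.mrna_mean)
                if rng.random() < config.mrna_positive_prob
                else 0
            )
            for _ in range(n_mrna_wanted):
                nuclear = rng.random() < config.nuclear_fraction
                pt = _place_in_cell(
                    rng, center, nucleus_r, expand_px, nuclear, mrna_pts,
                    config.min_spot_separation_px, (H, W),
                )
                if pt is None:
                    continue
                mrna_pts.append(pt)
                spot_rows.append(
                    {"field": field_idx, "cell": cell_idx, "channel": "mrna",
                     "r": pt[0], "c": pt[1], "nuclear": nuclear, "coloc": False}
                )
            n_upa_wanted = (
                _positive_count(rng, config, config.upa_mean)
                if rng.random() < config.upa_positive_prob
                else 0
            )
            free_targets = list(range(len(mrna_pts)))
            n_coloc = 0
            n_upa = 0
            for _ in range(n_upa_wanted):
                coloc = rng.random() < config.coloc_fraction
                if coloc:
                    if free_targets:
                        target = mrna_pts[free_targets.pop(int(rng.integers(len(free_targets))))]
                    else:
                        nuclear = rng.random() < config.nuclear_fraction
                        target = _place_in_cell(
                            rng, center, nucleus_r, expand_px, nuclear,
                            mrna_pts + upa_pts, config.min_spot_separation_px, (H, W),
                        )
                        if target is None:
                            continue
                        mrna_pts.append(target)
                        spot_rows.append(
                            {"field": field_idx, "cell": cell_idx, "channel": "mrna",
                             "r": target[0], "c": target[1], "nuclear": nuclear,
                             "coloc": False}
                        )
                    pt = (target[0] + rng.uniform(-0.7, 0.7),
                          target[1] + rng.uniform(-0.7, 0.7))
                    nuclear_spot = math.hypot(pt[0] - center[0], pt[1] - center[1]) <= nucleus_r
                    n_coloc += 1
                else:
                    nuclear_spot = rng.random() < config.nuclear_fraction
                    pt = _place_in_cell(
                        rng, center, nucleus_r, expand_px, nuclear_spot,
                        mrna_pts + upa_pts, config.min_spot_separation_px + 2.0, (H, W),
                    )
                    if pt is None:
                        continue
                upa_pts.append(pt)
                n_upa += 1
                spot_rows.append(
                    {"field": field_idx, "cell": cell_idx, "channel": "upa",
                     "r": pt[0], "c": pt[1], "nuclear": bool(nuclear_spot),
                     "coloc": coloc}
                )
            n_mrna = len(mrna_pts)
            cell_rows.append(
                {"field": field_idx, "cell": cell_idx,
                 "center_r": center[0], "center_c": center[1],
                 "nucleus_radius": nucleus_r, "n_mrna": n_mrna, "n_upa": n_upa,
                 "n_coloc": n_coloc, "mrna_positive": n_mrna > 0,
                 "upa_positive": n_upa > 0}
            )
            for pt_list, img in ((mrna_pts, mrna_img), (upa_pts, upa_img)):
                for (pr, pc) in pt_list:
                    r0, r1 = int(pr) - 6, int(pr) + 7
                    c0, c1 = int(pc) - 6, int(pc) + 7
                    r0, c0 = max(r0, 0), max(c0, 0)
                    r1, c1 = min(r1, H), min(c1, W)
                    sub_r, sub_c = np.mgrid[r0:r1, c0:c1]
                    img[r0:r1, c0:c1] += amplitude * np.exp(
                        -((sub_r - pr) ** 2 + (sub_c - pc) ** 2)
                        / (2 * config.spot_sigma_px**2)
                    )

        channels = {}
        for name, clean in (("dapi", dapi), ("mrna", mrna_img), ("upa", upa_img)):
            noisy = rng.poisson(np.clip(clean + config.background, 0, None)).astype(float)
            noisy += rng.normal(0.0, config.noise_sd, size=clean.shape)
            channels[name] = np.clip(noisy, 0, None)
        fields.append(
            SimulatedField(
                image=FishImage(channels, pixel_size_nm=config.pixel_size_nm),
                cells=pd.DataFrame(cell_rows),
                spots=pd.DataFrame(
                    spot_rows,
                    columns=["field", "cell", "channel", "r", "c", "nuclear", "coloc"],
                ),
            )
        )
    return fields


# ---------------------------------------------------------------------------
# presence/absence tables
# ---------------------------------------------------------------------------


def simulate_presence_table(
    config: SimulationConfig, seed: int = 0
) -> pd.DataFrame:
    """Long-format per-cell presence table from a planted logistic model."""
    if len(config.cell_type_logits) < 2:
        raise ValidationError("at least two cell types required")
    if len(config.donors) < 1:
        raise ValidationError("at least one donor required")
    rng = np.random.default_rng(seed)
    donors, types, present = [], [], []
    for donor in config.donors:
        delta = config.donor_effects.get(donor, 0.0)
        for cell_type, logit in config.cell_type_logits.items():
            p = 1.0 / (1.0 + math.exp(-(logit + delta)))
            draws = rng.random(config.n_cells_per_group) < p
            donors += [donor] * config.n_cells_per_group
            types += [cell_type] * config.n_cells_per_group
            present += [int(x) for x in draws]
    return presence_records(donors, types, present)
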