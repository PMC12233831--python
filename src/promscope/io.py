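"""Readers and writers for the formats the pipeline consumes and produces.

Coordinate conventions are handled at this boundary only: BED and bedGraph are
0-based half-open and read natively; paper-style spans and GTF-like records
are 1-based inclusive and converted on ingestion.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dualmod import CoverageTrack
from .fishquant import FishImage
from .intervals import GenomicInterval, ValidationError, parse_position_1based
from .locus import CagePeak, InitiationRegion, LocusAnnotation
from .orfscan import TranscriptSequence
from .reads import LongRead


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------


def load_reference() -> dict:
    """The shipped FOXP3 reference fixture: CAGE peaks, published initiation
    regions, the dual-modality worked counts, and per-donor speckle totals.

    Peaks and regions come back as domain objects (0-based half-open).
    """
    with resources.files("promscope.data").joinpath("foxp3_reference.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    strand = raw["strand"]
    peaks = []
    for rec in raw["cage_peaks"]:
        cluster = GenomicInterval.from_1based(rec["cluster"], strand)
        summit = parse_position_1based(rec["tss"].split(":")[1])
        peaks.append(
            CagePeak(
                cluster=cluster,
                summit=summit,
                score=float(rec["score"]),
                promoter_id=rec["promoter"],
                peak_number=int(rec["peak"]),
            )
        )
    regions = {}
    for name, rec in raw["initiation_regions"].items():
        promoter = name.split("_")[0]
        peak_number = int(name.rsplit("peak", 1)[1])
        source = next(
            p for p in peaks if p.promoter_id == promoter and p.peak_number == peak_number
        )
        regions[name] = {
            "region": InitiationRegion(
                GenomicInterval.from_1based(rec["span"], strand), source, promoter
            ),
            "ngs_coverage": float(rec["ngs_coverage"]),
        }
    raw["peaks"] = peaks
    raw["regions"] = regions
    raw["pas_min_three_prime"] = parse_position_1based(
        raw["pas_filter"]["min_three_prime"].split(":")[1]
    )
    return raw


# ---------------------------------------------------------------------------
# locus YAML
# ---------------------------------------------------------------------------


def _iv_to_list(iv: GenomicInterval) -> list[int]:
    return [int(iv.start), int(iv.end)]


def locus_to_dict(ann: LocusAnnotation) -> dict:
    def peak_dict(p: CagePeak) -> dict:
        return {
            "peak": p.peak_number,
            "cluster": _iv_to_list(p.cluster),
            "summit": p.summit,
            "score": p.score,
            "sigma": p.sigma,
        }

    return {
        "chrom": ann.chrom,
        "strand": ann.strand,
        "chrom_length": ann.chrom_length,
        "gene_interval": _iv_to_list(ann.gene_interval),
        "exons": [[num, iv.start, iv.end] for num, iv in ann.exons],
        "cds_exons": sorted(ann.cds_exons),
        "pas_position": ann.pas_position,
        "pas_min_3prime": ann.pas_min_3prime,
        "canonical_peaks": [peak_dict(p) for p in ann.canonical_peaks],
        "alternative_peaks": [peak_dict(p) for p in ann.alternative_peaks],
        "neighbor_promoter": _iv_to_list(ann.neighbor_promoter),
        "allowed_splice_patterns": [sorted(s) for s in ann.allowed_splice_patterns],
        "alt_first_exon_variants": [_iv_to_list(iv) for iv in ann.alt_first_exon_variants],
        "extended_first_exon": (
            _iv_to_list(ann.extended_first_exon)
            if ann.extended_first_exon is not None
            else None
        ),
    }


def locus_from_dict(data: dict) -> LocusAnnotation:
    chrom, strand = data["chrom"], data["strand"]

    def iv(pair: Sequence[int]) -> GenomicInterval:
        return GenomicInterval(chrom, int(pair[0]), int(pair[1]), strand)

    def peaks(records: Iterable[dict], promoter: str) -> list[CagePeak]:
        return [
            CagePeak(
                cluster=iv(rec["cluster"]),
                summit=int(rec["summit"]),
                score=float(rec["score"]),
                promoter_id=promoter,
                peak_number=int(rec["peak"]),
                sigma=rec.get("sigma"),
            )
            for rec in records
        ]

    return LocusAnnotation(
        chrom=chrom,
        strand=strand,
        chrom_length=int(data["chrom_length"]),
        gene_interval=iv(data["gene_interval"]),
        exons=[(int(num), iv([s, e])) for num, s, e in data["exons"]],
        cds_exons=set(data["cds_exons"]),
        pas_position=int(data["pas_position"]),
        pas_min_3prime=int(data["pas_min_3prime"]),
        canonical_peaks=peaks(data["canonical_peaks"], "canonical"),
        alternative_peaks=peaks(data["alternative_peaks"], "alternative"),
        neighbor_promoter=iv(data["neighbor_promoter"]),
        allowed_splice_patterns={
            frozenset(s) for s in data["allowed_splice_patterns"]
        },
        alt_first_exon_variants=[iv(p) for p in data["alt_first_exon_variants"]],
        extended_first_exon=(
            iv(data["extended_first_exon"])
            if data.get("extended_first_exon") is not None
            else None
        ),
    )


def save_locus(ann: LocusAnnotation, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(locus_to_dict(ann), sort_keys=False))


def load_locus(path: str | Path) -> LocusAnnotation:
    return locus_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# CAGE peaks: BED6 + summit + sigma
# ---------------------------------------------------------------------------


def save_cage_peaks(peaks: Sequence[CagePeak], path: str | Path) -> None:
    """BED6+2: name = promoter:peak_number, score, strand, summit, sigma."""
    lines = []
    for p in peaks:
        sigma = "" if p.sigma is None else f"{p.sigma:g}"
        lines.append(
            "\t".join(
                [
                    p.cluster.chrom,
                    str(p.cluster.start),
                    str(p.cluster.end),
                    f"{p.promoter_id}:{p.peak_number}",
                    f"{p.score:g}",
                    p.cluster.strand,
                    str(p.summit),
                    sigma,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_cage_peaks(path: str | Path) -> list[CagePeak]:
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 7:
            raise ParseError(f"{path}:{lineno}: expected >= 7 BED fields")
        try:
            promoter, number = fields[3].split(":")
            sigma = float(fields[7]) if len(fields) > 7 and fields[7] != "" else None
            peaks.append(
                CagePeak(
                    cluster=GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2]), fields[5]
                    ),
                    summit=int(fields[6]),
                    score=float(fields[4]),
                    promoter_id=promoter,
                    peak_number=int(number),
                    sigma=sigma,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


# ---------------------------------------------------------------------------
# long reads: TSV and BAM/SAM
# ---------------------------------------------------------------------------

READS_TSV_COLUMNS = ["read_id", "strand", "blocks", "polya_len", "replicate_id"]


def save_reads_tsv(reads: Sequence[LongRead], path: str | Path) -> None:
    """Documented tabular equivalent of a BAM: one row per read, blocks as
    comma-separated 0-based half-open start-end pairs."""
    rows = []
    for read in reads:
        rows.append(
            {
                "read_id": read.read_id,
                "strand": read.strand,
                "blocks": ",".join(f"{b.start}-{b.end}" for b in read.blocks),
                "polya_len": "" if read.polya_len is None else f"{read.polya_len:.2f}",
                "replicate_id": read.replicate_id,
                "chrom": read.blocks[0].chrom,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reads_tsv(path: str | Path) -> list[LongRead]:
    df = pd.read_csv(path, sep="\t", dtype={"polya_len": str}, keep_default_na=False)
    reads = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            chrom = getattr(row, "chrom", "chr?")
            blocks = tuple(
                GenomicInterval(chrom, int(pair.split("-")[0]), int(pair.split("-")[1]), row.strand)
                for pair in row.blocks.split(",")
            )
            polya = float(row.polya_len) if row.polya_len not in ("", "nan") else None
            reads.append(
                LongRead(
                    read_id=str(row.read_id),
                    strand=row.strand,
                    blocks=blocks,
                    polya_len=polya,
                    replicate_id=str(row.replicate_id),
                )
            )
        except (ValueError, ValidationError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return reads


def load_reads_bam(
    path: str | Path,
    region: Optional[GenomicInterval] = None,
    replicate_id: Optional[str] = None,
    polya_tag: str = "pt",
    min_intron: int = 30,
) -> list[LongRead]:
    """Primary alignments from a BAM/SAM file as LongRead records.

    Adjacent aligned blocks separated by gaps shorter than ``min_intron``
    (indels) are merged; only gaps of at least that size count as introns.
    """
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    reads = []
    rep = replicate_id if replicate_id is not None else Path(path).stem
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        iterator = (
            bam.fetch(region.chrom, region.start, region.end)
            if region is not None and bam.has_index()
            else bam
        )
        for aln in iterator:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            raw = aln.get_blocks()
            if not raw:
                continue
            merged: list[list[int]] = [list(raw[0])]
            for s, e in raw[1:]:
                if s - merged[-1][1] < min_intron:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            strand = "-" if aln.is_reverse else "+"
            polya = None
            if aln.has_tag(polya_tag):
                polya = float(aln.get_tag(polya_tag))
            reads.append(
                LongRead(
                    read_id=aln.query_name,
                    strand=strand,
                    blocks=tuple(
                        GenomicInterval(aln.reference_name, s, e, strand)
                        for s, e in merged
                    ),
                    polya_len=polya,
                    replicate_id=rep,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


def save_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    lines = []
    values = track.values
    run_start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[run_start]:
            lines.append(
                f"{track.chrom}\t{track.start + run_start}\t{track.start + i}\t"
                f"{values[run_start]:g}"
            )
            run_start = i
    Path(path).write_text("\n".join(lines) + "\n")


def load_bedgraph(path: str | Path, chrom: Optional[str] = None) -> CoverageTrack:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: malformed bedGraph ({exc})") from exc
    if df.empty:
        raise ParseError(f"{path}: empty bedGraph")
    if chrom is None:
        chrom = df["chrom"].iloc[0]
    df = df[df["chrom"] == chrom]
    start, end = int(df["start"].min()), int(df["end"].max())
    values = np.zeros(end - start, dtype=float)
    for row in df.itertuples(index=False):
        values[int(row.start) - start : int(row.end) - start] = float(row.value)
    return CoverageTrack(chrom, start, values)


# ---------------------------------------------------------------------------
# FASTA, TIFF, JSON
# ---------------------------------------------------------------------------


def save_transcripts_fasta(
    transcripts: dict[str, TranscriptSequence], path: str | Path
) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(ts.sequence),
            id=name,
            description=f"main_start={ts.main_start} splice={ts.splice_signature}",
        )
        for name, ts in transcripts.items()
    ]
    seqio_write(records, str(path), "fasta")


def load_transcripts_fasta(path: str | Path) -> dict[str, TranscriptSequence]:
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        main_start = None
        splice = "fl"
        for token in rec.description.split():
            if token.startswith("main_start="):
                value = token.split("=", 1)[1]
                main_start = None if value == "None" else int(value)
            elif token.startswith("splice="):
                splice = token.split("=", 1)[1]
        out[rec.id] = TranscriptSequence(
            rec.id, str(rec.seq), main_start=main_start,
            utr5_end=main_start, splice_signature=splice,
        )
    return out


CHANNEL_ORDER = ("dapi", "mrna", "upa")


def save_fish_image(image: FishImage, path: str | Path) -> None:
    import tifffile

    stack = np.stack([image.channels[ch] for ch in CHANNEL_ORDER]).astype(np.float32)
    tifffile.imwrite(
        str(path), stack, photometric="minisblack", metadata={"axes": "CYX"}
    )


def load_fish_image(
    path: str | Path,
    channel_order: Sequence[str] = CHANNEL_ORDER,
    pixel_size_nm: float = 104.0,
) -> FishImage:
    import tifffile

    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(channel_order):
        raise ParseError(
            f"{path}: expected {len(channel_order)} channels, found {stack.shape[0]}"
        )
    return FishImage(
        {ch: stack[i].astype(float) for i, ch in enumerate(channel_order)},
        pixel_size_nm=pixel_size_nm,
    )


def save_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
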