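"""Filtering and classification of aligned direct-RNA-sequencing reads.

Reads are filtered with four ordered rules before classification:

(i)   reads whose 5' end maps to the neighbouring gene's promoter are removed;
(ii)  reads whose 5' end maps outside every region of probable transcription
      initiation are interpreted as decay products or aborted sequencing and
      removed;
(iii) reads whose 3'-most nucleotide stops transcription-side of a threshold
      50 nt short of the annotated PAS are removed (truncated 3'-UTR);
(iv)  reads whose splice-junction chain matches no whitelisted transcript
      structure are removed (incomplete/incorrect ORF, immature transcripts).

Short upstream transcripts - alternative-promoter reads that terminate before
reaching the first coding exon - are exempt from rules (iii)/(iv), which they
would violate by definition, but remain subject to (i)/(ii).

The first violated rule is the one recorded, so a read violating both (i) and
(iii) reports (i).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .intervals import GenomicInterval, ValidationError
from .locus import (
    ALTERNATIVE,
    CANONICAL,
    InitiationRegion,
    LocusAnnotation,
    assign_five_prime,
    validate_regions,
)

# classification labels
CANONICAL_FL = "canonical_fl"
CANONICAL_D2 = "canonical_d2"
NOVEL_CANONICAL = "novel_canonical"
LONG_FL = "longFOXP3_fl"
LONG_D2 = "longFOXP3_d2"
LONG_MINOR = "longFOXP3_minor"
SHORT_UPSTREAM = "short_upstream"
EXCLUDED = "excluded"

CLASS_LABELS = (
    CANONICAL_FL,
    CANONICAL_D2,
    NOVEL_CANONICAL,
    LONG_FL,
    LONG_D2,
    LONG_MINOR,
    SHORT_UPSTREAM,
)

CANONICAL_CLASSES = (CANONICAL_FL, CANONICAL_D2)
LONG_CLASSES = (LONG_FL, LONG_D2, LONG_MINOR)

# exclusion reasons, in rule order
REASON_NEIGHBOR = "neighbor_promoter"
REASON_OUTSIDE = "outside_init_region"
REASON_SHORT_3UTR = "short_3utr"
REASON_ABERRANT = "aberrant_structure"
REASON_NONE = "none"


@dataclass(frozen=True)
class LongRead:
    """One aligned long read: ordered aligned blocks plus optional poly(A) length."""

    read_id: str
    strand: str
    blocks: tuple[GenomicInterval, ...]
    polya_len: Optional[float] = None
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError(f"read {self.read_id} has zero blocks")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"read {self.read_id}: blocks overlap or are unordered"
                )
        if self.polya_len is not None and self.polya_len < 0:
            raise ValidationError("polya_len must be non-negative")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.blocks[0].chrom,
            self.blocks[0].start,
            self.blocks[-1].end,
            self.strand,
        )

    @property
    def five_prime(self) -> int:
        """Genomic position of the transcription-start-side terminal base."""
        if self.strand == "-":
            return self.blocks[-1].end - 1
        return self.blocks[0].start

    @property
    def three_prime(self) -> int:
        """Genomic position of the PAS-side terminal base."""
        if self.strand == "-":
            return self.blocks[0].start
        return self.blocks[-1].end - 1

    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Implied introns: half-open gaps between consecutive blocks."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])
        )


@dataclass(frozen=True)
class ReadClass:
    label: str
    exclusion_reason: str = REASON_NONE

    def __post_init__(self) -> None:
        if (self.exclusion_reason == REASON_NONE) != (self.label != EXCLUDED):
            raise ValidationError(
                "exclusion_reason must be 'none' exactly when the read is not excluded"
            )

    @property
    def excluded(self) -> bool:
        return self.label == EXCLUDED


@dataclass(frozen=True)
class _TranscriptModel:
    """A whitelisted exon chain: first-exon structure x skip signature."""

    structure: str  # "canonical", "extended", or "variant<i>"
    signature: frozenset[int]
    exons: tuple[GenomicInterval, ...]  # transcription order
    junctions: tuple[tuple[int, int], ...]  # genomic order (by start)
    first_exon: GenomicInterval


def _chain_junctions(exons: Sequence[GenomicInterval]) -> tuple[tuple[int, int], ...]:
    ordered = sorted(exons, key=lambda iv: iv.start)
    return tuple((a.end, b.start) for a, b in zip(ordered, ordered[1:]))


class ReadClassifier:
    """Applies the filter rules (i)-(iv) and the promoter/isoform assignment.

    Parameters
    ----------
    ann : LocusAnnotation
    regions : initiation regions; default built from the annotation's peaks
        with the standard broadening (5 sigma) and technology shift (10 nt).
    junction_slack : permitted +/- nt mismatch per junction edge (default 0:
        exact junction matching).
    novel_overlap_frac : minimum fraction of a read's 5' block that must
        overlap an alternate first-exon variant for the read to count as a
        novel canonical-promoter transcript.
    """

    def __init__(
        self,
        ann: LocusAnnotation,
        regions: Optional[Sequence[InitiationRegion]] = None,
        junction_slack: int = 0,
        novel_overlap_frac: float = 0.5,
    ) -> None:
        self.ann = ann
        if regions is None:
            regions = ann.initiation_regions()
        else:
            validate_regions(regions)
        self.regions = list(regions)
        self.junction_slack = int(junction_slack)
        self.novel_overlap_frac = float(novel_overlap_frac)
        self._models = self._build_models()
        # transcription-upstream edge of the first coding-region exon (exon 1):
        # a read that never reaches it is a short upstream transcript.
        exon1 = ann.exon(1)
        self._exon1_entry = exon1.end - 1 if ann.strand == "-" else exon1.start

    # -- model construction -------------------------------------------------
    def _build_models(self) -> list[_TranscriptModel]:
        ann = self.ann
        body = [iv for num, iv in ann.exons if num != -1]
        body_nums = [num for num, _ in ann.exons if num != -1]
        firsts: list[tuple[str, GenomicInterval, set[frozenset[int]]]] = []
        canonical_sigs = {
            sig for sig in ann.allowed_splice_patterns if sig <= {2}
        }
        firsts.append(("canonical", ann.exon(-1), canonical_sigs))
        for i, iv in enumerate(ann.alt_first_exon_variants):
            firsts.append((f"variant{i}", iv, canonical_sigs))
        if ann.extended_first_exon is not None:
            firsts.append(
                ("extended", ann.extended_first_exon, set(ann.allowed_splice_patterns))
            )
        models = []
        for structure, first, sigs in firsts:
            for sig in sigs:
                exons = [first] + [
                    iv for num, iv in zip(body_nums, body) if num not in sig
                ]
                models.append(
                    _TranscriptModel(
                        structure=structure,
                        signature=sig,
                        exons=tuple(exons),
                        junctions=_chain_junctions(exons),
                        first_exon=first,
                    )
                )
        return models

    # -- junction matching --------------------------------------------------
    def _matches(self, read: LongRead, model: _TranscriptModel) -> bool:
        """Exact (slack-tolerant) equality of the read's junction chain with the
        model's junctions restricted to the read's genomic span."""
        lo, hi = read.span.start, read.span.end
        expected = [j for j in model.junctions if lo < j[0] and j[1] < hi]
        observed = list(read.junctions())
        if len(expected) != len(observed):
            return False
        s = self.junction_slack
        return all(
            abs(o[0] - e[0]) <= s and abs(o[1] - e[1]) <= s
            for o, e in zip(observed, expected)
        )

    def _matching_models(
        self, read: LongRead, promoter: str
    ) -> list[_TranscriptModel]:
        """Whitelisted models compatible with the read, restricted by promoter.

        The paper describes the minor skip signatures ({7}, {2,7}) only for
        longFOXP3, so the canonical promoter admits only the {}, {2} chains.
        """
        if promoter == CANONICAL:
            candidates = [m for m in self._models if m.signature <= {2}]
        else:
            candidates = self._models
        return [m for m in candidates if self._matches(read, m)]

    # -- the ordered rules --------------------------------------------------
    def filter_read(self, read: LongRead) -> Optional[str]:
        """Return the first violated rule's exclusion reason, or None if the
        read survives filtering."""
        reason, _promoter = self._apply_rules(read)
        return reason

    def _apply_rules(
        self, read: LongRead
    ) -> tuple[Optional[str], Optional[str]]:
        if read.strand != self.ann.strand:
            return REASON_ABERRANT, None
        five = read.five_prime
        if self.ann.neighbor_promoter.contains(five):  # rule (i)
            return REASON_NEIGHBOR, None
        promoter = assign_five_prime(five, self.regions)
        if promoter is None:  # rule (ii)
            return REASON_OUTSIDE, None
        if self._is_short_upstream(read, promoter):
            return None, promoter  # exempt from (iii)/(iv)
        if self.ann.upstream_of(read.three_prime, self.ann.pas_min_3prime):
            return REASON_SHORT_3UTR, promoter  # rule (iii)
        if not self._matching_models(read, promoter):  # rule (iv)
            return REASON_ABERRANT, promoter
        return None, promoter

    def _is_short_upstream(self, read: LongRead, promoter: str) -> bool:
        if promoter != ALTERNATIVE:
            return False
        # never entered exon 1: 3' end strictly transcription-upstream of it
        return self.ann.upstream_of(read.three_prime, self._exon1_entry)

    # -- classification -----------------------------------------------------
    def classify_read(self, read: LongRead) -> ReadClass:
        reason, promoter = self._apply_rules(read)
        if reason is not None:
            return ReadClass(EXCLUDED, reason)
        if promoter == ALTERNATIVE:
            if self._is_short_upstream(read, promoter):
                return ReadClass(SHORT_UPSTREAM)
            sig = self._long_signature(read, promoter)
            if sig == frozenset():
                return ReadClass(LONG_FL)
            if sig == frozenset({2}):
                return ReadClass(LONG_D2)
            return ReadClass(LONG_MINOR)
        if promoter == CANONICAL:
            models = self._matching_models(read, promoter)
            canonical = [m for m in models if m.structure == "canonical"]
            if canonical:
                sig = min(canonical, key=lambda m: len(m.signature)).signature
                return ReadClass(CANONICAL_D2 if 2 in sig else CANONICAL_FL)
            variants = [m for m in models if m.structure.startswith("variant")]
            for m in variants:
                five_block = (
                    read.blocks[-1] if read.strand == "-" else read.blocks[0]
                )
                if (
                    five_block.overlap_length(m.first_exon)
                    >= self.novel_overlap_frac * five_block.width
                ):
                    return ReadClass(NOVEL_CANONICAL)
            # extended structure shares the exon -1 donor; a canonical-promoter
            # read matching only it is structurally canonical
            extended = [m for m in models if m.structure == "extended"]
            if extended:
                sig = min(extended, key=lambda m: len(m.signature)).signature
                return ReadClass(CANONICAL_D2 if 2 in sig else CANONICAL_FL)
        raise RuntimeError(
            f"read {read.read_id} survived filtering but matches no promoter/structure"
        )

    def _long_signature(self, read: LongRead, promoter: str) -> frozenset[int]:
        models = self._matching_models(read, promoter)
        ext = [m for m in models if m.structure == "extended"]
        if not ext:
            # canonical structure junctions are a subset of extended ones
            ext = [m for m in models if m.structure == "canonical"]
        if not ext:
            raise RuntimeError(f"read {read.read_id}: no matching structure")
        # ambiguous (5'-truncated) reads take the least-skipped signature
        return min(ext, key=lambda m: len(m.signature)).signature

    # -- vectorised convenience ---------------------------------------------
    def classify_reads(self, reads: Iterable[LongRead]) -> pd.DataFrame:
        """One row per read: identity, geometry, label and exclusion reason."""
        rows = []
        for read in reads:
            rc = self.classify_read(read)
            rows.append(
                {
                    "read_id": read.read_id,
                    "replicate_id": read.replicate_id,
                    "five_prime": read.five_prime,
                    "three_prime": read.three_prime,
                    "span_start": read.span.start,
                    "span_end": read.span.end,
                    "polya_len": read.polya_len,
                    "label": rc.label,
                    "exclusion_reason": rc.exclusion_reason,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "read_id",
                "replicate_id",
                "five_prime",
                "three_prime",
                "span_start",
                "span_end",
                "polya_len",
                "label",
                "exclusion_reason",
            ],
        )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class AbundanceReport:
    counts: pd.DataFrame  # replicate x class counts (non-excluded classes)
    ratios: pd.DataFrame  # per-replicate abundance ratios (NaN = undefined)
    medians: dict[str, float]  # cross-replicate medians of the ratios
    promoter_output_ratio: float  # pooled canonical:alternative output
    n_excluded: int
    flags: list[str] = field(default_factory=list)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def abundance_report(classified: pd.DataFrame) -> AbundanceReport:
    """Per-replicate class counts and abundance ratios with cross-replicate medians.

    Ratios use the canonical classes (fl + d2) as the numerator base.  Ratios
    with a zero denominator are flagged undefined (NaN), never infinite; the
    median of an even number of replicate ratios is the mean of the central
    pair (numpy convention).
    """
    kept = classified[classified["label"] != EXCLUDED]
    counts = (
        kept.groupby(["replicate_id", "label"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=list(CLASS_LABELS), fill_value=0)
    if counts.empty:
        raise ValidationError("no classified reads: at least one replicate required")

    flags: list[str] = []
    rows = {}
    for rep, row in counts.iterrows():
        canonical = row[CANONICAL_FL] + row[CANONICAL_D2]
        long_total = sum(row[c] for c in LONG_CLASSES)
        if canonical == 0:
            flags.append(f"replicate {rep}: zero canonical reads, ratios undefined")
            rows[rep] = {
                "canonical_to_novel": float("nan"),
                "canonical_to_long": float("nan"),
                "canonical_to_short": float("nan"),
            }
            continue
        rows[rep] = {
            "canonical_to_novel": _safe_ratio(canonical, row[NOVEL_CANONICAL]),
            "canonical_to_long": _safe_ratio(canonical, long_total),
            "canonical_to_short": _safe_ratio(canonical, row[SHORT_UPSTREAM]),
        }
    ratios = pd.DataFrame.from_dict(rows, orient="index")
    medians = {
        col: float(np.nanmedian(ratios[col])) if ratios[col].notna().any() else float("nan")
        for col in ratios.columns
    }

    pooled = counts.sum(axis=0)
    num = pooled[CANONICAL_FL] + pooled[CANONICAL_D2] + pooled[NOVEL_CANONICAL]
    den = sum(pooled[c] for c in LONG_CLASSES) + pooled[SHORT_UPSTREAM]
    por = _safe_ratio(float(num), float(den))
    if not np.isfinite(por):
        flags.append("promoter output ratio undefined (no alternative-promoter reads)")
    return AbundanceReport(
        counts=counts,
        ratios=ratios,
        medians=medians,
        promoter_output_ratio=por,
        n_excluded=int((classified["label"] == EXCLUDED).sum()),
        flags=flags,
    )


def splice_fractions(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate fractions of longFOXP3 reads over {fl, d2, minor}.

    Adds a cross-replicate arithmetic-mean row ``mean``; replicates without
    any longFOXP3 read are excluded from the mean (undefined fractions).
    """
    long_reads = classified[classified["label"].isin(LONG_CLASSES)]
    if long_reads.empty:
        raise ValidationError("no longFOXP3 reads: splice fractions undefined")
    counts = (
        long_reads.groupby(["replicate_id", "label"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=list(LONG_CLASSES), fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions.columns = ["fl", "d2", "minor"]
    fractions.loc["mean"] = fractions.mean(axis=0)
    return fractions


def cleavage_offsets(
    classified: pd.DataFrame, ann: LocusAnnotation, window: int = 10
) -> tuple[pd.Series, pd.DataFrame]:
    """Signed offset of each non-excluded read's 3' end from the PAS.

    Offsets are signed in the direction of transcription: +2 means the read
    ran 2 nt further than the annotated cleavage site.  The histogram covers
    ``[-window, +window]`` with two overflow bins.
    """
    kept = classified[classified["label"] != EXCLUDED]
    sign = -1 if ann.strand == "+" else 1
    offsets = sign * (ann.pas_position - kept["three_prime"].astype(int))
    offsets.name = "cleavage_offset"
    bins = list(range(-window, window + 1))
    hist_counts = {b: int((offsets == b).sum()) for b in bins}
    under = int((offsets < -window).sum())
    over = int((offsets > window).sum())
    hist = pd.DataFrame(
        {
            "offset": [f"<{-window}"] + bins + [f">{window}"],
            "count": [under] + [hist_counts[b] for b in bins] + [over],
        }
    )
    return offsets, hist


@dataclass
class PolyAGroupStats:
    n: int
    mean: float
    median: float
    mode: float  # mode of integer-rounded lengths; ties -> smallest


@dataclass
class PolyAComparison:
    groups: dict[str, PolyAGroupStats]
    u_statistic: Optional[float]
    p_value: Optional[float]
    flags: list[str]


def _modal_length(lengths: np.ndarray) -> float:
    rounded = np.round(lengths).astype(int)
    values, freq = np.unique(rounded, return_counts=True)
    return float(values[freq == freq.max()].min())


def polya_stats(
    lengths_by_group: dict[str, Sequence[float]],
    compare: Optional[tuple[str, str]] = None,
) -> PolyAComparison:
    """Mean/median/modal poly(A) tail length per group plus an optional
    two-sided Mann-Whitney rank-sum comparison of two groups."""
    stats: dict[str, PolyAGroupStats] = {}
    flags: list[str] = []
    for name, lengths in lengths_by_group.items():
        arr = np.asarray([x for x in lengths if x is not None], dtype=float)
        if arr.size == 0:
            flags.append(f"group {name}: no tail lengths, statistics undefined")
            stats[name] = PolyAGroupStats(0, float("nan"), float("nan"), float("nan"))
            continue
        stats[name] = PolyAGroupStats(
            n=int(arr.size),
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            mode=_modal_length(arr),
        )
    u = p = None
    if compare is not None:
        a, b = compare
        xa = np.asarray(list(lengths_by_group[a]), dtype=float)
        xb = np.asarray(list(lengths_by_group[b]), dtype=float)
        if xa.size == 0 or xb.size == 0:
            flags.append("comparison undefined: a group is empty")
        else:
            method = "exact" if (xa.size + xb.size) <= 20 and _no_ties(xa, xb) else "asymptotic"
            res = _sstats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
    return PolyAComparison(groups=stats, u_statistic=u, p_value=p, flags=flags)


def _no_ties(a: np.ndarray, b: np.ndarray) -> bool:
    combined = np.concatenate([a, b])
    return np.unique(combined).size == combined.size
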