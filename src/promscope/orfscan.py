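"""ORF/uORF scanning, Kozak-context scoring and proteoform enumeration.

The scanner searches a transcript (RNA alphabet) for open reading frames that
start at AUG or CUG and terminate at the first in-frame stop, keeping those of
a minimum total length (150 nt including the stop, by default).  Each start is
annotated with a Kozak-context score from an internal position-weight model of
the vertebrate consensus (gccRccAUGG), in which the purine at -3 and the G at
+4 dominate.  Proteoform enumeration then partitions the hits of a transcript
with a known main start into the main proteoform, N-terminally extended
proteoforms (in-frame upstream starts sharing the main stop) and uORFs.

Molecular weights use average (not monoisotopic) residue masses, matching
kDa-scale gel comparisons.  Near-cognate (CUG) starts are translated with an
initiator methionine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data.IUPACData import protein_weights
from Bio.Seq import Seq

from .intervals import ValidationError

START_CODONS = frozenset({"AUG", "CUG"})
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
RNA_ALPHABET = frozenset("ACGU")
WATER_DA = 18.0153

MAIN_PROTEOFORM = "main_proteoform"
N_EXTENDED = "n_extended_proteoform"
UORF = "uORF"


@dataclass(frozen=True)
class TranscriptSequence:
    """A transcript in RNA alphabet with optional annotation of its main start."""

    name: str
    sequence: str
    main_start: Optional[int] = None  # offset of the annotated main start codon
    utr5_end: Optional[int] = None  # offset of the first CDS base (5'-UTR boundary)
    splice_signature: str = "fl"  # {"fl", "d2"}

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValidationError(f"invalid RNA letters {sorted(bad)} in {self.name}")
        for offset in (self.main_start, self.utr5_end):
            if offset is not None and not (0 <= offset <= len(seq)):
                raise ValidationError(f"offset {offset} outside sequence {self.name}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfRecord:
    start_offset: int
    start_codon: str
    kozak_score: float
    length_nt: int  # including the stop codon
    length_aa: int
    mw_kda: float
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_nt % 3 != 0:
            raise ValidationError("ORF length must be divisible by 3")
        if self.length_aa != self.length_nt // 3 - 1:
            raise ValidationError("length_aa inconsistent with length_nt")

    @property
    def stop_offset(self) -> int:
        """Offset of the first base of the stop codon."""
        return self.start_offset + self.length_nt - 3


# ---------------------------------------------------------------------------
# Kozak position-weight model
# ---------------------------------------------------------------------------

# preferences per context position (consensus gccRccAUGG); consensus base -> 1.0,
# N or out-of-sequence -> 0.0.  Positions -3 and +4 carry the dominant weights.
_KOZAK_PREFS: dict[int, dict[str, float]] = {
    -6: {"G": 1.0, "A": 0.5, "C": 0.4, "U": 0.3},
    -5: {"C": 1.0, "A": 0.4, "G": 0.4, "U": 0.3},
    -4: {"C": 1.0, "A": 0.5, "G": 0.4, "U": 0.3},
    -3: {"G": 1.0, "A": 0.9, "C": 0.15, "U": 0.1},
    -2: {"C": 1.0, "A": 0.5, "G": 0.4, "U": 0.3},
    -1: {"C": 1.0, "A": 0.5, "G": 0.4, "U": 0.35},
    +3: {"G": 1.0, "A": 0.3, "C": 0.25, "U": 0.2},  # the "+4" base, first after the codon
}
_KOZAK_WEIGHTS: dict[int, float] = {
    -6: 1.0,
    -5: 1.0,
    -4: 1.0,
    -3: 3.0,
    -2: 1.0,
    -1: 1.0,
    +3: 2.0,
}


def kozak_score(sequence: str, start_offset: int) -> float:
    """Position-weight similarity of a start's 10-base context to the consensus.

    Normalised so the consensus context (GCCGCCAUGG) scores 1.0 and an all-N
    (or out-of-sequence) context scores 0.0.  Deterministic; positions outside
    the sequence contribute 0.
    """
    seq = sequence.upper().replace("T", "U")
    total = 0.0
    for rel, weight in _KOZAK_WEIGHTS.items():
        pos = start_offset + rel
        base = seq[pos] if 0 <= pos < len(seq) else "N"
        total += weight * _KOZAK_PREFS[rel].get(base, 0.0)
    return total / sum(_KOZAK_WEIGHTS.values())


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------


def _first_inframe_stop(seq: str, start: int) -> Optional[int]:
    for pos in range(start + 3, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def _make_record(seq: str, start: int, stop: int) -> OrfRecord:
    length_nt = stop + 3 - start
    aa = translate_orf(seq[start : stop + 3])
    return OrfRecord(
        start_offset=start,
        start_codon=seq[start : start + 3],
        kozak_score=kozak_score(seq, start),
        length_nt=length_nt,
        length_aa=length_nt // 3 - 1,
        mw_kda=protein_mw(aa),
    )


def find_orfs(
    seq: TranscriptSequence | str,
    starts: Sequence[str] = ("AUG", "CUG"),
    min_len_nt: int = 150,
    region: Optional[tuple[int, int]] = None,
) -> list[OrfRecord]:
    """All ORFs starting at the given codons, in 5'->3' order of their starts.

    An ORF runs from its start codon to the first in-frame stop; candidates
    without an in-frame stop are excluded.  ``min_len_nt`` counts the stop
    codon.  ``region`` restricts the *start* positions scanned.
    """
    if min_len_nt < 6 or min_len_nt % 3 != 0:
        raise ValidationError("min_len_nt must be >= 6 and divisible by 3")
    start_set = {s.upper().replace("T", "U") for s in starts}
    if not start_set <= START_CODONS:
        raise ValidationError(f"unsupported start codons {start_set - START_CODONS}")
    ts = seq if isinstance(seq, TranscriptSequence) else TranscriptSequence("seq", seq)
    s = ts.sequence
    lo, hi = (0, len(s)) if region is None else region
    records = []
    for pos in range(lo, min(hi, len(s) - 2)):
        if s[pos : pos + 3] not in start_set:
            continue
        stop = _first_inframe_stop(s, pos)
        if stop is None:
            continue
        if stop + 3 - pos >= min_len_nt:
            records.append(_make_record(s, pos, stop))
    return records


def translate_orf(orf_rna: str) -> str:
    """Translate an ORF (start..stop) to its peptide; the initiator is Met even
    for near-cognate (CUG) starts."""
    if len(orf_rna) % 3 != 0:
        raise ValidationError("ORF length must be divisible by 3")
    aa = str(Seq(orf_rna).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValidationError("internal stop codon in ORF")
    if aa:
        aa = "M" + aa[1:]
    return aa


def protein_mw(aa_sequence: str) -> float:
    """Average molecular weight in kDa: residue masses plus one water."""
    mass = WATER_DA
    for letter in aa_sequence.upper():
        try:
            mass += protein_weights[letter] - WATER_DA
        except KeyError:
            raise ValidationError(f"unknown amino acid {letter!r}") from None
    return mass / 1000.0


# ---------------------------------------------------------------------------
# proteoform enumeration
# ---------------------------------------------------------------------------


def enumerate_proteoforms(
    seq: TranscriptSequence,
    main_start: Optional[int] = None,
    starts: Sequence[str] = ("AUG", "CUG"),
    min_uorf_nt: int = 150,
) -> list[OrfRecord]:
    """Categorise the coding potential of a transcript with a known main start.

    Returns the main ORF, every in-frame AUG/CUG upstream start that reaches
    the main stop without an intervening stop (N-terminally extended
    proteoforms), and all uORFs whose start codon lies in the 5'-UTR
    (including those overlapping the main ORF).
    """
    if main_start is None:
        main_start = seq.main_start
    if main_start is None:
        raise ValidationError("main start offset required")
    s = seq.sequence
    start_set = {c.upper().replace("T", "U") for c in starts}
    if s[main_start : main_start + 3] not in START_CODONS:
        raise ValidationError(
            f"main start {s[main_start:main_start + 3]!r} is not AUG/CUG"
        )
    main_stop = _first_inframe_stop(s, main_start)
    if main_stop is None:
        raise ValidationError("main ORF has no in-frame stop")
    records: list[OrfRecord] = []
    main = _make_record(s, main_start, main_stop)
    main.category = MAIN_PROTEOFORM
    records.append(main)

    # in-frame upstream starts with an unbroken frame to the main start
    for pos in range(main_start % 3, main_start, 3):
        codon = s[pos : pos + 3]
        if codon not in start_set:
            continue
        if _first_inframe_stop(s, pos) == main_stop:
            rec = _make_record(s, pos, main_stop)
            rec.category = N_EXTENDED
            records.append(rec)

    extended_starts = {r.start_offset for r in records}
    for rec in find_orfs(seq, starts=tuple(start_set), min_len_nt=min_uorf_nt):
        if rec.start_offset >= main_start:
            continue
        if rec.start_offset in extended_starts:
            continue
        rec.category = UORF
        records.append(rec)
    records.sort(key=lambda r: (r.start_offset, r.category or ""))
    return records


def proteoform_table(records: Sequence[OrfRecord], variant: str = "fl"):
    """Tabular summary (one row per ORF) mirroring a coding-potential report."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "variant": variant,
                "category": r.category,
                "start_offset": r.start_offset,
                "start_codon": r.start_codon,
                "kozak_score": round(r.kozak_score, 2),
                "length_aa": r.length_aa,
                "mw_kda": round(r.mw_kda, 1),
            }
            for r in records
        ]
    )
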