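"""Genomic interval primitives.

All internal coordinates are 0-based, half-open ``[start, end)``.  Paper-style
spans (``chrX:49,264,670-49,264,735``) and GTF records are 1-based inclusive
and are converted at the boundary; BED is read natively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

STRANDS = ("+", "-")

_SPAN_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)\s*[-–]\s*(?P<end>[\d,]+)$")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.start == self.end

    def contains(self, pos: int) -> bool:
        """Half-open membership: ``start <= pos < end``."""
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def mirrored(self, constant: int) -> "GenomicInterval":
        """Reflect through ``p -> constant - p`` and flip the strand.

        Maps the half-open span onto the half-open span covering exactly the
        reflected base positions, so widths are preserved.
        """
        start = constant - (self.end - 1)
        end = constant - self.start + 1
        strand = "-" if self.strand == "+" else "+"
        return GenomicInterval(self.chrom, start, end, strand)

    @classmethod
    def from_1based(cls, span: str, strand: str = "+") -> "GenomicInterval":
        """Parse a 1-based inclusive ``chrom:start-end`` span (en dash ok)."""
        m = _SPAN_RE.match(span.replace(" ", ""))
        if not m:
            raise ValidationError(f"cannot parse genomic span {span!r}")
        start = int(m.group("start").replace(",", ""))
        end = int(m.group("end").replace(",", ""))
        if start < 1 or end < start:
            raise ValidationError(f"invalid 1-based span {span!r}")
        return cls(m.group("chrom"), start - 1, end, strand)

    def to_1based(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def parse_position_1based(text: str) -> int:
    """Parse a single 1-based base position (possibly comma-grouped) to 0-based."""
    pos = int(str(text).replace(",", ""))
    if pos < 1:
        raise ValidationError(f"invalid 1-based position {text!r}")
    return pos - 1


def mirror_position(pos: int, constant: int) -> int:
    return constant - pos


def is_transcription_upstream(a: int, b: int, strand: str) -> bool:
    """True if ``a`` lies strictly transcription-upstream of ``b``.

    On the minus strand transcription proceeds toward lower coordinates, so
    upstream means a higher coordinate.
    """
    return a > b if strand == "-" else a < b
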