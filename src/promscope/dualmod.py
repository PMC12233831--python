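"""Dual-modality estimation of the non-adenylated:adenylated output ratio.

Direct RNA sequencing only sees poly(A)+ molecules, while short-read coverage
of a ribo-depleted sample sees all molecules.  The estimator combines the two:

* ``f`` - the fraction of the molecules covering the canonical initiation
  region that are intact alternative-promoter transcripts (longFOXP3), read
  off the DRS classification:
  ``f = n_intact / (n_canonical_output + n_intact + n_degraded)``.
* ``R`` - the non-adenylated:adenylated ratio of the alternative promoter's
  output, from the short-read coverage over the two initiation regions:
  ``R = (C_alt - f * C_canon) / (f * C_canon)``.

``f * C_canon`` is the short-read coverage attributable to adenylated
alternative-promoter transcripts; any excess coverage over the alternative
region itself is attributed to non-adenylated output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ValidationError
from .locus import ALTERNATIVE, CANONICAL, InitiationRegion, LocusAnnotation
from .reads import (
    CANONICAL_CLASSES,
    EXCLUDED,
    LONG_CLASSES,
    NOVEL_CANONICAL,
    REASON_OUTSIDE,
)


@dataclass
class CoverageTrack:
    """Per-base non-negative counts over a stated half-open interval."""

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValidationError("coverage counts must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.values.size

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def slice(self, region: GenomicInterval) -> np.ndarray:
        if region.chrom != self.chrom or not self.span.contains_interval(region):
            raise ValidationError(f"region {region} outside track span {self.span}")
        return self.values[region.start - self.start : region.end - self.start]


def region_coverage(
    track: CoverageTrack, region: GenomicInterval, mode: str = "mean"
) -> float:
    """Mean or max of the per-base counts over a half-open region."""
    if region.is_empty:
        raise ValidationError("cannot take coverage of an empty region")
    values = track.slice(region)
    if mode == "mean":
        return float(values.mean())
    if mode == "max":
        return float(values.max())
    raise ValueError(f"unknown coverage mode {mode!r}")


@dataclass(frozen=True)
class DualModalityInputs:
    n_canonical_output: int  # canonical-promoter reads (canonical + novel)
    n_intact_long: int  # reads classified longFOXP3
    n_degraded_long: int  # 5'-decayed longFOXP3 reads still spanning the canonical region
    c_canon: float  # NGS coverage over the canonical initiation region
    c_alt: float  # NGS coverage over the alternative initiation region

    def __post_init__(self) -> None:
        if min(self.n_canonical_output, self.n_intact_long, self.n_degraded_long) < 0:
            raise ValidationError("read counts must be non-negative")
        if self.c_canon < 0 or self.c_alt < 0:
            raise ValidationError("coverages must be non-negative")


def estimate_f(inputs: DualModalityInputs) -> float:
    """Fraction of canonical-region-covering molecules that are intact longFOXP3.

    NaN when the denominator is zero (undefined).
    """
    den = inputs.n_canonical_output + inputs.n_intact_long + inputs.n_degraded_long
    if den == 0:
        return float("nan")
    return inputs.n_intact_long / den


def estimate_nonadenylated_ratio(c_alt: float, c_canon: float, f: float) -> float:
    """R = (C_alt - f*C_canon) / (f*C_canon); NaN when f*C_canon == 0.

    A negative R means no detectable non-adenylated excess; it is reported
    as-is and flagged by :func:`dual_modality_report`.
    """
    denom = f * c_canon
    if not denom > 0 or not np.isfinite(denom):
        return float("nan")
    return (c_alt - denom) / denom


def dual_modality_report(inputs: DualModalityInputs) -> dict:
    """JSON-serialisable report: inputs, f, R (unrounded and rounded), warnings."""
    f = estimate_f(inputs)
    warnings: list[str] = []
    if math.isnan(f):
        warnings.append("f undefined: zero reads over the canonical region")
        ratio = float("nan")
    else:
        ratio = estimate_nonadenylated_ratio(inputs.c_alt, inputs.c_canon, f)
    if math.isnan(ratio) and not math.isnan(f):
        warnings.append("R undefined: f * C_canon is zero")
    if not math.isnan(ratio) and ratio < 0:
        warnings.append(
            "negative R: no detectable non-adenylated excess over the alternative region"
        )
    return {
        "inputs": {
            "n_canonical_output": inputs.n_canonical_output,
            "n_intact_longFOXP3": inputs.n_intact_long,
            "n_degraded_longFOXP3": inputs.n_degraded_long,
            "coverage_canonical_region": inputs.c_canon,
            "coverage_alternative_region": inputs.c_alt,
        },
        "f": None if math.isnan(f) else f,
        "nonadenylated_to_adenylated_ratio": None if math.isnan(ratio) else ratio,
        "ratio_rounded": None if math.isnan(ratio) else int(round(ratio)),
        "warnings": warnings,
    }


def coverage_ratio_exon11(
    ngs_track: CoverageTrack, drs_track: CoverageTrack, exon11: GenomicInterval
) -> float:
    """Cross-technology anchor: max(NGS)/max(DRS) over the terminal exon.

    NaN when the DRS maximum is zero (undefined).
    """
    ngs_max = region_coverage(ngs_track, exon11, mode="max")
    drs_max = region_coverage(drs_track, exon11, mode="max")
    if drs_max == 0:
        return float("nan")
    return ngs_max / drs_max


# ---------------------------------------------------------------------------
# assembling the estimator inputs from a classified read table
# ---------------------------------------------------------------------------


def _promoter_region(
    regions: list[InitiationRegion], promoter_id: str, peak_number: int
) -> InitiationRegion:
    for region in regions:
        if region.promoter_id == promoter_id and (
            region.source_peak is None or region.source_peak.peak_number == peak_number
        ):
            return region
    raise ValidationError(f"no initiation region for {promoter_id} peak {peak_number}")


def dual_modality_inputs_from_reads(
    classified: pd.DataFrame,
    ann: LocusAnnotation,
    ngs_track: CoverageTrack,
    regions: Optional[list[InitiationRegion]] = None,
    canonical_peak: int = 1,
    alternative_peak: int = 1,
    coverage_mode: str = "mean",
) -> DualModalityInputs:
    """Count the estimator's read classes and measure the two region coverages.

    "Degraded longFOXP3" is operationalised as reads excluded by filter (ii)
    whose 5' end lies between the alternative-promoter regions and the
    canonical region, and whose alignment still fully spans the canonical
    initiation region: these contribute coverage over the canonical promoter
    without being canonical transcripts.
    """
    if regions is None:
        regions = ann.initiation_regions()
    canon_region = _promoter_region(regions, CANONICAL, canonical_peak)
    alt_region = _promoter_region(regions, ALTERNATIVE, alternative_peak)

    labels = classified["label"]
    n_canonical = int(labels.isin(list(CANONICAL_CLASSES) + [NOVEL_CANONICAL]).sum())
    n_intact = int(labels.isin(LONG_CLASSES).sum())

    # lowest transcription-upstream edge of the alternative regions
    alt_edges = [
        r.interval for r in regions if r.promoter_id == ALTERNATIVE
    ]
    if ann.strand == "-":
        alt_floor = min(iv.start for iv in alt_edges)
        between = (
            (classified["five_prime"] < alt_floor)
            & (classified["five_prime"] >= canon_region.interval.end)
        )
        spans_canon = (classified["span_start"] <= canon_region.interval.start) & (
            classified["span_end"] >= canon_region.interval.end
        )
    else:
        alt_ceil = max(iv.end for iv in alt_edges)
        between = (
            (classified["five_prime"] >= alt_ceil)
            & (classified["five_prime"] < canon_region.interval.start)
        )
        spans_canon = (classified["span_start"] <= canon_region.interval.start) & (
            classified["span_end"] >= canon_region.interval.end
        )
    degraded = (
        (classified["label"] == EXCLUDED)
        & (classified["exclusion_reason"] == REASON_OUTSIDE)
        & between
        & spans_canon
    )
    n_degraded = int(degraded.sum())

    return DualModalityInputs(
        n_canonical_output=n_canonical,
        n_intact_long=n_intact,
        n_degraded_long=n_degraded,
        c_canon=region_coverage(ngs_track, canon_region.interval, coverage_mode),
        c_alt=region_coverage(ngs_track, alt_region.interval, coverage_mode),
    )
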