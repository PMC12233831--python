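import itertools
import math

import numpy as np
import pandas as pd
import pytest

from promscope.intervals import GenomicInterval, ValidationError
from promscope.locus import assign_five_prime
from promscope.reads import (
    CANONICAL_D2,
    CANONICAL_FL,
    CLASS_LABELS,
    EXCLUDED,
    LONG_D2,
    LONG_FL,
    LONG_MINOR,
    NOVEL_CANONICAL,
    SHORT_UPSTREAM,
    LongRead,
    ReadClassifier,
    abundance_report,
    cleavage_offsets,
    polya_stats,
    splice_fractions,
)
from promscope.simulate import SimulationConfig, simulate_drs_reads


def clip_blocks(ann, exons, five, three):
    """Independent minus-strand block builder for crafted reads."""
    blocks = []
    for iv in sorted(exons, key=lambda e: e.start):
        s, e = max(iv.start, three), min(iv.end, five + 1)
        if s < e:
            blocks.append(GenomicInterval(ann.chrom, s, e, "-"))
    return blocks


def make_read(ann, five, three, exons=None, skip=(), first=None, read_id="r"):
    chain = [first if first is not None else ann.exon(-1)] + [
        iv for num, iv in ann.exons if num != -1 and num not in skip
    ]
    if exons is not None:
        chain = exons
    return LongRead(read_id, "-", tuple(clip_blocks(ann, chain, five, three)))


class TestFilterRules:
    def test_neighbor_promoter_excluded(self, ann, classifier):
        read = LongRead("r", "-", (GenomicInterval(ann.chrom, 22550, 22601, "-"),))
        rc = classifier.classify_read(read)
        assert rc.label == EXCLUDED and rc.exclusion_reason == "neighbor_promoter"

    def test_five_prime_outside_regions_is_decay(self, ann, classifier):
        read = LongRead("r", "-", (GenomicInterval(ann.chrom, 19900, 21001, "-"),))
        rc = classifier.classify_read(read)
        assert rc.exclusion_reason == "outside_init_region"

    def test_truncated_3utr_excluded(self, ann, classifier):
        read = make_read(ann, five=20185, three=16100)
        rc = classifier.classify_read(read)
        assert rc.exclusion_reason == "short_3utr"

    def test_3utr_threshold_position_is_permitted(self, ann, classifier):
        read = make_read(ann, five=20185, three=ann.pas_min_3prime)
        assert classifier.classify_read(read).label == CANONICAL_FL

    def test_intron_retention_is_aberrant(self, ann, classifier):
        retained = GenomicInterval(ann.chrom, 18800, 19170, "-")  # exons 3+4 fused
        chain = [ann.exon(-1)] + [
            retained if num in (3, 4) else iv
            for num, iv in ann.exons
            if num not in (-1, 4)
        ]
        read = make_read(ann, five=20185, three=16000, exons=chain)
        assert classifier.classify_read(read).exclusion_reason == "aberrant_structure"

    def test_filter_order_rule_i_before_rule_iii(self, ann, classifier):
        # a read violating both (i) and (iii) reports (i)
        read = LongRead("r", "-", (GenomicInterval(ann.chrom, 16100, 22601, "-"),))
        assert classifier.classify_read(read).exclusion_reason == "neighbor_promoter"

    def test_opposite_strand_is_aberrant(self, ann, classifier):
        read = LongRead("r", "+", (GenomicInterval(ann.chrom, 16000, 16100, "+"),))
        assert classifier.classify_read(read).exclusion_reason == "aberrant_structure"

    def test_zero_block_read_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            LongRead("r", "-", ())


class TestClassification:
    def test_canonical_full_length(self, ann, classifier):
        read = make_read(ann, five=20185, three=16000)
        assert classifier.classify_read(read).label == CANONICAL_FL

    def test_canonical_delta2(self, ann, classifier):
        read = make_read(ann, five=20185, three=16000, skip=(2,))
        assert classifier.classify_read(read).label == CANONICAL_D2

    def test_novel_canonical_by_variant_first_exon(self, ann, classifier):
        read = make_read(
            ann, five=20185, three=16000, first=ann.alt_first_exon_variants[0]
        )
        assert classifier.classify_read(read).label == NOVEL_CANONICAL

    def test_long_delta2_from_alternative_promoter(self, ann, classifier):
        read = make_read(
            ann, five=21810, three=16000, skip=(2,), first=ann.extended_first_exon
        )
        assert classifier.classify_read(read).label == LONG_D2

    def test_long_minor_skip_signature(self, ann, classifier):
        read = make_read(
            ann, five=21810, three=16000, skip=(2, 7), first=ann.extended_first_exon
        )
        assert classifier.classify_read(read).label == LONG_MINOR

    def test_short_upstream_ends_in_first_intron(self, ann, classifier):
        read = LongRead("r", "-", (GenomicInterval(ann.chrom, 19900, 21811, "-"),))
        assert classifier.classify_read(read).label == SHORT_UPSTREAM

    def test_short_upstream_exempt_from_3utr_rule(self, ann, classifier):
        # terminates long before the PAS yet is not excluded
        rc = classifier.classify_read(
            LongRead("r", "-", (GenomicInterval(ann.chrom, 20500, 21811, "-"),))
        )
        assert rc.label == SHORT_UPSTREAM and rc.exclusion_reason == "none"


class TestPartitionAndRecovery:
    def test_every_read_gets_exactly_one_class(self, drs_run):
        df = drs_run["classified"]
        assert len(df) == len(drs_run["reads"])
        assert set(df["label"]) <= set(CLASS_LABELS) | {EXCLUDED}
        n_excluded = (df["label"] == EXCLUDED).sum()
        n_classified = df["label"].isin(CLASS_LABELS).sum()
        assert n_excluded + n_classified == len(df)

    def test_recovered_proportions_within_3_multinomial_se(self, drs_run):
        df = drs_run["classified"]
        kept = df[df["label"] != EXCLUDED]
        weights = drs_run["config"].class_weights
        total_w = sum(weights.values())
        n = len(kept)
        for cls, w in weights.items():
            p = w / total_w
            se = math.sqrt(p * (1 - p) / n)
            p_hat = (kept["label"] == cls).mean()
            assert abs(p_hat - p) <= 3 * se + 0.01, cls

    def test_decayed_past_region_never_classified(self, ann, drs_run):
        df = drs_run["classified"].merge(drs_run["truth"], on="read_id")
        regions = ann.initiation_regions()
        outside = df["read_five_prime"].apply(
            lambda p: assign_five_prime(int(p), regions) is None
        )
        gone = df[df["decayed"] & outside]
        assert len(gone) > 0
        assert (gone["label"] == EXCLUDED).all()

    def test_mirror_symmetry_of_classification(self, ann):
        config = SimulationConfig(n_reads=400, n_replicates=1)
        reads, _ = simulate_drs_reads(ann, config, seed=77)
        c = ann.chrom_length
        mirrored_reads = [
            LongRead(
                r.read_id,
                "+",
                tuple(sorted((b.mirrored(c) for b in r.blocks), key=lambda b: b.start)),
                r.polya_len,
                r.replicate_id,
            )
            for r in reads
        ]
        df = ReadClassifier(ann).classify_reads(reads)
        df_m = ReadClassifier(ann.mirrored()).classify_reads(mirrored_reads)
        assert (df["label"] == df_m["label"]).all()
        assert (df["exclusion_reason"] == df_m["exclusion_reason"]).all()


def classified_frame(counts_by_replicate):
    rows = []
    for rep, counts in counts_by_replicate.items():
        for label, n in counts.items():
            for i in range(n):
                rows.append(
                    {
                        "read_id": f"{rep}_{label}_{i}",
                        "replicate_id": rep,
                        "five_prime": 0,
                        "three_prime": 0,
                        "span_start": 0,
                        "span_end": 1,
                        "polya_len": None,
                        "label": label,
                        "exclusion_reason": "none",
                    }
                )
    return pd.DataFrame(rows)


class TestAbundanceReport:
    def test_median_of_replicate_ratios(self):
        df = classified_frame(
            {
                "r1": {CANONICAL_FL: 30, LONG_FL: 10},
                "r2": {CANONICAL_FL: 40, LONG_FL: 10},
                "r3": {CANONICAL_FL: 110, LONG_FL: 10},
            }
        )
        report = abundance_report(df)
        assert report.medians["canonical_to_long"] == 4.0

    def test_simple_ratio_and_undefined_denominators(self):
        df = classified_frame({"r1": {CANONICAL_FL: 40, LONG_FL: 10}})
        report = abundance_report(df)
        row = report.ratios.loc["r1"]
        assert row["canonical_to_long"] == 4.0
        assert np.isnan(row["canonical_to_novel"])
        assert np.isnan(row["canonical_to_short"])

    def test_zero_canonical_replicate_is_flagged_not_infinite(self):
        df = classified_frame({"r1": {LONG_FL: 10, NOVEL_CANONICAL: 5}})
        report = abundance_report(df)
        assert np.isnan(report.ratios.loc["r1", "canonical_to_long"])
        assert any("zero canonical" in f for f in report.flags)

    def test_alternative_promoter_output_pools_long_and_short(self):
        # 126 longFOXP3 + 4 minor-splice + 3 short = 133 alternative reads
        df = classified_frame(
            {"r1": {CANONICAL_FL: 206, LONG_FL: 126, LONG_MINOR: 4, SHORT_UPSTREAM: 3}}
        )
        report = abundance_report(df)
        pooled = report.counts.sum(axis=0)
        alt = pooled[[LONG_FL, "longFOXP3_d2", LONG_MINOR, SHORT_UPSTREAM]].sum()
        assert alt == 133
        assert report.promoter_output_ratio == pytest.approx(206 / 133)


class TestSpliceFractions:
    def test_single_replicate_percentages(self):
        df = classified_frame({"r1": {LONG_FL: 37, LONG_D2: 56, LONG_MINOR: 7}})
        fr = splice_fractions(df)
        assert fr.loc["r1"].tolist() == pytest.approx([0.37, 0.56, 0.07])
        assert fr.loc["r1", ["fl", "d2"]].sum() == pytest.approx(0.93)

    def test_all_full_length(self):
        df = classified_frame({"r1": {LONG_FL: 12}})
        assert splice_fractions(df).loc["r1"].tolist() == [1.0, 0.0, 0.0]

    def test_cross_replicate_means(self):
        df = classified_frame(
            {
                "r1": {LONG_FL: 40, LONG_D2: 60},
                "r2": {LONG_FL: 17, LONG_D2: 26, LONG_MINOR: 7},
            }
        )
        means = splice_fractions(df).loc["mean"]
        assert means.tolist() == pytest.approx([0.37, 0.56, 0.07])

    def test_no_long_reads_is_undefined(self):
        df = classified_frame({"r1": {CANONICAL_FL: 5}})
        with pytest.raises(ValidationError):
            splice_fractions(df)


class TestCleavageOffsets:
    def offsets_for(self, ann, three_primes):
        df = classified_frame({"r1": {CANONICAL_FL: len(three_primes)}})
        df["three_prime"] = list(three_primes)
        return cleavage_offsets(df, ann)

    def test_read_ending_at_pas_has_offset_zero(self, ann):
        offsets, _ = self.offsets_for(ann, [ann.pas_position])
        assert offsets.tolist() == [0]

    def test_minus_strand_read_running_past_pas_is_positive(self, ann):
        # 2 bases below the PAS = 2 nt further in the direction of transcription
        offsets, _ = self.offsets_for(ann, [ann.pas_position - 2])
        assert offsets.tolist() == [2]

    def test_mirror_sign_convention(self, ann):
        mirrored = ann.mirrored()
        offsets, _ = self.offsets_for(mirrored, [mirrored.pas_position + 2])
        assert offsets.tolist() == [2]

    def test_uniform_pm2_cohort_fully_within_histogram_core(self, ann, rng):
        threes = ann.pas_position - rng.integers(-2, 3, size=200)
        offsets, hist = self.offsets_for(ann, threes)
        assert offsets.abs().max() <= 2
        core = hist[hist["offset"].isin(range(-2, 3))]["count"].sum()
        assert core == 200


def mann_whitney_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    combined = sorted(x + y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    n = len(combined)
    us = []
    for idx in itertools.combinations(range(n), n1):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    total = len(us)
    hi = max(u_obs, n1 * (n - n1) - u_obs)
    lo = min(u_obs, n1 * (n - n1) - u_obs)
    p = ((us >= hi).sum() + (us <= lo).sum()) / total
    return u_obs, min(1.0, p)


class TestPolyAStats:
    def test_modal_length_tie_breaks_to_smallest(self):
        stats = polya_stats({"g": [88, 89, 89, 90, 90]})
        assert stats.groups["g"].mode == 89

    def test_basic_group_statistics(self):
        stats = polya_stats({"g": [88, 89, 89, 90]})
        g = stats.groups["g"]
        assert (g.mode, g.median) == (89, 89)

    def test_identical_groups_show_no_shift(self):
        values = list(range(1, 11))
        comparison = polya_stats(
            {"a": values, "b": values}, compare=("a", "b")
        )
        assert comparison.u_statistic == pytest.approx(len(values) ** 2 / 2)
        assert comparison.p_value > 0.9

    def test_exact_p_matches_enumeration_oracle(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        comparison = polya_stats({"a": x, "b": y}, compare=("a", "b"))
        u_oracle, p_oracle = mann_whitney_oracle(x, y)
        assert comparison.u_statistic == pytest.approx(u_oracle)
        assert comparison.p_value == pytest.approx(p_oracle)

    def test_empty_group_is_flagged(self):
        stats = polya_stats({"a": [], "b": [1.0]})
        assert any("undefined" in f for f in stats.flags)
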