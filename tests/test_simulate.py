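import math

import numpy as np
import pandas as pd
import pytest

from promscope.dualmod import region_coverage
from promscope.intervals import GenomicInterval, ValidationError
from promscope.reads import CANONICAL_FL, SHORT_UPSTREAM
from promscope.simulate import (
    NONADENYLATED_SHORT,
    SimulationConfig,
    coverage_from_molecules,
    default_locus,
    simulate_drs_reads,
    simulate_fish_images,
    simulate_locus,
    simulate_molecules,
    simulate_ngs_coverage,
    simulate_presence_table,
)


class TestLocusTemplate:
    def test_twelve_exons_with_pas_in_terminal_exon(self, ann):
        assert len(ann.exons) == 12
        assert ann.exon_numbers == [-1] + list(range(1, 12))
        assert ann.exon(11).contains(ann.pas_position)

    def test_alternative_promoter_is_transcription_upstream(self, ann):
        # minus-strand locus: alternative promoter at higher coordinates
        alt = ann.alternative_peaks[0].summit
        canon = ann.canonical_peaks[0].summit
        assert ann.upstream_of(alt, canon)

    def test_long_transcript_length_and_extension(self, transcripts):
        assert len(transcripts["longFOXP3_fl"]) == 3903
        canonical = len(transcripts["canonical_fl"])
        assert len(transcripts["longFOXP3_fl"]) / canonical == pytest.approx(1.86, abs=0.01)

    def test_mirrored_template_is_the_reflection(self):
        ann = default_locus()
        mirrored = default_locus(mirror=True)
        assert mirrored.strand == "+"
        c = ann.chrom_length
        for (num, iv), (num_m, iv_m) in zip(ann.exons, mirrored.exons):
            assert num == num_m
            assert iv_m == iv.mirrored(c)


class TestDeterminism:
    def test_same_seed_identical_reads(self, ann):
        config = SimulationConfig(n_reads=300, n_replicates=2)
        reads1, truth1 = simulate_drs_reads(ann, config, seed=9)
        reads2, truth2 = simulate_drs_reads(ann, config, seed=9)
        assert [
            (r.read_id, r.blocks, r.polya_len) for r in reads1
        ] == [(r.read_id, r.blocks, r.polya_len) for r in reads2]
        pd.testing.assert_frame_equal(truth1, truth2)
        reads3, _ = simulate_drs_reads(ann, config, seed=10)
        assert [r.blocks for r in reads1] != [r.blocks for r in reads3]

    def test_same_seed_identical_images(self):
        config = SimulationConfig(n_fields=1, n_cells_per_field=9, field_shape=(384, 384))
        f1 = simulate_fish_images(config, seed=4)[0]
        f2 = simulate_fish_images(config, seed=4)[0]
        for ch in f1.image.channels:
            assert np.array_equal(f1.image.channels[ch], f2.image.channels[ch])
        pd.testing.assert_frame_equal(f1.cells, f2.cells)

    def test_same_seed_identical_presence_tables(self):
        t1 = simulate_presence_table(SimulationConfig(n_cells_per_group=50), seed=2)
        t2 = simulate_presence_table(SimulationConfig(n_cells_per_group=50), seed=2)
        pd.testing.assert_frame_equal(t1, t2)


class TestReadGeneration:
    def test_class_mixture_within_3_multinomial_se(self, ann, rng):
        config = SimulationConfig()
        molecules = simulate_molecules(ann, config, rng, 10_000)
        weights = config.class_weights
        total = sum(weights.values())
        for cls, w in weights.items():
            p = w / total
            se = math.sqrt(p * (1 - p) / len(molecules))
            assert abs((molecules["true_class"] == cls).mean() - p) <= 3 * se + 1e-9

    def test_no_decay_no_jitter_reads_start_at_summits(self, ann):
        config = SimulationConfig(
            n_reads=200, n_replicates=1, decay_fraction=0.0,
            tss_jitter_sd=0.0, tech_shift_range=(0, 0),
        )
        reads, truth = simulate_drs_reads(ann, config, seed=6)
        summits = {p.summit for p in ann.all_peaks}
        assert set(truth["read_five_prime"]) <= summits
        for read in reads:
            assert read.five_prime in summits

    def test_polya_modes_separate_by_class(self, ann, rng):
        config = SimulationConfig(decay_fraction=0.0)
        molecules = simulate_molecules(ann, config, rng, 8000)
        foxp3 = molecules[molecules["true_class"] == CANONICAL_FL]["polya_len"]
        short = molecules[molecules["true_class"] == SHORT_UPSTREAM]["polya_len"]
        # log-normal mode = exp(mu - sigma^2); estimate mu from the log sample
        sigma2 = SimulationConfig().polya_log_sigma ** 2

        def mode_estimate(x):
            return math.exp(np.log(x.astype(float)).mean() - sigma2)

        assert abs(mode_estimate(foxp3) - 89) <= 4
        assert abs(mode_estimate(short) - 53) <= 4
        assert foxp3.median() > short.median()

    def test_invalid_molecule_count_rejected(self, ann, rng):
        with pytest.raises(ValidationError):
            simulate_molecules(ann, SimulationConfig(), rng, 0)


class TestNgsCoverage:
    def test_single_class_tile_coverage_uniform_over_interior(self, ann):
        config = SimulationConfig(
            class_weights={CANONICAL_FL: 1.0}, decay_fraction=0.0,
            tss_jitter_sd=0.0, ngs_molecules=400,
        )
        track, _ = simulate_ngs_coverage(ann, config, seed=3)
        interior = GenomicInterval(ann.chrom, 17300, 17420)  # exon 10
        values = track.slice(interior)
        assert values.std() / values.mean() < 0.10

    def test_fragment_sampling_mode_mean_matches_base_count(self, ann, rng):
        config = SimulationConfig(
            class_weights={CANONICAL_FL: 1.0}, decay_fraction=0.0,
            ngs_mode="sample", ngs_fragment_length=100, ngs_fragments_per_kb=30.0,
        )
        molecules = simulate_molecules(ann, config, rng, 30)
        track = coverage_from_molecules(ann, molecules, config, rng)
        # total fragment-bases over the span equals the summed coverage
        assert track.values.sum() > 0
        assert track.values.sum() % 1 == 0

    def test_nonadenylated_species_present_at_rho(self, ann, rng):
        config = SimulationConfig(nonadenylated_ratio=2.0)
        molecules = simulate_molecules(ann, config, rng, 5000, include_nonadenylated=True)
        n_alt_polya = molecules["true_class"].isin(
            ["longFOXP3_fl", "longFOXP3_d2", "longFOXP3_minor", SHORT_UPSTREAM]
        ).sum()
        n_non = (molecules["true_class"] == NONADENYLATED_SHORT).sum()
        assert n_non == round(2.0 * n_alt_polya)
        assert molecules[molecules["true_class"] == NONADENYLATED_SHORT]["polya_len"].isna().all()

    def test_nonadenylated_transcripts_end_between_the_promoters(self, ann, rng):
        config = SimulationConfig(nonadenylated_ratio=1.0)
        molecules = simulate_molecules(ann, config, rng, 3000, include_nonadenylated=True)
        nonpa = molecules[molecules["true_class"] == NONADENYLATED_SHORT]
        canon_region_top = 20196  # transcription-downstream edge of the canonical region
        assert (nonpa["three_prime"] > canon_region_top).all()
        assert (nonpa["three_prime"] < 22050).all()


class TestImagesAndPresence:
    def test_no_upa_probability_means_no_upa_spots(self):
        config = SimulationConfig(
            n_fields=1, n_cells_per_field=9, field_shape=(384, 384),
            upa_positive_prob=0.0,
        )
        field = simulate_fish_images(config, seed=8)[0]
        assert (field.cells["n_upa"] == 0).all()
        assert (field.spots["channel"] != "upa").all()

    def test_field_too_small_for_cells_rejected(self):
        config = SimulationConfig(n_fields=1, n_cells_per_field=100, field_shape=(256, 256))
        with pytest.raises(ValidationError):
            simulate_fish_images(config, seed=1)

    def test_single_cell_type_rejected(self):
        config = SimulationConfig(cell_type_logits={"only": 0.0})
        with pytest.raises(ValidationError):
            simulate_presence_table(config, seed=1)

    def test_presence_fractions_follow_planted_logits(self):
        config = SimulationConfig(n_cells_per_group=400)
        table = simulate_presence_table(config, seed=77)
        frac = table.groupby("cell_type")["present"].mean()
        assert abs(frac["naive_treg"] - 0.88) < 0.05
        assert abs(frac["naive_tconv"] - 0.06) < 0.04


class TestTruthSufficiency:
    def test_truth_tables_score_reads_without_generator_internals(self, drs_run):
        truth = drs_run["truth"]
        required = {
            "read_id", "replicate_id", "true_class", "decayed",
            "truncation_nt", "read_five_prime", "three_prime", "polya_len",
        }
        assert required <= set(truth.columns)
        assert truth["read_id"].is_unique

    def test_locus_pair_round_trip(self):
        ann, transcripts = simulate_locus(seed=0)
        assert set(transcripts) == {
            "longFOXP3_fl", "longFOXP3_d2", "canonical_fl", "canonical_d2"
        }
        assert ann.extended_first_exon is not None
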