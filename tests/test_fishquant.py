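import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy.stats import spearmanr

from promscope.fishquant import (
    FishConfig,
    SpotObject,
    cell_table,
    colocalize,
    detect_spots,
    expand_cells,
    expand_radius_px,
    quantify_field,
    segment_nuclei,
    summarize_culture,
    upa_only_to_coloc_ratio,
)
from promscope.intervals import ValidationError
from promscope.simulate import SimulationConfig, simulate_fish_images


def disk_image(centers, radius=12, shape=(256, 256), amplitude=200.0, noise=5.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, 20.0)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] += amplitude
    return img + rng.normal(0, noise, shape)


def gaussian_spots(centers, shape=(256, 256), amplitude=90.0, sigma=1.3, noise=10.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, 20.0)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in centers:
        img += amplitude * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
    return img + rng.normal(0, noise, shape)


class TestSegmentNuclei:
    def test_blank_image_yields_zero_nuclei(self):
        assert segment_nuclei(np.zeros((128, 128))).max() == 0

    def test_five_separated_disks(self):
        centers = [(40, 40), (40, 200), (128, 128), (210, 60), (210, 200)]
        labels = segment_nuclei(disk_image(centers))
        assert labels.max() == 5

    def test_touching_disks_split_by_watershed(self):
        # two disks overlapping by ~20% of their diameter
        labels = segment_nuclei(disk_image([(128, 110), (128, 130)], radius=12))
        assert labels.max() == 2


class TestExpandCells:
    def test_physical_radius_to_pixels(self):
        assert expand_radius_px(3.0, 104.0) == 29

    def test_zero_radius_keeps_cell_equal_to_nucleus(self):
        nuclei = segment_nuclei(disk_image([(128, 128)]))
        cells, cytoplasm = expand_cells(nuclei, 0.0, 104.0)
        assert np.array_equal(cells, nuclei)
        assert cytoplasm.max() == 0

    def test_collision_resolved_by_nearest_nucleus(self):
        nuclei = np.zeros((120, 160), dtype=np.int32)
        nuclei[60, 50] = 1
        nuclei[60, 90] = 2  # 40 px apart, expansion radius 29 px
        cells, cytoplasm = expand_cells(nuclei, 3.0, 104.0)
        assert set(np.unique(cells)) == {0, 1, 2}
        # masks disjoint by construction of a label image; boundary equidistant
        ys, xs = np.nonzero(cells == 1)
        assert xs.max() <= 70
        ys, xs = np.nonzero(cells == 2)
        assert xs.min() >= 70
        assert not np.any((cytoplasm > 0) & (nuclei > 0))


class TestDetectSpots:
    def test_blank_and_pure_noise_images_yield_no_spots(self):
        assert detect_spots(np.zeros((128, 128))) == []
        rng = np.random.default_rng(0)
        noise = 20.0 + rng.normal(0, 10, (128, 128))
        assert len(detect_spots(noise)) <= 1

    def test_ten_planted_spots_all_recovered(self):
        rng = np.random.default_rng(5)
        centers = [(20 + 22 * i, 30 + 19 * ((i * 7) % 10)) for i in range(10)]
        img = gaussian_spots(centers, amplitude=90.0, noise=10.0)  # SNR ~ 8
        spots = detect_spots(img)
        assert len(spots) == 10
        detected = np.array([s.centroid for s in spots])
        for r, c in centers:
            assert np.min(np.hypot(detected[:, 0] - r, detected[:, 1] - c)) < 2.0

    def test_merged_blobs_count_once(self):
        img = gaussian_spots([(100, 100), (100, 101)])
        assert len(detect_spots(img)) == 1


def square_spot(spot_id, channel, r0, c0, size):
    coords = np.array([(r, c) for r in range(r0, r0 + size) for c in range(c0, c0 + size)])
    return SpotObject(
        spot_id=spot_id,
        channel=channel,
        pixels=coords,
        centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
        area=len(coords),
    )


class TestColocalize:
    def test_identical_masks_fully_colocalized(self):
        upa = [square_spot(1, "upa", 10, 10, 4)]
        mrna = [square_spot(1, "mrna", 10, 10, 4)]
        tagged, meta = colocalize(upa, mrna, (64, 64))
        assert all(s.colocalized for s in tagged)
        assert meta["min_overlap"] == 0.3

    def test_quarter_overlap_fails_threshold_030(self):
        upa = [square_spot(1, "upa", 10, 10, 4)]  # 16 px
        mrna = [square_spot(1, "mrna", 12, 12, 2)]  # overlaps 4/16 = 25%
        tagged, _ = colocalize(upa, mrna, (64, 64), min_overlap=0.3)
        assert not tagged[0].colocalized
        tagged, _ = colocalize(upa, mrna, (64, 64), min_overlap=0.25)
        assert tagged[0].colocalized

    def test_anti_monotone_in_threshold(self, rng):
        upa = [
            square_spot(i, "upa", int(rng.integers(0, 60)), int(rng.integers(0, 60)), 3)
            for i in range(30)
        ]
        mrna = [
            square_spot(i, "mrna", int(rng.integers(0, 60)), int(rng.integers(0, 60)), 3)
            for i in range(30)
        ]
        counts = []
        for threshold in (0.1, 0.3, 0.5, 0.8, 1.0):
            tagged, _ = colocalize(upa, mrna, (64, 64), min_overlap=threshold)
            counts.append(sum(s.colocalized for s in tagged))
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            colocalize([], [], (8, 8), min_overlap=0.0)


class TestSummaries:
    def test_published_per_donor_ratio_formula(self):
        assert round(upa_only_to_coloc_ratio(850, 1713), 1) == 2.0
        assert np.isnan(upa_only_to_coloc_ratio(0, 10))

    def test_summary_of_empty_cells(self):
        cells = pd.DataFrame(
            {
                "cell_id": [1, 2],
                "n_mrna": 0, "n_mrna_nuclear": 0, "n_upa": 0, "n_upa_nuclear": 0,
                "n_coloc": 0, "n_coloc_nuclear": 0, "n_upa_only": 0,
            }
        )
        s = summarize_culture(cells)
        assert s.pct_cells_with_mrna == 0.0 and s.pct_cells_with_upa == 0.0
        assert np.isnan(s.ratio_upa_only_to_coloc) and s.flags

    def test_summarize_requires_cells(self):
        with pytest.raises(ValidationError):
            summarize_culture(pd.DataFrame(columns=["n_mrna"]))


class TestCompartmentBounds:
    @pytest.mark.parametrize("nuclear_fraction,check", [(1.0, "nuclear"), (0.0, "cyto")])
    def test_planted_compartment_recovered(self, nuclear_fraction, check):
        config = SimulationConfig(
            n_fields=1, n_cells_per_field=25, field_shape=(576, 576),
            nuclear_fraction=nuclear_fraction, upa_positive_prob=0.0,
        )
        field = simulate_fish_images(config, seed=41)[0]
        cells, _ = quantify_field(field.image)
        s = summarize_culture(cells)
        if check == "nuclear":
            assert s.pct_nuclear_mrna == 100.0
        else:
            assert s.pct_nuclear_mrna <= 5.0


class TestRecovery:
    def match_cells(self, field, cells_label_image):
        """Map segmented cell ids to truth cells via the truth nucleus centers."""
        mapping = {}
        for _, row in field.cells.iterrows():
            cid = int(cells_label_image[int(row.center_r), int(row.center_c)])
            if cid:
                mapping[cid] = (int(row.cell), row.n_mrna)
        return mapping

    def test_per_cell_count_recovery(self, fish_run):
        """Recovered per-cell mRNA counts track the planted counts (Spearman
        >= 0.9) with a pooled count error below 10%."""
        truths, recovered = [], []
        total_true = total_found = 0
        for result in fish_run:
            field = result["field"]
            nuclei = segment_nuclei(field.image.channels["dapi"])
            cells_img, _ = expand_cells(nuclei, 3.0, field.image.pixel_size_nm)
            by_id = result["cells"].set_index("cell_id")
            for _, row in field.cells.iterrows():
                cid = int(cells_img[int(row.center_r), int(row.center_c)])
                if cid in by_id.index:
                    truths.append(row.n_mrna)
                    recovered.append(by_id.loc[cid, "n_mrna"])
            total_true += field.cells.n_mrna.sum()
            total_found += result["cells"].n_mrna.sum()
        rho, _ = spearmanr(truths, recovered)
        assert rho >= 0.9
        assert abs(total_found - total_true) / total_true <= 0.10

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_fraction_positive_within_binomial_ci(self, p):
        config = SimulationConfig(
            n_fields=1, n_cells_per_field=64, field_shape=(960, 960),
            upa_positive_prob=p,
        )
        field = simulate_fish_images(config, seed=int(p * 100))[0]
        cells, _ = quantify_field(field.image)
        n = len(cells)
        p_hat = (cells.n_upa > 0).mean()
        half_width = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) <= half_width + 0.02
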