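"""Ratio images, HSI rendering, mosaics, segmentation and ROI statistics."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.colors import rgb_to_hsv

from isopulse.constants import MIMS_BASELINE_RATIO
from isopulse.mims_imaging import (
    HUE_BLUE,
    HUE_MAGENTA,
    RatioImage,
    RoiSet,
    hsi_render,
    nuc_cyto_ratio,
    percent_above_background,
    ratio_image,
    roi_stats,
    segment_nuclei,
    stitch_tiles,
    write_ratio_tiff,
)
from isopulse.synthetic_data import (
    IonImageStack,
    RegionSpec,
    synthesize_mims_fields,
)


def uniform_stack(n14=10_000, n15=37, shape=(8, 8)):
    return IonImageStack(
        np.full(shape, n14, dtype=np.uint32),
        np.full(shape, n15, dtype=np.uint32),
        np.zeros(shape, dtype=np.uint32),
    )


class TestRatioImage:
    def test_natural_abundance_reads_zero_percent(self):
        img = ratio_image(uniform_stack(10_000, 37))
        assert img.ratio == pytest.approx(0.0037)
        assert img.percent_above == pytest.approx(0.0)

    def test_default_baseline_is_natural_abundance(self):
        img = ratio_image(uniform_stack())
        assert img.baseline == 0.0037

    def test_labeled_region_reads_300_percent(self):
        img = ratio_image(uniform_stack(10_000, 148))
        assert img.percent_above == pytest.approx(300.0)

    def test_zero_count_pixels_masked(self):
        stack = uniform_stack()
        stack.n14[0, 0] = 0
        img = ratio_image(stack)
        assert not img.valid[0, 0]
        assert img.valid[1:].all()
        assert len(img.valid_values()) == stack.n14.size - 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            IonImageStack(
                np.zeros((4, 4), np.uint32),
                np.zeros((4, 5), np.uint32),
                np.zeros((4, 4), np.uint32),
            )

    def test_masking_monotone_in_min_counts(self):
        stack = synthesize_mims_fields((40, 40), [], mean_14n_counts=30, seed=2)
        n_valid = [
            ratio_image(stack, min_14n_counts=t).valid.sum() for t in (10, 20, 30, 40)
        ]
        assert all(a >= b for a, b in zip(n_valid, n_valid[1:]))


class TestPercentAbove:
    @pytest.mark.parametrize(
        "r,expected", [(0.0037, 0.0), (0.0074, 100.0), (0.0, -100.0)]
    )
    def test_values(self, r, expected):
        assert percent_above_background(r, 0.0037) == pytest.approx(expected)

    def test_linear_in_ratio(self):
        r = np.linspace(0, 0.02, 11)
        p = percent_above_background(r, 0.0037)
        slopes = np.diff(p) / np.diff(r)
        assert slopes == pytest.approx(100.0 / 0.0037)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_above_background(0.004, 0.0)


class TestHsiRender:
    def _image(self, percents):
        r = MIMS_BASELINE_RATIO * (1.0 + np.asarray(percents, float) / 100.0)
        return RatioImage(ratio=r, valid=np.ones(r.shape, bool))

    def test_bounds_map_to_blue_and_magenta(self):
        img = self._image([[0.0, 300.0]])
        render = hsi_render(img, 0.0, 300.0, intensity=np.ones((1, 2)))
        hsv = rgb_to_hsv(render.rgb)
        assert hsv[0, 0, 0] == pytest.approx(HUE_BLUE)
        assert hsv[0, 1, 0] == pytest.approx(HUE_MAGENTA)

    def test_midpoint_hue_is_halfway(self):
        img = self._image([[150.0]])
        render = hsi_render(img, 0.0, 300.0, intensity=np.ones((1, 1)))
        hsv = rgb_to_hsv(render.rgb)
        assert hsv[0, 0, 0] == pytest.approx((HUE_BLUE + HUE_MAGENTA) / 2)

    def test_values_clamped_at_bounds(self):
        img = self._image([[-50.0, 500.0]])
        render = hsi_render(img, 0.0, 300.0, intensity=np.ones((1, 2)))
        hsv = rgb_to_hsv(render.rgb)
        assert hsv[0, 0, 0] == pytest.approx(HUE_BLUE)
        assert hsv[0, 1, 0] == pytest.approx(HUE_MAGENTA)

    def test_invalid_bounds_rejected(self):
        img = self._image([[0.0]])
        with pytest.raises(ValueError):
            hsi_render(img, 300.0, 0.0)
        with pytest.raises(ValueError):
            hsi_render(img, 0.0, np.inf)

    def test_rendering_leaves_statistics_unchanged(self):
        stack = synthesize_mims_fields(
            (30, 30), [RegionSpec(1, 150.0, ("rect", 5, 5, 25, 25))], seed=4
        )
        img = ratio_image(stack)
        rois = RoiSet(stack.labels)
        before = roi_stats(img, rois)
        hsi_render(img)
        after = roi_stats(img, rois)
        pd.testing.assert_frame_equal(before, after)


class TestStitching:
    def test_grid_concatenation(self):
        tiles = [
            synthesize_mims_fields((10, 10), [], mean_14n_counts=100, seed=s)
            for s in range(4)
        ]
        mosaic = stitch_tiles(tiles, (2, 2))
        assert mosaic.shape == (20, 20)
        np.testing.assert_array_equal(mosaic.n14[:10, :10], tiles[0].n14)
        np.testing.assert_array_equal(mosaic.n14[:10, 10:], tiles[1].n14)
        np.testing.assert_array_equal(mosaic.n14[10:, :10], tiles[2].n14)

    def test_single_tile_identity(self):
        tile = synthesize_mims_fields((12, 12), [], seed=1)
        mosaic = stitch_tiles([tile], (1, 1))
        np.testing.assert_array_equal(mosaic.n15, tile.n15)

    def test_tile_count_mismatch_rejected(self):
        tile = synthesize_mims_fields((8, 8), [], seed=1)
        with pytest.raises(ValueError):
            stitch_tiles([tile, tile], (2, 2))

    def test_uniform_region_consistent_across_tile_seam(self):
        """A uniform labeling level spanning two tiles: the mosaic ROI mean
        matches the single-tile value within Poisson error."""
        dose = 10_000
        tiles = [
            synthesize_mims_fields((40, 40), [], mean_14n_counts=dose, seed=s)
            for s in (10, 11)
        ]
        mosaic = stitch_tiles(tiles, (1, 2))
        img = ratio_image(mosaic)
        labels = np.zeros(mosaic.shape, dtype=np.int32)
        labels[:, 20:60] = 1  # straddles the seam
        table = roi_stats(img, RoiSet(labels))
        se = np.sqrt(0.0037 / dose / (40 * 40))
        assert abs(table.loc[0, "mean_ratio"] - 0.0037) < 3 * se


class TestSegmentation:
    def test_bright_disks_recovered(self):
        regions = [
            RegionSpec(i + 1, 0.0, ("disk", 20 + 30 * (i // 2), 20 + 35 * (i % 2), 6),
                       is_nucleus=True)
            for i in range(5)
        ]
        stack = synthesize_mims_fields((90, 90), regions, seed=7)
        mask = segment_nuclei(stack.p31)
        n_found = mask.max()
        assert n_found == 5
        for spec in regions:
            truth = stack.labels == spec.label
            found_labels = np.unique(mask[truth])
            found_labels = found_labels[found_labels > 0]
            assert len(found_labels) == 1
            found = mask == found_labels[0]
            iou = (truth & found).sum() / (truth | found).sum()
            assert iou >= 0.8

    def test_blank_channel_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="blank"):
            mask = segment_nuclei(np.zeros((20, 20)))
        assert mask.sum() == 0

    def test_small_component_excluded(self):
        regions = [
            RegionSpec(1, 0.0, ("disk", 15, 15, 6), is_nucleus=True),
            RegionSpec(2, 0.0, ("disk", 40, 40, 2), is_nucleus=True),
        ]
        stack = synthesize_mims_fields((60, 60), regions, seed=8)
        mask = segment_nuclei(stack.p31, min_area=30)
        assert mask.max() == 1
        assert not mask[stack.labels == 2].any()


class TestRoiStats:
    def test_region_mean_within_three_se(self):
        stack = synthesize_mims_fields(
            (40, 40), [RegionSpec(1, 150.0, ("rect", 4, 4, 29, 24))],
            mean_14n_counts=10_000, seed=9,
        )
        img = ratio_image(stack)
        table = roi_stats(img, RoiSet(stack.labels, {1: "granulosa"}))
        row = table.iloc[0]
        assert row["n_pixels"] == 500
        assert abs(row["mean_percent_above"] - 150.0) < 3 * row["se_percent_above"]

    def test_fully_masked_roi_flagged_excluded(self):
        stack = uniform_stack()
        stack.n14[:4, :] = 0
        img = ratio_image(stack)
        labels = np.zeros((8, 8), np.int32)
        labels[:4, :] = 1
        labels[4:, :] = 2
        table = roi_stats(img, RoiSet(labels))
        assert table.set_index("label").loc[1, "excluded"]
        assert not table.set_index("label").loc[2, "excluded"]

    def test_misaligned_mask_rejected(self):
        img = ratio_image(uniform_stack())
        with pytest.raises(ValueError):
            roi_stats(img, RoiSet(np.zeros((5, 5), np.int32)))

    def test_distinct_levels_separable_by_anova(self):
        """Pixel ratios of ROIs generated at 0% and 150% above background are
        cleanly distinguished by a one-way ANOVA."""
        from isopulse.stats_report import one_way_anova

        stack = synthesize_mims_fields(
            (30, 64),
            [
                RegionSpec(1, 0.0, ("rect", 2, 2, 28, 30)),
                RegionSpec(2, 150.0, ("rect", 2, 34, 28, 62)),
            ],
            mean_14n_counts=10_000,
            seed=12,
        )
        img = ratio_image(stack)
        groups = [
            img.ratio[(stack.labels == lab) & img.valid] for lab in (1, 2)
        ]
        res = one_way_anova(groups)
        assert res.pvalue < 0.05

    def test_writer_roundtrip(self, tmp_path):
        import tifffile

        stack = uniform_stack()
        img = ratio_image(stack)
        out = tmp_path / "ratio.tif"
        write_ratio_tiff(img, out)
        back = tifffile.imread(out)
        assert back.shape == (2, 8, 8)
        assert back[0, 0, 0] == pytest.approx(0.0037, abs=1e-6)


class TestNucCyto:
    def test_uniform_labeling_ratio_one_not_significant(self):
        from isopulse.experiments import nuc_cyto_experiment

        table, test = nuc_cyto_experiment(nucleus_multiplier=1.0, seed=21)
        ok = table[~table["excluded"]]
        assert ok["nc_ratio"].mean() == pytest.approx(1.0, abs=0.02)
        assert test.pvalue > 0.05

    def test_twofold_nuclear_enrichment_recovered(self):
        from isopulse.experiments import nuc_cyto_experiment

        table, test = nuc_cyto_experiment(
            n_cells=20, dose=10_000, nucleus_multiplier=2.0, seed=9
        )
        ok = table[~table["excluded"]]
        sem = ok["nc_ratio"].std(ddof=1) / np.sqrt(len(ok))
        assert abs(ok["nc_ratio"].mean() - 2.0) < 3 * sem
        assert test.pvalue < 0.05

    def test_single_cell_skips_test(self):
        from isopulse.experiments import nuc_cyto_experiment

        with pytest.warns(UserWarning, match="fewer than 2"):
            table, test = nuc_cyto_experiment(n_cells=1, seed=3)
        assert test is None
        assert len(table) == 1

    def test_cell_without_cytoplasm_excluded(self):
        ratio = np.full((10, 10), 0.0037)
        img = RatioImage(ratio=ratio, valid=np.ones((10, 10), bool))
        cells = np.zeros((10, 10), np.int32)
        cells[2:6, 2:6] = 1
        nuclei = cells.copy()  # nucleus fills the whole cell
        with pytest.warns(UserWarning):
            table, test = nuc_cyto_ratio(img, nuclei, cells)
        assert table.loc[0, "excluded"]
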