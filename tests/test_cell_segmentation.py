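"""Nuclear masking, elevation building and watershed segmentation."""

import numpy as np
import pytest
from scipy import ndimage

from buho import cell_segmentation as seg
from buho import image_io as io
from buho.cell_segmentation import BinaryMask, EmptyMaskError


class TestNuclearMask:
    def test_sixty_percent_rule(self, channel_factory):
        """Pixels at or above 60% of the image maximum become nuclear."""
        data = np.zeros((8, 8))
        data[2, 2] = 200.0
        data[5, 5] = 130.0  # above 0.6 * 200 = 120
        data[6, 6] = 110.0  # below
        mask = seg.make_nuclear_mask(channel_factory(data), 0.6)
        assert mask.pixels[2, 2] and mask.pixels[5, 5]
        assert not mask.pixels[6, 6]

    def test_constant_bright_image_is_all_ones(self, channel_factory):
        mask = seg.make_nuclear_mask(channel_factory(np.full((6, 6), 50.0)), 0.6)
        assert mask.pixels.all()

    def test_two_gaussian_nuclei_give_two_components(self, channel_factory):
        """Only the peak cores of two well-separated nuclei clear the cut."""
        yy, xx = np.mgrid[0:64, 0:64]
        img = 10.0 + 190.0 * (
            np.exp(-(((yy - 20) ** 2 + (xx - 20) ** 2)) / (2 * 4.0**2))
            + np.exp(-(((yy - 44) ** 2 + (xx - 44) ** 2)) / (2 * 4.0**2))
        )
        mask = seg.make_nuclear_mask(channel_factory(img), 0.6)
        _, n = ndimage.label(mask.pixels, structure=np.ones((3, 3)))
        assert n == 2

    def test_empty_field_raises(self, channel_factory):
        with pytest.raises(EmptyMaskError):
            seg.make_nuclear_mask(channel_factory(np.zeros((8, 8))), 0.6)

    def test_holes_are_filled(self, channel_factory):
        data = np.zeros((9, 9))
        data[2:7, 2:7] = 200.0
        data[4, 4] = 0.0  # nucleolar dark spot
        mask = seg.make_nuclear_mask(channel_factory(data), 0.6)
        assert mask.pixels[4, 4]


class TestElevation:
    def test_endpoint_behaviour(self, channel_factory):
        """Nuclei are forced to zero, saturated stain is zero, background is high."""
        foci = channel_factory(np.array([[0.0, 255.0, 40.0]]))
        nuc = BinaryMask(np.array([[0, 0, 1]]), 0.2)
        elev = seg.build_elevation(foci, nuc, gain=2.0, cap=255.0)
        assert elev.pixels[0, 0] == 255.0  # unstained background: highest
        assert elev.pixels[0, 1] == 0.0  # stain at cap: basin floor
        assert elev.pixels[0, 2] == 0.0  # nuclear pixel forced to 0

    def test_gain_boost(self, channel_factory):
        foci = channel_factory(np.array([[50.0]]))
        nuc = BinaryMask(np.array([[0]]), 0.2)
        elev = seg.build_elevation(foci, nuc, gain=2.0, cap=255.0)
        assert elev.pixels[0, 0] == 255.0 - 100.0


def _flood_basin(elevation, start_mask, barrier):
    """Oracle: pixels reachable from the marker without crossing the barrier."""
    reach = start_mask.copy()
    changed = True
    struct = np.ones((3, 3), dtype=bool)
    while changed:
        grown = ndimage.binary_dilation(reach, structure=struct) & ~barrier
        changed = bool((grown & ~reach).any())
        reach = grown | reach
    return reach


class TestWatershed:
    def test_single_nucleus_single_basin(self, channel_factory):
        data = np.full((32, 32), 10.0)
        data[14:18, 14:18] = 250.0
        nuc = seg.make_nuclear_mask(channel_factory(data), 0.6)
        elev = seg.build_elevation(channel_factory(np.full((32, 32), 40.0)), nuc)
        labels = seg.segment_cells(elev, nuc)
        assert labels.n_cells == 1
        assert (labels.labels > 0).sum() == 32 * 32  # no internal ridge

    def test_two_basins_split_at_ridge(self, channel_factory):
        """A bright elevation ridge separates two nuclei into two basins,
        agreeing with a flood-fill oracle on each side of the barrier."""
        side = 64
        foci = np.full((side, side), 200.0)
        foci[:, 31:33] = 0.0  # unstained gap -> elevation ridge
        nuc_img = np.zeros((side, side))
        nuc_img[28:36, 10:18] = 250.0
        nuc_img[28:36, 46:54] = 250.0
        nuc = seg.make_nuclear_mask(channel_factory(nuc_img), 0.6)
        elev = seg.build_elevation(channel_factory(foci), nuc, gain=1.0)
        labels = seg.segment_cells(elev, nuc)
        assert labels.n_cells == 2
        left = labels.labels[32, 10]
        right = labels.labels[32, 50]
        assert left != right and left > 0 and right > 0
        barrier = np.zeros((side, side), bool)
        barrier[:, 31:33] = True
        oracle_left = _flood_basin(elev.pixels, nuc_img > 120, barrier)
        # every pixel the oracle reaches from the left marker side that is
        # left of the barrier must carry the left label (ridge pixels aside)
        lhs = oracle_left & (np.arange(side)[None, :] < 31)
        vals = labels.labels[lhs]
        assert set(vals[vals > 0]) == {left}

    def test_label_count_matches_planted_nuclei(self, small_field):
        imgs, truth = small_field
        nuclear = io.contrast_stretch(io.clip_intensity(imgs.nuclear, 255))
        nuc = seg.make_nuclear_mask(nuclear, 0.6)
        foci = io.wiener_denoise(io.clip_intensity(imgs.foci, 255))
        elev = seg.build_elevation(foci, nuc)
        labels = seg.segment_cells(elev, nuc)
        assert labels.n_cells == len(truth.cells)

    def test_basins_partition_non_ridge_pixels(self, small_field):
        imgs, truth = small_field
        nuclear = io.contrast_stretch(io.clip_intensity(imgs.nuclear, 255))
        nuc = seg.make_nuclear_mask(nuclear, 0.6)
        foci = io.wiener_denoise(io.clip_intensity(imgs.foci, 255))
        labels = seg.segment_cells(seg.build_elevation(foci, nuc), nuc)
        # each nucleus component lies inside exactly one basin
        markers, n = ndimage.label(nuc.pixels, structure=np.ones((3, 3)))
        for k in range(1, n + 1):
            vals = labels.labels[markers == k]
            owners = set(vals[vals > 0])
            assert len(owners) == 1


class TestForegroundAndFilter:
    def test_foreground_frac_zero_disables_filtering(self, channel_factory):
        fg = seg.cell_foreground(channel_factory(np.zeros((4, 4))), None, 0.0)
        assert fg.pixels.all()

    def test_background_pixels_excluded(self, channel_factory):
        data = np.zeros((4, 4))
        data[1, 1] = 100.0
        fg = seg.cell_foreground(channel_factory(data), None, 0.05)
        assert fg.pixels[1, 1]
        assert not fg.pixels[0, 0]

    def test_footprint_overlap_with_truth(self, small_field):
        """Stained-foreground mask recovers the planted cell footprints."""
        imgs, truth = small_field
        stretched = io.contrast_stretch(io.wiener_denoise(io.clip_intensity(imgs.foci, 255)))
        fg = seg.cell_foreground(stretched, None, 0.2)
        planted = truth.cell_labels > 0
        inter = (fg.pixels & planted).sum()
        union = (fg.pixels | planted).sum()
        assert inter / union > 0.9

    def test_small_cell_filter_matches_area_oracle(self, small_field):
        imgs, truth = small_field
        nuclear = io.contrast_stretch(io.clip_intensity(imgs.nuclear, 255))
        nuc = seg.make_nuclear_mask(nuclear, 0.6)
        foci = io.wiener_denoise(io.clip_intensity(imgs.foci, 255))
        labels = seg.segment_cells(seg.build_elevation(foci, nuc), nuc)
        fg = seg.cell_foreground(io.clip_intensity(imgs.foci, 255), labels, 0.05)
        threshold = 80.0  # deliberately high so some cells drop
        filtered = seg.filter_small_cells(labels, threshold, fg)
        px_area = labels.pixel_size_um**2
        expected = {
            cid
            for cid in labels.cell_ids
            if ((labels.labels == cid) & fg.pixels).sum() * px_area >= threshold
        }
        assert set(filtered.cell_ids) == expected

    def test_zero_threshold_is_identity(self, small_field):
        imgs, _ = small_field
        nuclear = io.contrast_stretch(io.clip_intensity(imgs.nuclear, 255))
        nuc = seg.make_nuclear_mask(nuclear, 0.6)
        foci = io.wiener_denoise(io.clip_intensity(imgs.foci, 255))
        labels = seg.segment_cells(seg.build_elevation(foci, nuc), nuc)
        filtered = seg.filter_small_cells(labels, 0.0)
        assert filtered.cell_ids == labels.cell_ids
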