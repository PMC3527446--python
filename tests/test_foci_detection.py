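"""Prototype extraction, normalized cross-correlation, seeding and merging."""

import numpy as np
import pytest

from buho import foci_detection as det
from buho.cell_segmentation import BinaryMask
from buho.foci_detection import Prototype, PrototypeBank, SeedMap


def brute_force_ncc(image, patch):
    """Sliding-window Pearson correlation oracle (loops, no FFT)."""
    ph, pw = patch.shape
    h, w = image.shape
    out = np.full((h, w), np.nan)
    pz = patch - patch.mean()
    pn = np.sqrt((pz**2).sum())
    for r in range(ph // 2, h - (ph - 1 - ph // 2)):
        for c in range(pw // 2, w - (pw - 1 - pw // 2)):
            win = image[r - ph // 2 : r - ph // 2 + ph, c - pw // 2 : c - pw // 2 + pw]
            wz = win - win.mean()
            wn = np.sqrt((wz**2).sum())
            if wn == 0 or pn == 0:
                out[r, c] = 0.0
            else:
                out[r, c] = float((pz * wz).sum() / (pn * wn))
    return out


class TestExtractRotate:
    def test_crop_geometry(self, channel_factory, rng):
        img = channel_factory(rng.uniform(0, 255, (64, 64)))
        p = det.extract_prototype(img, (30, 40), granule_box=5, margin=2)
        assert p.patch.shape == (9, 9)
        assert p.patch[4, 4] == img.pixels[30, 40]
        bare = det.extract_prototype(img, (30, 40), granule_box=5, margin=0)
        assert bare.patch.shape == (5, 5)

    def test_zero_variance_patch_rejected(self, channel_factory):
        img = channel_factory(np.full((32, 32), 9.0))
        with pytest.raises(ValueError, match="variance"):
            det.extract_prototype(img, (16, 16), 5, 2)

    def test_self_match_scores_one_at_extraction_center(self, channel_factory, rng):
        img = channel_factory(rng.uniform(0, 255, (48, 48)))
        p = det.extract_prototype(img, (20, 25), 5, 2)
        cmap = det.normxcorr(img, p)
        assert cmap.values[20, 25] == pytest.approx(1.0, abs=1e-9)

    def test_four_quarter_turns_restore_patch(self, channel_factory, rng):
        img = channel_factory(rng.uniform(0, 255, (32, 32)))
        p = det.extract_prototype(img, (16, 16), 5, 2)
        q = det.rotate_prototype(det.rotate_prototype(p, 2), 2)
        np.testing.assert_array_equal(q.patch, p.patch)
        assert q.rotation_deg == 0

    def test_symmetric_patch_invariant_under_rotation(self):
        yy, xx = np.mgrid[-4:5, -4:5]
        patch = np.exp(-(yy**2 + xx**2) / 8.0)
        p = Prototype(patch, "sym", 0.8)
        r = det.rotate_prototype(p, 1)
        np.testing.assert_allclose(r.patch, p.patch, atol=1e-12)


class TestNormxcorr:
    def test_matches_brute_force_oracle(self, channel_factory, rng):
        image = rng.uniform(0, 255, (24, 24))
        patch = rng.uniform(0, 255, (5, 5))
        cmap = det.normxcorr(channel_factory(image), Prototype(patch, "P", 0.8))
        oracle = brute_force_ncc(image, patch)
        valid = ~np.isnan(oracle)
        np.testing.assert_array_equal(cmap.valid, valid)
        np.testing.assert_allclose(cmap.values[valid], oracle[valid], atol=1e-10)

    def test_affine_intensity_invariance(self, channel_factory, rng):
        image = rng.uniform(10, 100, (24, 24))
        patch = rng.uniform(0, 50, (5, 5))
        p = Prototype(patch, "P", 0.8)
        base = det.normxcorr(channel_factory(image), p)
        scaled = det.normxcorr(channel_factory(3.0 * image + 7.0), p)
        np.testing.assert_allclose(
            scaled.values[scaled.valid], base.values[base.valid], atol=1e-7
        )

    def test_zero_variance_window_scores_zero(self, channel_factory, rng):
        image = np.full((16, 16), 20.0)
        patch = rng.uniform(0, 50, (5, 5))
        cmap = det.normxcorr(channel_factory(image), Prototype(patch, "P", 0.8))
        assert np.all(np.abs(cmap.values[cmap.valid]) < 1e-6)


class TestThresholdSeeds:
    def test_strict_threshold_and_provenance(self):
        values = np.full((5, 5), np.nan)
        valid = np.zeros((5, 5), bool)
        values[2, 2], valid[2, 2] = 0.9, True
        values[2, 3], valid[2, 3] = 0.85, True
        cmap = det.CorrelationMap(values, valid, "IV")
        seeds = det.threshold_seeds(cmap, 0.85)
        assert seeds.n_seeds == 1  # 0.85 itself is not above the threshold
        assert seeds.provenance[(2, 2)] == {("IV", "raw")}

    def test_extreme_threshold_empties_noise_map(self, rng):
        values = rng.uniform(-0.5, 0.5, (20, 20))
        cmap = det.CorrelationMap(values, np.ones((20, 20), bool), "I")
        assert det.threshold_seeds(cmap, 0.999).n_seeds == 0

    def test_matches_elementwise_oracle(self, rng):
        values = rng.uniform(-1, 1, (20, 20))
        valid = rng.random((20, 20)) > 0.2
        cmap = det.CorrelationMap(np.where(valid, values, np.nan), valid, "I")
        seeds = det.threshold_seeds(cmap, 0.3)
        np.testing.assert_array_equal(seeds.pixels, valid & (values > 0.3))


class TestDetectAndMask:
    def test_union_over_prototypes(self, channel_factory, rng):
        image = channel_factory(rng.uniform(0, 255, (40, 40)))
        p1 = det.extract_prototype(image, (10, 10), 5, 2, id="A", similarity_threshold=0.95)
        p2 = det.extract_prototype(image, (30, 30), 5, 2, id="B", similarity_threshold=0.95)
        lone = det.detect_seeds(image, PrototypeBank([p1]), use_sharpened_pass=False)
        both = det.detect_seeds(image, PrototypeBank([p1, p2]), use_sharpened_pass=False)
        s1 = det.detect_seeds(image, PrototypeBank([p2]), use_sharpened_pass=False)
        np.testing.assert_array_equal(both.pixels, lone.pixels | s1.pixels)

    def test_detection_independent_of_bank_order(self, channel_factory, rng):
        image = channel_factory(rng.uniform(0, 255, (40, 40)))
        p1 = det.extract_prototype(image, (10, 10), 5, 2, id="A", similarity_threshold=0.9)
        p2 = det.extract_prototype(image, (30, 30), 5, 2, id="B", similarity_threshold=0.9)
        fwd = det.detect_seeds(image, PrototypeBank([p1, p2]), False)
        rev = det.detect_seeds(image, PrototypeBank([p2, p1]), False)
        np.testing.assert_array_equal(fwd.pixels, rev.pixels)
        assert fwd.provenance == rev.provenance

    def test_sharpened_pass_recovers_faint_blurred_granule(self, channel_factory):
        """A blurred dim granule below the raw threshold is recovered only
        when the unsharp second pass runs."""
        from buho.image_io import unsharp_filter

        yy, xx = np.mgrid[-6:7, -6:7]
        crisp = 12.0 + 30.0 * np.exp(-(yy**2 + xx**2) / (2 * 2.0**2))
        gy, gx = np.mgrid[0:48, 0:48]
        blurred = 30.0 * np.exp(-(((gy - 24) ** 2 + (gx - 24) ** 2)) / (2 * 2.9**2))
        img = channel_factory(np.full((48, 48), 12.0) + blurred)

        raw_peak = det.normxcorr(img, Prototype(crisp, "I", 0.5)).values[24, 24]
        sharp_img = unsharp_filter(img, 0.2)
        sharp_peak = det.normxcorr(sharp_img, Prototype(crisp, "I", 0.5)).values[24, 24]
        # sharpening must genuinely raise the similarity of the blurred focus
        assert sharp_peak > raw_peak + 1e-4
        st = float((raw_peak + sharp_peak) / 2)

        bank = PrototypeBank([Prototype(crisp, "I", st)])
        raw_only = det.detect_seeds(img, bank, use_sharpened_pass=False)
        with_pass = det.detect_seeds(img, bank, use_sharpened_pass=True)
        assert raw_only.n_seeds == 0
        assert with_pass.n_seeds > 0
        assert all(
            p == "sharpened" for tags in with_pass.provenance.values() for _, p in tags
        )

    def test_mask_seeds_elementwise(self, rng):
        pix = rng.random((16, 16)) > 0.7
        seeds = SeedMap(pix, {tuple(p): {("I", "raw")} for p in np.argwhere(pix)})
        nuc = BinaryMask(rng.random((16, 16)) > 0.8, 0.2)
        fg = BinaryMask(rng.random((16, 16)) > 0.3, 0.2)
        out = det.mask_seeds(seeds, nuc, fg)
        np.testing.assert_array_equal(out.pixels, pix & ~nuc.pixels & fg.pixels)
        for pos in out.provenance:
            assert out.pixels[pos]


class TestMergeSeeds:
    @staticmethod
    def _two_seed_objects(offset):
        pix = np.zeros((32, 32), bool)
        a, b = (12, 12), (12 + offset[0], 12 + offset[1])
        pix[a] = pix[b] = True
        seeds = SeedMap(pix, {a: {("I", "raw")}, b: {("II", "raw")}})
        return det.merge_seeds(seeds, pixel_size_um=0.2)

    def test_single_seed_dilates_to_nine_pixels(self):
        pix = np.zeros((16, 16), bool)
        pix[8, 8] = True
        objs = det.merge_seeds(SeedMap(pix, {(8, 8): {("I", "raw")}}), 0.2)
        assert len(objs) == 1
        assert objs[0].pixel_count == 9
        assert objs[0].point == (8, 8)
        assert objs[0].area_um2 == pytest.approx(9 * 0.04)
        assert objs[0].prototype_hits == {"I"}

    def test_merge_distance_three_split_distance_five(self):
        assert len(self._two_seed_objects((0, 3))) == 1
        assert len(self._two_seed_objects((3, 3))) == 1
        assert len(self._two_seed_objects((0, 5))) == 2
        assert len(self._two_seed_objects((5, 5))) == 2

    def test_merged_object_pools_prototype_hits(self):
        objs = self._two_seed_objects((0, 2))
        assert len(objs) == 1
        assert objs[0].prototype_hits == {"I", "II"}

    def test_every_seed_lies_in_exactly_one_object(self, rng):
        pix = rng.random((48, 48)) > 0.92
        seeds = SeedMap(pix, {tuple(p): {("I", "raw")} for p in np.argwhere(pix)})
        objs = det.merge_seeds(seeds, 0.2)
        assert len(objs) <= seeds.n_seeds
        owners = {}
        for obj in objs:
            for r, c in obj.pixel_set:
                owners.setdefault((r, c), []).append(obj.focus_id)
        for p in map(tuple, np.argwhere(pix)):
            assert len(owners[p]) == 1


class TestSizeAndRedundancy:
    def test_reliability_uses_bounding_box_larger_side(self):
        small = det.FocusObject(1, (1, 1), np.argwhere(np.ones((3, 3))), 9, 0.36)
        assert not det.size_reliability(small, 6)
        stretched = det.FocusObject(2, (0, 0), np.argwhere(np.ones((10, 4))), 40, 1.6)
        assert det.size_reliability(stretched, 6)

    def test_reliability_matches_bbox_oracle(self, rng):
        for _ in range(20):
            pts = rng.integers(0, 20, size=(rng.integers(1, 12), 2))
            obj = det.FocusObject(1, tuple(pts[0]), pts, len(pts), 1.0)
            width = max(np.ptp(pts[:, 0]) + 1, np.ptp(pts[:, 1]) + 1)
            assert det.size_reliability(obj, 6) == (width > 6)

    def test_redundancy_matrix_corners(self, bank):
        pts = np.array([[0, 0]])
        objs = [
            det.FocusObject(i, (0, 0), pts, 1, 0.04, prototype_hits={pid})
            for i, pid in enumerate(["I", "II"])
        ]
        mat = det.prototype_redundancy(objs, bank)
        assert mat[0, 0] == 50.0 and mat[1, 1] == 50.0 and mat[1, 0] == 0.0

        all_hit = [
            det.FocusObject(1, (0, 0), pts, 1, 0.04,
                            prototype_hits={p.id for p in bank})
        ]
        mat = det.prototype_redundancy(all_hit, bank)
        tri = np.tril_indices(len(bank))
        assert np.all(mat[tri] == 100.0)

    def test_redundancy_matches_set_intersection_oracle(self, bank, rng):
        ids = [p.id for p in bank]
        objs = []
        for i in range(40):
            hits = {pid for pid in ids if rng.random() < 0.3} or {ids[0]}
            objs.append(det.FocusObject(i, (0, 0), np.array([[0, 0]]), 1, 0.04,
                                        prototype_hits=hits))
        mat = det.prototype_redundancy(objs, bank)
        for i, pi in enumerate(ids):
            for j, pj in enumerate(ids[: i + 1]):
                expect = 100.0 * sum(
                    1 for o in objs if pi in o.prototype_hits and pj in o.prototype_hits
                ) / len(objs)
                assert mat[i, j] == pytest.approx(expect)


class TestBankIO:
    def test_bank_round_trip(self, bank, tmp_path):
        det.save_bank(bank, tmp_path / "bank")
        back = det.load_bank(tmp_path / "bank")
        assert len(back) == len(bank)
        for a, b in zip(bank, back):
            assert a.id == b.id
            assert a.similarity_threshold == pytest.approx(b.similarity_threshold)
            np.testing.assert_allclose(a.patch, b.patch, rtol=1e-6)


class TestRefineSizes:
    def test_halfmax_footprint_of_clean_gaussian(self, channel_factory):
        """FWHM re-segmentation recovers the above-half-max disc of a granule."""
        yy, xx = np.mgrid[0:64, 0:64]
        sigma = 3.0
        prof = np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2)) / (2 * sigma**2))
        img = channel_factory(12.0 + 40.0 * prof)
        seed_px = np.zeros((64, 64), bool)
        seed_px[32, 32] = True
        objs = det.merge_seeds(SeedMap(seed_px, {(32, 32): {("I", "raw")}}), 0.2)
        refined = det.refine_focus_sizes(img, objs)
        expected = int((prof >= 0.5).sum())
        assert refined[0].pixel_count == pytest.approx(expected, rel=0.15)

    def test_flat_image_leaves_object_unchanged(self, channel_factory):
        img = channel_factory(np.full((32, 32), 20.0))
        seed_px = np.zeros((32, 32), bool)
        seed_px[16, 16] = True
        objs = det.merge_seeds(SeedMap(seed_px, {(16, 16): {("I", "raw")}}), 0.2)
        refined = det.refine_focus_sizes(img, objs)
        assert refined[0].pixel_count == objs[0].pixel_count
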