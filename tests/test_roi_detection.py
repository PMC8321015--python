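import logging

import numpy as np
import pytest

from vitimap.roi_detection import (PolygonRoi, detect_patches, manual_patch,
                                   rasterize_roi)

from conftest import bf_detect, bf_rasterize


def square(x0, y0, x1, y1):
    return PolygonRoi.from_list([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


class TestRasterize:
    def test_axis_aligned_square_pixel_count(self):
        mask = rasterize_roi(square(10, 10, 20, 20), 32, 32)
        assert mask.sum() == 121  # 11 x 11, boundary inclusive
        assert np.array_equal(mask, bf_rasterize(square(10, 10, 20, 20).vertices,
                                                 32, 32))

    def test_full_frame_rectangle_sets_everything(self):
        mask = rasterize_roi(square(0, 0, 406, 609), 610, 407)
        assert mask.all()

    def test_polygon_outside_frame_is_an_error(self):
        tri = PolygonRoi.from_list([[100, 100], [110, 100], [105, 110]])
        with pytest.raises(ValueError):
            rasterize_roi(tri, 32, 32)

    def test_fewer_than_three_vertices_rejected(self):
        with pytest.raises(ValueError):
            PolygonRoi.from_list([[0, 0], [5, 5]])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_polygons_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        verts = rng.uniform(1, 30, size=(n, 2))
        roi = PolygonRoi(vertices=verts)
        try:
            mask = rasterize_roi(roi, 32, 32)
        except ValueError:
            assert not bf_rasterize(verts, 32, 32).any()
            return
        assert np.array_equal(mask, bf_rasterize(verts, 32, 32))


class TestDetect:
    @pytest.fixture()
    def graded(self):
        """20x20 image with graded values inside a 5..14 square ROI."""
        img = np.zeros((20, 20))
        img[6:13, 6:13] = 0.3
        img[8:11, 8:11] = 0.8  # ROI maximum
        return img

    def test_adaptive_cutoff_is_threshold_times_roi_max(self, graded):
        mask = detect_patches(graded, [square(5, 5, 14, 14)], 0.5)
        # cutoff = 0.5 * 0.8 = 0.4: only the 0.8 block passes
        assert np.array_equal(mask.pixels, graded >= 0.4)

    def test_threshold_zero_detects_every_roi_pixel(self, graded):
        roi = square(5, 5, 14, 14)
        mask = detect_patches(graded, [roi], 0.0)
        assert np.array_equal(mask.pixels, rasterize_roi(roi, 20, 20))

    def test_threshold_one_keeps_only_the_roi_maximum(self, graded):
        mask = detect_patches(graded, [square(5, 5, 14, 14)], 1.0)
        assert np.array_equal(mask.pixels, graded == 0.8)

    def test_each_roi_uses_its_own_cutoff(self):
        img = np.zeros((20, 40))
        img[5:10, 5:10] = 0.9    # bright region
        img[5:10, 25:30] = 0.3   # dim region, same relative contrast
        img[5:7, 5:7] = 0.45
        img[5:7, 25:27] = 0.15
        rois = [square(4, 4, 11, 11), square(24, 4, 31, 11)]
        mask = detect_patches(img, rois, 0.5)
        # bright ROI cutoff 0.45 keeps 0.45 and 0.9; dim ROI cutoff 0.15
        assert mask.pixels[5, 5] and mask.pixels[8, 8]
        assert mask.pixels[5, 25] and mask.pixels[8, 28]
        # ...but the dim region would vanish under the bright ROI's cutoff
        single = detect_patches(img, [square(4, 4, 31, 11)], 0.5)
        assert not single.pixels[5, 25]

    def test_manual_patch_equals_threshold_zero(self, graded):
        roi = square(5, 5, 14, 14)
        manual = manual_patch(roi, 20, 20)
        auto = detect_patches(graded, [roi], 0.0)
        assert np.array_equal(manual.pixels, auto.pixels)

    def test_empty_roi_list_rejected(self, graded):
        with pytest.raises(ValueError):
            detect_patches(graded, [], 0.5)

    @pytest.mark.parametrize("bad_t", [-0.1, 1.5])
    def test_threshold_out_of_range_rejected(self, graded, bad_t):
        with pytest.raises(ValueError):
            detect_patches(graded, [square(5, 5, 14, 14)], bad_t)

    def test_all_dark_roi_skipped_unless_threshold_zero(self, caplog):
        img = np.zeros((16, 16))
        roi = square(2, 2, 8, 8)
        with caplog.at_level(logging.WARNING):
            mask = detect_patches(img, [roi], 0.5)
        assert not mask.pixels.any()
        assert "zero maximum" in caplog.text
        assert detect_patches(img, [roi], 0.0).pixels.sum() == 49

    def test_provenance_tracks_first_detecting_roi(self, graded):
        mask = detect_patches(graded, [square(5, 5, 14, 14),
                                       square(7, 7, 12, 12)], 0.5)
        assert set(np.unique(mask.provenance[mask.pixels])) == {1}
        assert (mask.provenance[~mask.pixels] == 0).all()


class TestDetectionProperties:
    @pytest.fixture()
    def random_case(self):
        rng = np.random.default_rng(99)
        img = rng.uniform(0, 1, size=(28, 28))
        rois = [PolygonRoi(vertices=rng.uniform(2, 25, size=(5, 2)))
                for _ in range(3)]
        return img, rois

    def test_monotone_in_threshold(self, random_case):
        img, rois = random_case
        prev = detect_patches(img, rois, 0.0).pixels
        for t in np.linspace(0.1, 1.0, 10):
            cur = detect_patches(img, rois, float(t)).pixels
            assert not (cur & ~prev).any()  # shrinking only
            prev = cur

    @pytest.mark.parametrize("c", [0.25, 0.5, 2.0, 4.0])
    def test_scale_invariance(self, random_case, c):
        img, rois = random_case
        a = detect_patches(img, rois, 0.5).pixels
        b = detect_patches(c * img, rois, 0.5).pixels
        assert np.array_equal(a, b)

    def test_locality_outside_rois(self, random_case):
        img, rois = random_case
        union = np.zeros_like(img, dtype=bool)
        for r in rois:
            union |= rasterize_roi(r, *img.shape)
        tampered = img.copy()
        tampered[~union] = 0.999
        assert np.array_equal(detect_patches(img, rois, 0.5).pixels,
                              detect_patches(tampered, rois, 0.5).pixels)

    @pytest.mark.parametrize("seed,t", [(0, 0.5), (1, 0.3), (2, 0.9),
                                        (3, 0.0), (4, 1.0)])
    def test_agrees_with_bruteforce_oracle(self, seed, t):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, size=(24, 24))
        rois = [PolygonRoi(vertices=rng.uniform(1, 22, size=(4, 2)))
                for _ in range(2)]
        got = detect_patches(img, rois, t).pixels
        want = bf_detect(img, [r.vertices for r in rois], t)
        assert np.array_equal(got, want)
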