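"""Li minimum cross-entropy thresholding and ROI correction factors."""

import dataclasses

import numpy as np
import pytest

from dermafluor import (
    DegenerateContrastError,
    GeneratorConfig,
    InvalidInputError,
    correction_factors,
    li_threshold,
    li_threshold_bruteforce,
    make_lesion_image,
    segment_lesion,
)
from dermafluor.roi_segmentation import li_cross_entropy


def exhaustive_minimum(image):
    """Minimum criterion value over all candidate thresholds (oracle)."""
    g = np.unique(np.asarray(image, dtype=float).ravel())
    g[g == 0] = 0.5
    cand = (g[:-1] + g[1:]) / 2.0
    return min(li_cross_entropy(image, t) for t in cand)


def canonical_threshold(image, t):
    """Midpoint between the occupied gray levels straddling ``t``.

    Two thresholds inducing the same partition map to the same canonical
    value, so threshold comparisons become partition comparisons.
    """
    g = np.asarray(image, dtype=float).ravel()
    g[g == 0] = 0.5
    return (g[g < t].max() + g[g >= t].min()) / 2.0


def _lesion_photo(seed, **kw):
    cfg = dataclasses.replace(GeneratorConfig(), **kw)
    return make_lesion_image(cfg, np.random.default_rng(seed))


class TestLiThreshold:
    def test_two_level_image_separates_exactly(self):
        photo, mask = _lesion_photo(0, image_noise_sd=0.0)
        t = li_threshold(photo)
        assert 60 < t < 200
        assert np.array_equal(photo < t, mask)

    def test_iterative_attains_exhaustive_minimum(self):
        for seed in range(10):
            photo, _ = _lesion_photo(seed)
            t_iter = li_threshold(photo)
            # attains the exhaustive criterion minimum ...
            assert li_cross_entropy(photo, t_iter) <= exhaustive_minimum(photo) + 1e-9
            # ... via the same partition as the exhaustive best threshold
            t_brute = li_threshold_bruteforce(photo)
            assert canonical_threshold(photo, t_iter) == canonical_threshold(
                photo, t_brute
            )
            assert np.array_equal(photo < t_iter, photo < t_brute)

    def test_near_exhaustive_on_dense_low_contrast_histograms(self):
        # overlapping populations, every gray level occupied: the continuous
        # fixed point sits within the discretization error of the argmin
        for seed in range(5):
            photo, _ = _lesion_photo(seed, pigment_level=100, skin_level=150,
                                     image_noise_sd=20.0)
            t_iter = li_threshold(photo)
            t_brute = li_threshold_bruteforce(photo)
            assert abs(t_iter - t_brute) <= 2.0
            rel = li_cross_entropy(photo, t_iter) - exhaustive_minimum(photo)
            assert rel <= 1e-4 * abs(exhaustive_minimum(photo))

    def test_matches_skimage_partition(self):
        # independent reference implementation agrees on the segmentation
        skimage_filters = pytest.importorskip("skimage.filters")
        for seed in (3, 4):
            photo, _ = _lesion_photo(seed)
            t_ref = skimage_filters.threshold_li(photo)
            assert np.array_equal(photo < li_threshold(photo), photo < t_ref)

    def test_shift_moves_oracle_threshold_by_shift(self):
        photo, _ = _lesion_photo(0, image_noise_sd=0.0)
        t0 = li_threshold_bruteforce(photo.astype(float))
        t1 = li_threshold_bruteforce(photo.astype(float) + 20.0)
        assert t1 == pytest.approx(t0 + 20.0)
        # the iterative threshold still induces the same partition
        shifted = photo.astype(float) + 20.0
        assert np.array_equal(shifted < li_threshold(shifted),
                              photo < li_threshold(photo))

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateContrastError):
            li_threshold(np.full((10, 10), 7, dtype=np.uint8))


class TestSegmentLesion:
    def test_noise_free_recovers_ground_truth_exactly(self):
        photo, mask = _lesion_photo(1, image_noise_sd=0.0)
        seg = segment_lesion(photo)
        assert seg.contrast_ok
        assert np.array_equal(seg.lesion_mask, mask)

    def test_noisy_default_jaccard_above_090(self):
        for seed in range(5):
            photo, mask = _lesion_photo(seed)
            seg = segment_lesion(photo)
            inter = np.logical_and(seg.lesion_mask, mask).sum()
            union = np.logical_or(seg.lesion_mask, mask).sum()
            assert inter / union >= 0.9

    def test_constant_image_flagged_not_raised(self):
        seg = segment_lesion(np.full((20, 20), 128, dtype=np.uint8))
        assert not seg.contrast_ok and not seg.lesion_mask.any()

    def test_speckle_removed_by_largest_component(self):
        photo = np.full((50, 50), 200, dtype=np.uint8)
        photo[10:30, 10:30] = 60  # lesion
        photo[45, 45] = 60  # isolated dark speckle
        seg = segment_lesion(photo)
        assert seg.lesion_mask[15, 15] and not seg.lesion_mask[45, 45]

    def test_inverted_polarity(self):
        photo = np.full((30, 30), 60, dtype=np.uint8)
        photo[5:15, 5:15] = 200  # bright target
        seg = segment_lesion(photo, invert=True)
        assert seg.lesion_mask[10, 10] and not seg.lesion_mask[0, 0]


class TestCorrectionFactors:
    def test_rect_congruent_with_filled_mask_is_noop(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 5:25] = True
        f = correction_factors(mask, (5, 10, 25, 20))
        assert (f.f_cov, f.f_pig) == (1.0, 1.0)

    def test_whole_image_rect_half_mask(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[:, :20] = True
        f = correction_factors(mask, (0, 0, 40, 20))
        assert (f.f_cov, f.f_pig) == (1.0, 0.5)

    def test_rect_inside_mask(self):
        mask = np.zeros((40, 50), dtype=bool)
        mask[5:30, 5:45] = True  # 25 x 40 = 1000 px
        f = correction_factors(mask, (10, 10, 30, 30))  # 400 px inside
        assert f.f_cov == pytest.approx(0.4)
        assert f.f_pig == pytest.approx(1.0)

    def test_elliptical_lesion_bbox_rect_is_noop(self):
        # Recommended procedure: operator rect = lesion bounding box
        photo, mask = _lesion_photo(2, image_noise_sd=0.0)
        ys, xs = np.nonzero(mask)
        rect = (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
        f = correction_factors(mask, rect)
        assert (f.f_cov, f.f_pig) == (1.0, 1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateContrastError):
            correction_factors(np.zeros((10, 10), dtype=bool), (0, 0, 5, 5))

    def test_out_of_bounds_rect_rejected(self):
        mask = np.ones((10, 10), dtype=bool)
        with pytest.raises(InvalidInputError):
            correction_factors(mask, (0, 0, 11, 5))

    def test_growing_rect_increases_coverage(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        covs = [
            correction_factors(mask, (5, 5, 5 + w, 25)).f_cov
            for w in (5, 10, 15, 20)
        ]
        assert covs == sorted(covs)
        assert all(0 <= c <= 1 for c in covs)
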