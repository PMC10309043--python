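"""Dataset builder: stretch, distance geometry, saturation guarantee."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import membrain as mb
from membrain.dataset import (
    InsufficientAnnotationError,
    PreprocessParams,
    UNLABELED,
    crop_patch,
)


def brute_chessboard_vec(mask: np.ndarray) -> np.ndarray:
    """Exhaustive pairwise-minimum oracle, vectorised: per labeled pixel,
    min over every unlabeled/outside pixel of the Chebyshev distance."""
    h, w = mask.shape
    padded = np.pad(mask, 1, constant_values=False)
    falses = np.argwhere(~padded) - 1
    trues = np.argwhere(mask)
    out = np.zeros((h, w), dtype=int)
    if len(trues) and len(falses):
        d = np.maximum(
            np.abs(trues[:, None, 0] - falses[None, :, 0]),
            np.abs(trues[:, None, 1] - falses[None, :, 1]),
        ).min(axis=1)
        out[trues[:, 0], trues[:, 1]] = d
    return out


def brute_chessboard(mask: np.ndarray) -> np.ndarray:
    """O(n^2) oracle: min Chebyshev distance to any unlabeled/outside pixel."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=int)
    falses = [(r, c) for r in range(-1, h + 1) for c in range(-1, w + 1)
              if not (0 <= r < h and 0 <= c < w) or not mask[r, c]]
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                out[r, c] = min(max(abs(r - fr), abs(c - fc)) for fr, fc in falses)
    return out


class TestStretch:
    def test_endpoints_map_to_0_and_255(self):
        img = np.array([[50, 125, 200]], dtype=np.uint8)
        out = mb.stretch_grayscale(img, PreprocessParams(low=50, high=200))
        assert out[0, 0] == 0 and out[0, 2] == 255

    def test_constant_image_unchanged(self):
        img = np.full((5, 5), 7, np.uint8)
        np.testing.assert_array_equal(mb.stretch_grayscale(img), img)

    def test_two_valued_linear_map(self):
        img = np.array([[10, 20]], dtype=np.uint8)
        out = mb.stretch_grayscale(img, PreprocessParams(low=10, high=20))
        assert out.tolist() == [[0, 255]]

    def test_clipping_outside_anchors(self):
        img = np.array([[0, 100, 200, 255]], dtype=np.uint8)
        out = mb.stretch_grayscale(img, PreprocessParams(low=50, high=250))
        # (100-50)/200*255 = 63.75 -> 64; (200-50)/200*255 = 191.25 -> 191
        assert out.tolist() == [[0, 64, 191, 255]]


class TestSaturatedMask:
    @pytest.mark.parametrize(
        "labels,expect",
        [
            (np.zeros((4, 4), np.uint8), np.ones((4, 4), bool)),
            (np.full((4, 4), UNLABELED, np.uint8), np.zeros((4, 4), bool)),
        ],
        ids=["fully-annotated", "all-unlabeled"],
    )
    def test_extremes(self, labels, expect):
        np.testing.assert_array_equal(mb.saturated_mask(labels), expect)

    def test_checkerboard(self):
        labels = np.indices((6, 6)).sum(0) % 2 * UNLABELED
        np.testing.assert_array_equal(mb.saturated_mask(labels), labels == 0)


class TestChessboardDistance:
    def test_single_true_pixel_has_distance_one(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert mb.chessboard_distance(m)[2, 2] == 1

    def test_all_true_3x3(self):
        d = mb.chessboard_distance(np.ones((3, 3), bool))
        assert d[1, 1] == 2
        assert (d[[0, 0, 2, 2], [0, 2, 0, 2]] == 1).all()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 32), st.integers(4, 32))
    def test_matches_brute_force_oracle(self, seed, h, w):
        mask = np.random.default_rng(seed).random((h, w)) < 0.7
        np.testing.assert_array_equal(mb.chessboard_distance(mask), brute_chessboard(mask))


def patch_is_saturated(mask: np.ndarray, center, s: int) -> bool:
    """Brute-force oracle: the s x s crop lies inside and is fully labeled."""
    r0, c0 = center[0] - s // 2, center[1] - s // 2
    if r0 < 0 or c0 < 0 or r0 + s > mask.shape[0] or c0 + s > mask.shape[1]:
        return False
    return bool(mask[r0 : r0 + s, c0 : c0 + s].all())


class TestValidCenters:
    def test_fully_annotated_10x10_s4_interior_block(self):
        # brute-force derivation: crop rows c-2..c+1 inside and labeled
        # -> centers are rows/cols 2..8, a 7x7 block
        centers = mb.valid_patch_centers(np.ones((10, 10), bool), 4)
        assert len(centers) == 49
        assert centers.min() == 2 and centers.max() == 8
        assert all(patch_is_saturated(np.ones((10, 10), bool), c, 4) for c in centers)

    def test_identity_patch_when_s_equals_image_size(self):
        centers = mb.valid_patch_centers(np.ones((128, 128), bool), 128)
        assert [tuple(c) for c in centers] == [(64, 64)]

    def test_patch_larger_than_image_gives_no_center(self):
        assert len(mb.valid_patch_centers(np.ones((10, 10), bool), 12)) == 0

    def test_hole_excludes_centers_whose_window_contains_it(self):
        # s=2 window of centre c is rows/cols c-1..c, so the hole at (6, 6)
        # invalidates exactly the centres (6..7, 6..7)
        mask = np.ones((12, 12), bool)
        mask[6, 6] = False
        centers = {tuple(c) for c in mb.valid_patch_centers(mask, 2)}
        for r in (6, 7):
            for c in (6, 7):
                assert (r, c) not in centers
        assert (5, 5) in centers and (8, 8) in centers

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([2, 3, 4, 5, 7, 8]))
    def test_every_center_passes_brute_force_patch_scan(self, seed, s):
        mask = np.random.default_rng(seed).random((24, 24)) < 0.85
        for c in mb.valid_patch_centers(mask, s):
            assert patch_is_saturated(mask, c, s)


class TestExtractPatches:
    def test_fully_annotated_draws_are_registered_and_saturated(self):
        rng = np.random.default_rng(5)
        em = rng.integers(0, 256, (512, 512), dtype=np.uint8)
        labels = rng.integers(0, 2, (512, 512), dtype=np.uint8)
        cfg = mb.PatchConfig(patch_size=256, patches_per_image=10, rng_seed=11)
        ds = mb.extract_patches(em, labels, cfg)
        assert len(ds) == 10
        assert ds.em.shape == ds.labels.shape == (10, 256, 256)
        assert not (ds.labels == UNLABELED).any()

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(5)
        em = rng.integers(0, 256, (300, 300), dtype=np.uint8)
        labels = np.zeros((300, 300), np.uint8)
        cfg = mb.PatchConfig(patch_size=128, patches_per_image=5, rng_seed=3,
                             augmentations=("flip", "gaussian_blur"))
        a = mb.extract_patches(em, labels, cfg)
        b = mb.extract_patches(em, labels, cfg)
        np.testing.assert_array_equal(a.em, b.em)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.manifest == b.manifest

    def test_no_rotation_full_patch_is_the_stretched_input(self):
        em = np.random.default_rng(0).integers(0, 256, (128, 128), dtype=np.uint8)
        labels = np.zeros((128, 128), np.uint8)
        cfg = mb.PatchConfig(patch_size=128, patches_per_image=1, rotation=False)
        ds = mb.extract_patches(em, labels, cfg)
        np.testing.assert_array_equal(ds.em[0], mb.stretch_grayscale(em))
        np.testing.assert_array_equal(ds.labels[0], labels)

    def test_insufficient_annotation_raises_informative_error(self):
        em = np.zeros((256, 256), np.uint8)
        labels = np.full((256, 256), UNLABELED, np.uint8)
        labels[:20, :20] = 1
        cfg = mb.PatchConfig(patch_size=128, patches_per_image=1, max_retries=5)
        with pytest.raises(InsufficientAnnotationError, match="patch size"):
            mb.extract_patches(em, labels, cfg)

    def test_saturation_guarantee_under_rotation(self):
        # partial annotation + arbitrary angles: no unlabeled pixel may leak
        rng = np.random.default_rng(2)
        em = rng.integers(0, 256, (300, 300), dtype=np.uint8)
        labels = np.full((300, 300), UNLABELED, np.uint8)
        labels[40:260, 30:270] = rng.integers(0, 2, (220, 240))
        cfg = mb.PatchConfig(patch_size=128, patches_per_image=40, rng_seed=7)
        ds = mb.extract_patches(em, labels, cfg)
        assert not (ds.labels == UNLABELED).any()

    def test_split_fractions(self):
        em = np.zeros((256, 256), np.uint8)
        labels = np.zeros((256, 256), np.uint8)
        cfg = mb.PatchConfig(patch_size=128, patches_per_image=20, rng_seed=1)
        ds = mb.extract_patches(em, labels, cfg)
        assert len(ds.val_idx) == 2 and len(ds.train_idx) == 18
        assert set(ds.val_idx) | set(ds.train_idx) == set(range(20))

    def test_class_frequencies_sum_to_one(self):
        em = np.zeros((256, 256), np.uint8)
        labels = np.random.default_rng(0).integers(0, 2, (256, 256), dtype=np.uint8)
        ds = mb.extract_patches(em, labels, mb.PatchConfig(patch_size=128, patches_per_image=5))
        assert ds.class_frequencies().sum() == pytest.approx(1.0)

    def test_save_load_round_trip(self, tmp_path):
        em = np.random.default_rng(0).integers(0, 256, (256, 256), dtype=np.uint8)
        labels = np.zeros((256, 256), np.uint8)
        ds = mb.extract_patches(em, labels, mb.PatchConfig(patch_size=128, patches_per_image=4))
        ds.save(tmp_path / "d")
        back = mb.PatchDataset.load(tmp_path / "d")
        np.testing.assert_array_equal(back.em, ds.em)
        np.testing.assert_array_equal(back.labels, ds.labels)
        assert back.config == ds.config
        assert back.preprocess == ds.preprocess


class TestAugment:
    def test_double_flip_is_identity(self):
        rng = np.random.default_rng(0)
        em = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        lab = rng.integers(0, 2, (32, 32), dtype=np.uint8)
        for op in ("flip_h", "flip_v"):
            e1, l1 = mb.augment_pair(em, lab, op, rng)
            e2, l2 = mb.augment_pair(e1, l1, op, rng)
            np.testing.assert_array_equal(e2, em)
            np.testing.assert_array_equal(l2, lab)

    def test_flip_moves_both_images_identically(self):
        em = np.arange(16, dtype=np.uint8).reshape(4, 4)
        lab = np.arange(16, dtype=np.uint8).reshape(4, 4)
        e, l = mb.augment_pair(em, lab, "flip_h", np.random.default_rng(0))
        np.testing.assert_array_equal(e, l)

    @pytest.mark.parametrize("op", ["gaussian_blur", "motion_blur", "histogram_equalize"])
    def test_photometric_ops_leave_labels_untouched(self, op):
        rng = np.random.default_rng(1)
        em = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        lab = rng.integers(0, 3, (64, 64), dtype=np.uint8)
        e, l = mb.augment_pair(em, lab, op, rng)
        np.testing.assert_array_equal(l, lab)
        assert e.shape == em.shape and e.dtype == np.uint8

    def test_histogram_equalize_constant_patch_unchanged(self):
        em = np.full((16, 16), 42, np.uint8)
        e, _ = mb.augment_pair(em, em.copy(), "histogram_equalize", np.random.default_rng(0))
        np.testing.assert_array_equal(e, em)

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown augmentation"):
            mb.augment_pair(np.zeros((4, 4), np.uint8), np.zeros((4, 4), np.uint8),
                            "elastic", np.random.default_rng(0))
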