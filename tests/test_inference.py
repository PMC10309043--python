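"""Inference engine: tiling equivalence, mode consistency, purity."""

import json

import numpy as np
import pytest

import membrain as mb
from membrain.dataset import PreprocessParams
from membrain.inference import (
    PredictionRequest,
    ProbabilityBlock,
    categorical_from_prob,
    predict_anchors,
    predict_block,
    predict_volume,
    read_anchor_file,
)
from membrain.nn import UNetConfig, build_unet


@pytest.fixture(scope="module")
def model():
    return build_unet(UNetConfig(depth=2, base_channels=4, n_classes=2), 11)


@pytest.fixture(scope="module")
def fixture_volume(tmp_path_factory):
    """3-section 256x256 fixture volume stored with 128-px tiles (so the
    chunked path exercises a 2x2 tile grid)."""
    root = tmp_path_factory.mktemp("vol")
    em_vol, _ = mb.generate_volume(
        mb.MosaicSpec(rng_seed=6), 3, root / "em", root / "lab",
        drift=1.0, tile_size=128,
    )
    return em_vol


IDENT = PreprocessParams(low=0.0, high=255.0)


class TestPredictBlock:
    def test_output_shape_and_normalization(self, model):
        block = np.random.default_rng(0).integers(0, 256, (2, 256, 256), dtype=np.uint8)
        pb = predict_block(model, block, IDENT)
        assert pb.probs.shape == (2, 2, 256, 256)
        np.testing.assert_allclose(pb.probs.sum(axis=1), 1.0, atol=1e-5)

    def test_side_not_multiple_of_128_rejected(self, model):
        with pytest.raises(ValueError, match="128"):
            predict_block(model, np.zeros((1, 100, 100), np.uint8), IDENT)

    def test_tiling_equivalence(self, model):
        """Per-tile evaluation of a stitched 2x2-tile image equals the
        four independent tile predictions, bit-identically."""
        rng = np.random.default_rng(1)
        big = rng.integers(0, 256, (1, 256, 256), dtype=np.uint8)
        whole = predict_block(model, big, IDENT, tile=128).probs
        for y0 in (0, 128):
            for x0 in (0, 128):
                tile = predict_block(
                    model, big[:, y0 : y0 + 128, x0 : x0 + 128], IDENT, tile=128
                ).probs
                np.testing.assert_array_equal(
                    whole[:, :, y0 : y0 + 128, x0 : x0 + 128], tile
                )


class TestCategorical:
    def test_one_hot_recovered(self):
        probs = np.zeros((1, 3, 2, 2), np.float32)
        probs[0, 2] = 1.0
        assert (categorical_from_prob(ProbabilityBlock(probs, (0, 0, 0))) == 2).all()

    def test_uniform_prob_ties_to_class_zero(self):
        probs = np.full((1, 3, 4, 4), 1 / 3, np.float32)
        assert (categorical_from_prob(ProbabilityBlock(probs, (0, 0, 0))) == 0).all()

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(2)
        probs = rng.random((2, 3, 8, 8)).astype(np.float32)
        got = categorical_from_prob(ProbabilityBlock(probs, (0, 0, 0)))
        brute = np.empty((2, 8, 8), np.uint8)
        for z in range(2):
            for y in range(8):
                for x in range(8):
                    brute[z, y, x] = int(np.argmax(probs[z, :, y, x]))
        np.testing.assert_array_equal(got, brute)


class TestPredictVolume:
    def test_tile_count_and_vsvi(self, model, fixture_volume, tmp_path):
        req = PredictionRequest(mode="whole", preprocess=IDENT)
        class_vol, vsvi_path = predict_volume(model, fixture_volume, req, tmp_path / "out")
        # 3 sections x 2x2 tiles
        assert len(class_vol.existing_tiles()) == 12
        assert vsvi_path.is_file()
        desc = mb.VsviDescriptor.load(vsvi_path)
        for mip, z, r, c in class_vol.existing_tiles():
            assert (class_vol.root / desc.source_url_pattern.format(
                mip=mip, z=z, row=r, col=c)).is_file()

    def test_two_runs_bit_identical(self, model, fixture_volume, tmp_path):
        req = PredictionRequest(mode="whole", preprocess=IDENT)
        out_a, _ = predict_volume(model, fixture_volume, req, tmp_path / "a")
        out_b, _ = predict_volume(model, fixture_volume, req, tmp_path / "b")
        roi = ((0, 0, 0), fixture_volume.shape)
        np.testing.assert_array_equal(out_a.read_roi(roi), out_b.read_roi(roi))

    def test_resume_skips_existing_tiles(self, model, fixture_volume, tmp_path):
        req = PredictionRequest(mode="whole", preprocess=IDENT, resume=True)
        predict_volume(model, fixture_volume, req, tmp_path / "out")
        run1 = json.loads((tmp_path / "out" / "run.json").read_text())
        predict_volume(model, fixture_volume, req, tmp_path / "out")
        run2 = json.loads((tmp_path / "out" / "run.json").read_text())
        assert run1["sections_written"] == 12 and run1["sections_skipped"] == 0
        assert run2["sections_written"] == 0 and run2["sections_skipped"] == 12

    def test_box_agrees_with_whole_on_overlap(self, model, fixture_volume, tmp_path):
        whole, _ = predict_volume(
            model, fixture_volume, PredictionRequest(mode="whole", preprocess=IDENT),
            tmp_path / "whole",
        )
        box_req = PredictionRequest(
            mode="box", roi=((1, 64, 64), (3, 200, 256)), preprocess=IDENT
        )
        box, _ = predict_volume(model, fixture_volume, box_req, tmp_path / "box")
        roi = ((1, 0, 0), (3, 256, 256))  # tile-aligned superset of the box
        np.testing.assert_array_equal(whole.read_roi(roi), box.read_roi(roi))

    def test_output_loads_back_exactly(self, model, fixture_volume, tmp_path):
        req = PredictionRequest(mode="whole", preprocess=IDENT)
        class_vol, _ = predict_volume(model, fixture_volume, req, tmp_path / "out")
        reopened = mb.open_volume(class_vol.root)
        raw = fixture_volume.read_roi(((0, 0, 0), (1, 256, 256)))
        pb = predict_block(model, raw, IDENT, tile=128)
        np.testing.assert_array_equal(
            reopened.read_roi(((0, 0, 0), (1, 256, 256))),
            categorical_from_prob(pb),
        )

    def test_probability_tiles_quantized_to_uint8(self, model, fixture_volume, tmp_path):
        req = PredictionRequest(mode="whole", preprocess=IDENT)
        predict_volume(model, fixture_volume, req, tmp_path / "out")
        pv = mb.open_volume(tmp_path / "out" / "prob_c1")
        q = pv.read_roi(((0, 0, 0), (1, 256, 256)))
        assert q.dtype == np.uint8 and q.max() > 0

    def test_roi_outside_volume_rejected(self, model, fixture_volume, tmp_path):
        req = PredictionRequest(mode="box", roi=((0, 0, 0), (9, 256, 256)),
                                preprocess=IDENT)
        from membrain.store import BoundsError

        with pytest.raises(BoundsError):
            predict_volume(model, fixture_volume, req, tmp_path / "out")


class TestPredictAnchors:
    def test_center_anchor_full_cube(self, model, fixture_volume, tmp_path):
        req = PredictionRequest(mode="anchors", anchors=[(128, 128, 1)], cube=128,
                                preprocess=IDENT)
        res = predict_anchors(model, fixture_volume, req, tmp_path / "anch")
        assert len(res) == 1
        blk = res[0]["block"]
        # z clipped to the 3-section volume, full 128x128 in-plane
        assert blk.probs.shape == (3, 2, 128, 128)
        assert (tmp_path / "anch" / "anchor_000" / "classes.npy").is_file()

    def test_corner_anchor_clipped_and_flagged(self, model, fixture_volume):
        req = PredictionRequest(mode="anchors", anchors=[(0, 0, 0)], cube=128,
                                preprocess=IDENT)
        res = predict_anchors(model, fixture_volume, req)
        assert res[0]["clipped"]
        assert res[0]["block"].probs.shape == (3, 2, 64, 64)

    def test_anchor_agrees_with_whole_volume(self, model, fixture_volume, tmp_path):
        whole, _ = predict_volume(
            model, fixture_volume, PredictionRequest(mode="whole", preprocess=IDENT),
            tmp_path / "w",
        )
        req = PredictionRequest(mode="anchors", anchors=[(100, 90, 1)], cube=128,
                                preprocess=IDENT)
        res = predict_anchors(model, fixture_volume, req)
        (z0, y0, x0), (z1, y1, x1) = res[0]["extent"]
        np.testing.assert_array_equal(
            res[0]["classes"],
            whole.read_roi(((z0, y0, x0), (z1, y1, x1))),
        )

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            PredictionRequest(mode="anchors", anchors=[])

    def test_anchor_file_parsing(self, tmp_path):
        p = tmp_path / "anchors.txt"
        p.write_text("# x y z\n10 20 1\n\n30 40 2  # comment\n")
        assert read_anchor_file(p) == [(10, 20, 1), (30, 40, 2)]
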