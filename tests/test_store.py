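"""Tile store: round trips, chunk traversal, descriptors, pyramids."""

import json

import numpy as np
import pytest
from PIL import Image

from membrain.store import (
    AlignmentError,
    BoundsError,
    ChunkSpec,
    FormatError,
    VsviDescriptor,
    create_volume,
    open_volume,
)


@pytest.fixture()
def small_vol(tmp_path):
    """3-section 256x256 uint8 store with 128-px tiles, fully written."""
    vol = create_volume(tmp_path / "v", (3, 256, 256), tile_size=128)
    rng = np.random.default_rng(0)
    data = rng.integers(0, 256, (3, 256, 256), dtype=np.uint8)
    vol.write_block((0, 0, 0), data)
    return vol, data


class TestRoundTrip:
    def test_write_then_read_identity(self, small_vol):
        vol, data = small_vol
        out = vol.read_roi(((0, 0, 0), (3, 256, 256)))
        np.testing.assert_array_equal(out, data)

    def test_label_dtype_round_trip(self, tmp_path):
        vol = create_volume(tmp_path / "lab", (1, 128, 128), tile_size=128,
                            dtype="uint16", value_semantics="instance-id")
        data = np.arange(128 * 128, dtype=np.uint16).reshape(1, 128, 128)
        vol.write_block((0, 0, 0), data)
        np.testing.assert_array_equal(vol.read_roi(((0, 0, 0), (1, 128, 128))), data)

    def test_reopen_from_descriptor(self, small_vol):
        vol, data = small_vol
        again = open_volume(vol.root)
        np.testing.assert_array_equal(
            again.read_roi(((1, 0, 0), (2, 256, 256))), data[1:2]
        )

    def test_partial_tile_write_pads_with_zero(self, tmp_path):
        vol = create_volume(tmp_path / "v", (1, 128, 128), tile_size=128)
        vol.write_block((0, 0, 0), np.full((1, 100, 100), 9, np.uint8))
        files = list(vol.root.rglob("*.png"))
        assert len(files) == 1
        tile = np.asarray(Image.open(files[0]))
        assert tile.shape == (128, 128)
        assert (tile[:100, :100] == 9).all() and (tile[100:, :] == 0).all()

    def test_partial_overwrite_preserves_other_pixels(self, small_vol):
        vol, data = small_vol
        vol.write_block((0, 0, 0), np.zeros((1, 10, 10), np.uint8))
        out = vol.read_roi(((0, 0, 0), (1, 128, 128)))[0]
        assert (out[:10, :10] == 0).all()
        np.testing.assert_array_equal(out[10:, :], data[0, 10:128, :128])


class TestTilingContract:
    def test_every_tile_file_is_exactly_tile_sized(self, small_vol):
        vol, _ = small_vol
        for p in vol.root.rglob("*.png"):
            assert Image.open(p).size == (128, 128)

    def test_tile_count_by_ceiling_division(self, tmp_path):
        # 3 sections of 2048^2 with 1024 tiles -> 4 tiles/section, 12 total
        vol = create_volume(tmp_path / "v", (3, 2048, 2048))
        vol.write_block((0, 0, 0), np.ones((3, 2048, 2048), np.uint8))
        assert vol.shape == (3, 2048, 2048)
        assert vol.tile_grid(0) == (2, 2)
        assert len(vol.existing_tiles()) == 12

    def test_unaligned_origin_rejected(self, small_vol):
        vol, _ = small_vol
        with pytest.raises(AlignmentError):
            vol.write_block((0, 5, 0), np.zeros((1, 10, 10), np.uint8))

    def test_default_tile_size_is_1024(self, tmp_path):
        vol = create_volume(tmp_path / "v", (1, 1024, 1024))
        vol.write_block((0, 0, 0), np.ones((1, 1024, 1024), np.uint8))
        files = list(vol.root.rglob("*.png"))
        assert len(files) == 1
        assert Image.open(files[0]).size == (1024, 1024)


class TestChunkedReads:
    def test_single_chunk_roi(self, tmp_path):
        vol = create_volume(tmp_path / "v", (16, 128, 128), tile_size=128)
        vol.write_block((0, 0, 0), np.ones((16, 128, 128), np.uint8))
        chunks = list(vol.read_chunks(((0, 0, 0), (16, 128, 128)),
                                      spec=ChunkSpec(z_depth=16, tile=128)))
        assert len(chunks) == 1
        assert chunks[0][1].shape == (16, 128, 128)

    def test_z_chunking_by_ceiling_division(self, tmp_path):
        vol = create_volume(tmp_path / "v", (33, 128, 128), tile_size=128)
        vol.write_block((0, 0, 0), np.zeros((33, 128, 128), np.uint8))
        depths = [b.shape[0] for _, b in vol.read_chunks(
            ((0, 0, 0), (33, 128, 128)), spec=ChunkSpec(z_depth=16, tile=128))]
        assert depths == [16, 16, 1]

    def test_chunk_count_tiles_times_zchunks(self, small_vol):
        vol, _ = small_vol
        chunks = list(vol.read_chunks(((0, 0, 0), (3, 256, 256)),
                                      spec=ChunkSpec(z_depth=16, tile=128)))
        assert len(chunks) == 4  # 2x2 tiles, one z-chunk

    def test_traversal_order_z_innermost_then_x_then_y(self, small_vol):
        vol, _ = small_vol
        origins = [o for o, _ in vol.read_chunks(
            ((0, 0, 0), (3, 256, 256)), spec=ChunkSpec(z_depth=2, tile=128))]
        assert origins == [
            (0, 0, 0), (2, 0, 0), (0, 0, 128), (2, 0, 128),
            (0, 128, 0), (2, 128, 0), (0, 128, 128), (2, 128, 128),
        ]

    def test_partition_property_random_rois(self, small_vol):
        # chunks tile the roi exactly once: reassembly is the identity
        vol, data = small_vol
        rng = np.random.default_rng(7)
        for _ in range(10):
            z0, y0, x0 = rng.integers(0, 2), rng.integers(0, 200), rng.integers(0, 200)
            z1 = rng.integers(z0 + 1, 4)
            y1 = rng.integers(y0 + 1, 257)
            x1 = rng.integers(x0 + 1, 257)
            roi = ((int(z0), int(y0), int(x0)), (int(z1), int(y1), int(x1)))
            out = np.full((z1 - z0, y1 - y0, x1 - x0), 255, np.uint8)
            seen = np.zeros(out.shape, dtype=int)
            for (oz, oy, ox), block in vol.read_chunks(roi, spec=ChunkSpec(z_depth=2, tile=128)):
                dz, dy, dx = block.shape
                out[oz - z0 : oz - z0 + dz, oy - y0 : oy - y0 + dy, ox - x0 : ox - x0 + dx] = block
                seen[oz - z0 : oz - z0 + dz, oy - y0 : oy - y0 + dy, ox - x0 : ox - x0 + dx] += 1
            assert (seen == 1).all(), "chunk traversal must cover the roi exactly once"
            np.testing.assert_array_equal(out, data[z0:z1, y0:y1, x0:x1])

    def test_roi_outside_volume_raises(self, small_vol):
        vol, _ = small_vol
        with pytest.raises(BoundsError):
            list(vol.read_chunks(((0, 0, 0), (4, 256, 256))))


class TestVsvi:
    def test_round_trip_is_identity(self):
        d = VsviDescriptor(depth=3, height=2048, width=2048)
        assert VsviDescriptor.from_json(d.to_json()) == d
        assert VsviDescriptor.from_json(VsviDescriptor.from_json(d.to_json()).to_json()) == d

    def test_tile_size_not_multiple_of_128_rejected(self):
        d = VsviDescriptor(depth=1, height=10, width=10, tile_size=1000)
        with pytest.raises(FormatError, match="128"):
            d.validate()

    def test_missing_field_named_in_error(self):
        raw = json.loads(VsviDescriptor().to_json())
        del raw["tile_size"]
        with pytest.raises(FormatError, match="tile_size"):
            VsviDescriptor.from_json(json.dumps(raw))

    def test_pattern_resolves_written_tile(self, tmp_path):
        vol = create_volume(tmp_path / "v", (1, 128, 128), tile_size=128)
        vol.write_block((0, 0, 0), np.ones((1, 128, 128), np.uint8))
        desc = vol.write_vsvi()
        path = vol.root / desc.source_url_pattern.format(mip=0, z=0, row=0, col=0)
        assert path.is_file()

    def test_empty_volume_has_no_descriptor_to_offer(self, tmp_path):
        vol = create_volume(tmp_path / "v", (1, 128, 128), tile_size=128)
        with pytest.raises(FormatError, match="empty"):
            vol.write_vsvi()

    def test_corrupt_descriptor_rejected(self, tmp_path):
        p = tmp_path / "bad.vsvi"
        p.write_text("{not json")
        with pytest.raises(FormatError, match="JSON"):
            open_volume(p)


class TestMips:
    def test_grayscale_mip_is_block_mean(self, small_vol):
        vol, data = small_vol
        vol.build_mips(1)
        got = vol.read_roi(((0, 0, 0), (3, 128, 128)), mip=1)
        expect = np.rint(
            data.astype(float).reshape(3, 128, 2, 128, 2).mean(axis=(2, 4))
        ).astype(np.uint8)
        np.testing.assert_array_equal(got, expect)

    def test_label_mip_is_stride2_subsample(self, tmp_path):
        vol = create_volume(tmp_path / "lab", (1, 256, 256), tile_size=128,
                            dtype="uint16", value_semantics="instance-id")
        data = np.random.default_rng(1).integers(0, 50, (1, 256, 256)).astype(np.uint16)
        vol.write_block((0, 0, 0), data)
        vol.build_mips(1)
        got = vol.read_roi(((0, 0, 0), (1, 128, 128)), mip=1)
        np.testing.assert_array_equal(got, data[:, ::2, ::2])
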