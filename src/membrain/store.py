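"""Filesystem-backed tile-pyramid volumes with VSVI descriptors.

A :class:`TileVolume` stores a 3D grayscale or label volume as per-section
PNG tiles of a fixed edge length (default 1024 px), organised in an image
pyramid of power-of-two mip levels.  The layout mirrors the chunked storage
contract used by volume-annotation tools: data is traversed z-first in
16-section stacks of single tiles, each tile file has exactly
``tile_size x tile_size`` pixels (edge tiles are zero-padded), and the whole
store is described by a ``.vsvi`` text descriptor in JSON syntax so that a
viewer can resolve every tile from the naming pattern alone.

Coordinates are 0-based ``(z, y, x)`` voxels with half-open ROIs
``((z0, y0, x0), (z1, y1, x1))``; rows index y, columns index x.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from PIL import Image

DEFAULT_TILE_SIZE = 1024
DEFAULT_Z_DEPTH = 16
DEFAULT_NAMING = "mip{mip}/z{z:05d}/r{row:03d}_c{col:03d}.png"
DESCRIPTOR_NAME = "volume.vsvi"

VALUE_SEMANTICS = ("grayscale", "class-index", "probability", "instance-id")
_DTYPES = {"uint8": np.uint8, "uint16": np.uint16}


class FormatError(ValueError):
    """Raised for a missing or malformed VSVI descriptor."""


class AlignmentError(ValueError):
    """Raised when a write origin is not aligned to the tile grid."""


class BoundsError(IndexError):
    """Raised when an ROI falls outside the volume extents."""


def _check_tile_size(tile_size: int, context: str = "tile_size") -> None:
    if tile_size <= 0 or tile_size % 128 != 0:
        raise FormatError(
            f"{context} must be a positive multiple of 128, got {tile_size}"
        )


@dataclass(frozen=True)
class ChunkSpec:
    """Traversal unit for chunked reads: a z-stack of one tile footprint."""

    z_depth: int = DEFAULT_Z_DEPTH
    tile: int = DEFAULT_TILE_SIZE

    def __post_init__(self) -> None:
        if self.z_depth < 1:
            raise ValueError(f"z_depth must be >= 1, got {self.z_depth}")
        _check_tile_size(self.tile, "chunk tile")


@dataclass
class VsviDescriptor:
    """JSON-syntax text descriptor (extension ``.vsvi``) of a tiled volume.

    ``source_url_pattern`` contains ``{mip}``, ``{z}``, ``{row}``, ``{col}``
    placeholders (Python format syntax) resolving each tile file relative to
    the descriptor's directory.
    """

    source_url_pattern: str = DEFAULT_NAMING
    depth: int = 0
    height: int = 0
    width: int = 0
    voxel_size_nm: tuple[float, float, float] = (30.0, 8.0, 8.0)  # (z, y, x)
    tile_size: int = DEFAULT_TILE_SIZE
    mip_min: int = 0
    mip_max: int = 0
    value_semantics: str = "grayscale"
    dtype: str = "uint8"

    _REQUIRED = (
        "source_url_pattern",
        "depth",
        "height",
        "width",
        "voxel_size_nm",
        "tile_size",
        "mip_min",
        "mip_max",
        "value_semantics",
        "dtype",
    )

    def validate(self) -> None:
        _check_tile_size(self.tile_size)
        for name in ("depth", "height", "width"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} must be non-negative")
        if self.mip_min < 0 or self.mip_max < self.mip_min:
            raise FormatError("mip range invalid: require 0 <= mip_min <= mip_max")
        if self.value_semantics not in VALUE_SEMANTICS:
            raise FormatError(
                f"value_semantics must be one of {VALUE_SEMANTICS}, "
                f"got {self.value_semantics!r}"
            )
        if self.dtype not in _DTYPES:
            raise FormatError(f"dtype must be one of {tuple(_DTYPES)}, got {self.dtype!r}")
        for ph in ("{mip", "{z", "{row", "{col"):
            if ph not in self.source_url_pattern:
                raise FormatError(
                    f"source_url_pattern missing placeholder {ph}}}"
                )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["voxel_size_nm"] = list(self.voxel_size_nm)
        return json.dumps(d, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "VsviDescriptor":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"descriptor is not valid JSON: {exc}") from exc
        if not isinstance(raw, dict):
            raise FormatError("descriptor root must be a JSON object")
        missing = [k for k in cls._REQUIRED if k not in raw]
        if missing:
            raise FormatError(f"descriptor missing field(s): {', '.join(missing)}")
        try:
            desc = cls(
                source_url_pattern=str(raw["source_url_pattern"]),
                depth=int(raw["depth"]),
                height=int(raw["height"]),
                width=int(raw["width"]),
                voxel_size_nm=tuple(float(v) for v in raw["voxel_size_nm"]),
                tile_size=int(raw["tile_size"]),
                mip_min=int(raw["mip_min"]),
                mip_max=int(raw["mip_max"]),
                value_semantics=str(raw["value_semantics"]),
                dtype=str(raw["dtype"]),
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"descriptor field has wrong type: {exc}") from exc
        if len(desc.voxel_size_nm) != 3:
            raise FormatError("voxel_size_nm must have exactly 3 entries (z, y, x)")
        desc.validate()
        return desc

    def save(self, path: Path | str) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Path | str) -> "VsviDescriptor":
        p = Path(path)
        if not p.is_file():
            raise FormatError(f"descriptor not found: {p}")
        return cls.from_json(p.read_text())


class TileVolume:
    """Handle on a tile-pyramid store rooted at a directory."""

    def __init__(self, root: Path | str, descriptor: VsviDescriptor, writable: bool = False):
        descriptor.validate()
        self.root = Path(root)
        self.descriptor = descriptor
        self.writable = writable

    # -- metadata ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        d = self.descriptor
        return (d.depth, d.height, d.width)

    @property
    def tile_size(self) -> int:
        return self.descriptor.tile_size

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(_DTYPES[self.descriptor.dtype])

    @property
    def mip_levels(self) -> list[int]:
        d = self.descriptor
        return list(range(d.mip_min, d.mip_max + 1))

    def shape_at(self, mip: int) -> tuple[int, int, int]:
        d, h, w = self.shape
        f = 2**mip
        return (d, math.ceil(h / f), math.ceil(w / f))

    def tile_grid(self, mip: int) -> tuple[int, int]:
        """(rows, cols) of the tile grid at a mip level."""
        _, h, w = self.shape_at(mip)
        return (math.ceil(h / self.tile_size), math.ceil(w / self.tile_size))

    def tile_path(self, mip: int, z: int, row: int, col: int) -> Path:
        rel = self.descriptor.source_url_pattern.format(mip=mip, z=z, row=row, col=col)
        return self.root / rel

    def existing_tiles(self) -> list[tuple[int, int, int, int]]:
        """All (mip, z, row, col) whose tile file exists on disk."""
        out = []
        for mip in self.mip_levels:
            rows, cols = self.tile_grid(mip)
            for z in range(self.shape[0]):
                for r in range(rows):
                    for c in range(cols):
                        if self.tile_path(mip, z, r, c).is_file():
                            out.append((mip, z, r, c))
        return out

    # -- tile I/O ---------------------------------------------------------
    def _load_tile(self, mip: int, z: int, row: int, col: int) -> np.ndarray:
        p = self.tile_path(mip, z, row, col)
        t = self.tile_size
        if not p.is_file():
            return np.zeros((t, t), dtype=self.dtype)
        arr = np.asarray(Image.open(p))
        if arr.shape != (t, t):
            raise FormatError(
                f"tile {p} has shape {arr.shape}, expected {(t, t)}"
            )
        return arr.astype(self.dtype, copy=False)

    def _save_tile(self, mip: int, z: int, row: int, col: int, tile: np.ndarray) -> None:
        p = self.tile_path(mip, z, row, col)
        p.parent.mkdir(parents=True, exist_ok=True)
        if self.dtype == np.uint8:
            img = Image.fromarray(tile.astype(np.uint8), mode="L")
        else:
            img = Image.fromarray(tile.astype(np.uint16))
        img.save(p, format="PNG")

    # -- block I/O --------------------------------------------------------
    def _check_roi(self, roi, mip: int) -> None:
        (z0, y0, x0), (z1, y1, x1) = roi
        d, h, w = self.shape_at(mip)
        if not (0 <= z0 < z1 <= d and 0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise BoundsError(
                f"roi {roi} outside volume extents {(d, h, w)} at mip {mip}"
            )

    def read_roi(self, roi, mip: int = 0) -> np.ndarray:
        """Assemble an arbitrary ROI from tiles; missing tiles read as 0."""
        self._check_roi(roi, mip)
        (z0, y0, x0), (z1, y1, x1) = roi
        t = self.tile_size
        out = np.zeros((z1 - z0, y1 - y0, x1 - x0), dtype=self.dtype)
        for z in range(z0, z1):
            for row in range(y0 // t, (y1 - 1) // t + 1):
                for col in range(x0 // t, (x1 - 1) // t + 1):
                    tile = self._load_tile(mip, z, row, col)
                    ty0, tx0 = row * t, col * t
                    sy0, sy1 = max(y0, ty0), min(y1, ty0 + t)
                    sx0, sx1 = max(x0, tx0), min(x1, tx0 + t)
                    out[z - z0, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = tile[
                        sy0 - ty0 : sy1 - ty0, sx0 - tx0 : sx1 - tx0
                    ]
        return out

    def write_block(self, origin, block: np.ndarray, mip: int = 0) -> None:
        """Write a (dz, dy, dx) block whose (y, x) origin is tile-aligned.

        Each section of the block is split into fixed-size PNG tiles; edge
        tiles are zero-padded to the full tile size and flushed immediately.
        A partial overwrite of an existing tile preserves its other pixels.
        """
        if not self.writable:
            raise PermissionError("volume opened read-only")
        z0, y0, x0 = origin
        t = self.tile_size
        if y0 % t or x0 % t:
            raise AlignmentError(
                f"origin (y={y0}, x={x0}) not aligned to tile grid of {t}"
            )
        block = np.asarray(block)
        if block.ndim == 2:
            block = block[None]
        dz, dy, dx = block.shape
        self._check_roi(((z0, y0, x0), (z0 + dz, y0 + dy, x0 + dx)), mip)
        for iz in range(dz):
            z = z0 + iz
            for row in range(y0 // t, (y0 + dy - 1) // t + 1):
                for col in range(x0 // t, (x0 + dx - 1) // t + 1):
                    ty0, tx0 = row * t, col * t
                    sy1 = min(y0 + dy, ty0 + t)
                    sx1 = min(x0 + dx, tx0 + t)
                    full = (sy1 - ty0 == t) and (sx1 - tx0 == t) and ty0 >= y0 and tx0 >= x0
                    if full:
                        tile = block[iz, ty0 - y0 : ty0 - y0 + t, tx0 - x0 : tx0 - x0 + t]
                    else:
                        tile = self._load_tile(mip, z, row, col).copy()
                        tile[: sy1 - ty0, : sx1 - tx0] = block[
                            iz, ty0 - y0 : sy1 - y0, tx0 - x0 : sx1 - x0
                        ]
                    self._save_tile(mip, z, row, col, tile)

    def read_chunks(
        self, roi, mip: int = 0, spec: ChunkSpec | None = None
    ) -> Iterator[tuple[tuple[int, int, int], np.ndarray]]:
        """Yield (origin, block) chunks covering the ROI exactly once.

        Chunks are z-stacks of ``spec.z_depth`` sections over one tile
        footprint, truncated at ROI edges, ordered z-innermost, then x
        (columns), then y (rows) — the cache-friendly traversal order of
        16-section annotation-tool stacks.
        """
        spec = spec or ChunkSpec(tile=self.tile_size)
        self._check_roi(roi, mip)
        (z0, y0, x0), (z1, y1, x1) = roi
        t, zd = spec.tile, spec.z_depth
        for y in range(y0, y1, t):
            for x in range(x0, x1, t):
                for z in range(z0, z1, zd):
                    sub = ((z, y, x), (min(z + zd, z1), min(y + t, y1), min(x + t, x1)))
                    yield (z, y, x), self.read_roi(sub, mip)

    # -- descriptor / pyramid --------------------------------------------
    def save_descriptor(self) -> Path:
        p = self.root / DESCRIPTOR_NAME
        self.descriptor.save(p)
        return p

    def write_vsvi(self, out: Path | str | None = None, value_semantics: str | None = None) -> VsviDescriptor:
        """Emit the .vsvi descriptor for the tiles currently on disk."""
        if not self.existing_tiles():
            raise FormatError("cannot write a .vsvi for an empty volume (no tiles)")
        desc = dataclasses.replace(self.descriptor)
        if value_semantics is not None:
            desc.value_semantics = value_semantics
        desc.validate()
        desc.save(Path(out) if out is not None else self.root / DESCRIPTOR_NAME)
        self.descriptor = desc
        return desc

    def build_mips(self, up_to: int) -> None:
        """Build mip levels 1..up_to from mip 0.

        Grayscale/probability volumes use 2x2 block means (edge-replicated to
        even size); label volumes use stride-2 nearest subsampling, since
        averaging categorical IDs is meaningless.
        """
        if not self.writable:
            raise PermissionError("volume opened read-only")
        categorical = self.descriptor.value_semantics in ("class-index", "instance-id")
        for mip in range(1, up_to + 1):
            d, h, w = self.shape_at(mip - 1)
            for z in range(d):
                sec = self.read_roi(((z, 0, 0), (z + 1, h, w)), mip - 1)[0]
                if categorical:
                    down = sec[::2, ::2]
                else:
                    eh, ew = h + h % 2, w + w % 2
                    pad = np.pad(sec.astype(np.float64), ((0, eh - h), (0, ew - w)), mode="edge")
                    down = pad.reshape(eh // 2, 2, ew // 2, 2).mean(axis=(1, 3))
                    down = np.rint(down).astype(self.dtype)
                self.descriptor.mip_max = max(self.descriptor.mip_max, mip)
                self.write_block((z, 0, 0), down[None], mip=mip)
        self.save_descriptor()

    def validate_store(self) -> int:
        """Check every existing tile file; return the number checked."""
        n = 0
        for mip, z, r, c in self.existing_tiles():
            self._load_tile(mip, z, r, c)
            n += 1
        return n


def create_volume(
    root: Path | str,
    shape: tuple[int, int, int],
    tile_size: int = DEFAULT_TILE_SIZE,
    dtype: str = "uint8",
    value_semantics: str = "grayscale",
    naming_scheme: str = DEFAULT_NAMING,
    voxel_size_nm: tuple[float, float, float] = (30.0, 8.0, 8.0),
) -> TileVolume:
    """Create a new writable tile store (directory layout made lazily)."""
    depth, height, width = shape
    desc = VsviDescriptor(
        source_url_pattern=naming_scheme,
        depth=depth,
        height=height,
        width=width,
        voxel_size_nm=tuple(voxel_size_nm),
        tile_size=tile_size,
        value_semantics=value_semantics,
        dtype=dtype,
    )
    desc.validate()
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    vol = TileVolume(root, desc, writable=True)
    vol.save_descriptor()
    return vol


def open_volume(path: Path | str, mode: str = "read", **create_kwargs) -> TileVolume:
    """Open a tile store from its directory or .vsvi descriptor path.

    ``mode="write"`` on a missing store creates it, in which case a ``shape``
    keyword (and optionally tile_size/dtype/...) must be supplied.
    """
    if mode not in ("read", "write"):
        raise ValueError(f"mode must be 'read' or 'write', got {mode!r}")
    p = Path(path)
    if p.is_file() or p.suffix == ".vsvi":
        desc_path, root = p, p.parent
    else:
        desc_path, root = p / DESCRIPTOR_NAME, p
    if desc_path.is_file():
        desc = VsviDescriptor.load(desc_path)
        return TileVolume(root, desc, writable=(mode == "write"))
    if mode == "write" and "shape" in create_kwargs:
        return create_volume(root, **create_kwargs)
    raise FormatError(f"no descriptor at {desc_path}")
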