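"""Chunked tiled prediction over tile-store volumes.

Whole-volume, boxed-ROI and anchor-point prediction all evaluate the
network on the *global* tile grid of the input volume (16-section z-chunks
of one tile footprint, traversed z-first), so overlapping regions across
the three modes agree bit-exactly and two identical runs are bit-identical.
Tiles are predicted independently with no overlap or blending — each
1024 x 1024 (or configured) tile is a valid network input because training
patches are multiples of 128 px.  Edge tiles are zero-padded to the full
tile footprint before the forward pass, exactly as the store pads them on
disk.

Outputs are written back through the tile store: a categorical class-index
volume (uint8 PNG tiles) plus optional per-class probability volumes
(probabilities scaled [0,1] -> [0,255]), each with its own ``.vsvi``
descriptor, and a ``run.json`` provenance record.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import PreprocessParams, stretch_grayscale
from .nn.unet import UNet
from .store import ChunkSpec, TileVolume, create_volume


@dataclass
class ProbabilityBlock:
    """Per-pixel per-class probabilities for a z-stack, with its origin in
    volume coordinates.  Axis order (z, class, y, x); class-sums are 1."""

    probs: np.ndarray
    origin: tuple[int, int, int]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]


@dataclass
class PredictionRequest:
    """One of three prediction modalities.

    mode="whole": the full volume; mode="box": ``roi`` (half-open 3D box);
    mode="anchors": cubes of side ``cube`` centred on ``anchors`` (x, y, z)
    points.  ``mip`` selects the pyramid level, which should match the
    resolution the network was trained at.  ``preprocess`` carries the
    grayscale-stretch anchors persisted with the training dataset.
    """

    mode: str = "whole"
    roi: tuple | None = None
    anchors: list[tuple[int, int, int]] | None = None
    cube: int = 256
    mip: int = 0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    write_probabilities: bool = True
    resume: bool = False
    chunk: ChunkSpec | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("whole", "box", "anchors"):
            raise ValueError(f"mode must be whole|box|anchors, got {self.mode!r}")
        if self.mode == "box" and self.roi is None:
            raise ValueError("box mode requires roi")
        if self.mode == "anchors":
            if not self.anchors:
                raise ValueError("anchors mode requires a non-empty anchor list")
            if self.cube < 128 or self.cube % 128 != 0:
                raise ValueError(f"cube size must be a multiple of 128, got {self.cube}")


def categorical_from_prob(prob: ProbabilityBlock | np.ndarray) -> np.ndarray:
    """Argmax class map; ties break toward the lower class index."""
    p = prob.probs if isinstance(prob, ProbabilityBlock) else np.asarray(prob)
    return p.argmax(axis=-3).astype(np.uint8)


def predict_block(
    model: UNet,
    block: np.ndarray,
    preprocess: PreprocessParams | None = None,
    tile: int = 1024,
    origin: tuple[int, int, int] = (0, 0, 0),
) -> ProbabilityBlock:
    """Stretch grayscale with the stored params, then predict per section.

    Blocks larger than ``tile`` are evaluated independently per tile (the
    prediction of a stitched image therefore equals the stitching of
    per-tile predictions under the same tiling).  Sides must be multiples
    of 128.
    """
    block = np.asarray(block)
    if block.ndim == 2:
        block = block[None]
    dz, dy, dx = block.shape
    if dy % 128 or dx % 128:
        raise ValueError(f"block sides {(dy, dx)} must be multiples of 128")
    stretched = stretch_grayscale(block, (preprocess or PreprocessParams()).resolve(block))
    out = np.empty((dz, model.config.n_classes, dy, dx), dtype=np.float32)
    for y0 in range(0, dy, tile):
        for x0 in range(0, dx, tile):
            sub = stretched[:, y0 : y0 + tile, x0 : x0 + tile]
            probs = model.forward(sub.astype(np.float32) / 255.0)
            out[:, :, y0 : y0 + sub.shape[1], x0 : x0 + sub.shape[2]] = probs
    return ProbabilityBlock(out, origin)


def _fixed_preprocess(p: PreprocessParams) -> PreprocessParams:
    """Pin unresolved stretch anchors to the identity map (0, 255).

    Volume prediction must be a pure function of (model, volume, request);
    resolving percentile anchors per chunk would make the stretch depend on
    the traversal, so anchors not persisted from the training dataset fall
    back to no-op stretching.
    """
    return PreprocessParams(
        p.low_percentile,
        p.high_percentile,
        p.low if p.low is not None else 0.0,
        p.high if p.high is not None else 255.0,
    )


def _model_hash(model: UNet) -> str:
    h = hashlib.sha256()
    for name in sorted(model.params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(model.params[name]).tobytes())
    return h.hexdigest()[:16]


class _OutputStores:
    """Lazy class-index + per-class probability stores under one root."""

    def __init__(self, out_dir: Path, shape, tile_size, n_classes, write_probs):
        self.root = Path(out_dir)
        self.classes = create_volume(
            self.root / "classes", shape, tile_size=tile_size,
            dtype="uint8", value_semantics="class-index",
        )
        self.probs = [
            create_volume(
                self.root / f"prob_c{k}", shape, tile_size=tile_size,
                dtype="uint8", value_semantics="probability",
            )
            for k in range(n_classes)
        ] if write_probs else []

    def tile_written(self, z, row, col) -> bool:
        return self.classes.tile_path(0, z, row, col).is_file()

    def write(self, origin, pb: ProbabilityBlock) -> None:
        classmap = categorical_from_prob(pb)
        self.classes.write_block(origin, classmap)
        for k, pv in enumerate(self.probs):
            q = np.clip(np.rint(pb.probs[:, k] * 255.0), 0, 255).astype(np.uint8)
            pv.write_block(origin, q)

    def finalize(self) -> None:
        self.classes.write_vsvi(self.root / "classes.vsvi")
        for k, pv in enumerate(self.probs):
            pv.write_vsvi(self.root / f"prob_c{k}.vsvi")


def _tile_range(lo: int, hi: int, t: int) -> range:
    return range(lo // t, (hi - 1) // t + 1)


def _predict_tile_stack(model, vol, req, z0, z1, row, col):
    """Evaluate one global-grid tile footprint over [z0, z1); zero-padded
    at the volume edge to the full (multiple-of-128) tile size."""
    t = vol.tile_size
    _, h, w = vol.shape_at(req.mip)
    y0, x0 = row * t, col * t
    y1, x1 = min(y0 + t, h), min(x0 + t, w)
    raw = vol.read_roi(((z0, y0, x0), (z1, y1, x1)), req.mip)
    if raw.shape[1:] != (t, t):
        pad = np.zeros((raw.shape[0], t, t), dtype=raw.dtype)
        pad[:, : raw.shape[1], : raw.shape[2]] = raw
        raw = pad
    return predict_block(model, raw, req.preprocess, tile=t, origin=(z0, y0, x0))


def predict_volume(
    model: UNet, vol: TileVolume, req: PredictionRequest, out_dir: Path | str
) -> tuple[TileVolume, Path]:
    """Predict a whole volume or a boxed ROI, writing viewer-loadable tiles.

    The prediction covers the tile-aligned superset of the requested ROI
    (whole tiles are the unit of work and of output).  With
    ``req.resume=True``, tiles whose class-index file already exists are
    skipped.  Returns the class-index volume and the path of its ``.vsvi``.
    """
    if req.mode == "anchors":
        raise ValueError("use predict_anchors for anchor-mode requests")
    import dataclasses as _dc

    req = _dc.replace(req, preprocess=_fixed_preprocess(req.preprocess))
    d, h, w = vol.shape_at(req.mip)
    roi = req.roi if req.mode == "box" else ((0, 0, 0), (d, h, w))
    vol._check_roi(roi, req.mip)
    (z0, y0, x0), (z1, y1, x1) = roi
    t = vol.tile_size
    spec = req.chunk or ChunkSpec(tile=t)

    out = _OutputStores(
        Path(out_dir), (d, h, w), t, model.config.n_classes, req.write_probabilities
    )
    t_start = time.time()
    n_written = n_skipped = 0
    for row in _tile_range(y0, y1, t):
        for col in _tile_range(x0, x1, t):
            for zc in range(z0, z1, spec.z_depth):
                zc1 = min(zc + spec.z_depth, z1)
                if req.resume and all(
                    out.tile_written(z, row, col) for z in range(zc, zc1)
                ):
                    n_skipped += zc1 - zc
                    continue
                pb = _predict_tile_stack(model, vol, req, zc, zc1, row, col)
                out.write((zc, row * t, col * t), pb)
                n_written += zc1 - zc
    out.finalize()

    run = {
        "model_hash": _model_hash(model),
        "request": {
            "mode": req.mode, "roi": roi, "mip": req.mip,
            "preprocess": asdict(req.preprocess),
        },
        "tile_size": t,
        "z_depth": spec.z_depth,
        "sections_written": n_written,
        "sections_skipped": n_skipped,
        "elapsed_s": round(time.time() - t_start, 3),
    }
    (Path(out_dir) / "run.json").write_text(json.dumps(run, indent=2))
    return out.classes, Path(out_dir) / "classes.vsvi"


def predict_anchors(
    model: UNet,
    vol: TileVolume,
    req: PredictionRequest,
    out_dir: Path | str | None = None,
) -> list[dict]:
    """Predict cubes centred on anchor points; clipped at volume edges.

    Each anchor yields a dict with the clipped probability block, its class
    map, the requested vs clipped extents, and a ``clipped`` flag; blocks
    are also written under per-anchor subdirectories when ``out_dir`` is
    given.  Predictions agree exactly with whole-volume output because the
    same global-tile evaluation underlies both.
    """
    if req.mode != "anchors":
        raise ValueError("predict_anchors requires an anchors-mode request")
    import dataclasses as _dc

    req = _dc.replace(req, preprocess=_fixed_preprocess(req.preprocess))
    d, h, w = vol.shape_at(req.mip)
    t = vol.tile_size
    half = req.cube // 2
    results = []
    for idx, (ax, ay, az) in enumerate(req.anchors):
        if not (0 <= az < d and 0 <= ay < h and 0 <= ax < w):
            raise IndexError(f"anchor {idx} at {(ax, ay, az)} outside volume {(d, h, w)}")
        want = (
            (az - half, ay - half, ax - half),
            (az + half, ay + half, ax + half),
        )
        got = (
            (max(want[0][0], 0), max(want[0][1], 0), max(want[0][2], 0)),
            (min(want[1][0], d), min(want[1][1], h), min(want[1][2], w)),
        )
        (gz0, gy0, gx0), (gz1, gy1, gx1) = got
        probs = np.zeros(
            (gz1 - gz0, model.config.n_classes, gy1 - gy0, gx1 - gx0), dtype=np.float32
        )
        for row in _tile_range(gy0, gy1, t):
            for col in _tile_range(gx0, gx1, t):
                pb = _predict_tile_stack(model, vol, req, gz0, gz1, row, col)
                ty0, tx0 = row * t, col * t
                sy0, sy1 = max(gy0, ty0), min(gy1, ty0 + t)
                sx0, sx1 = max(gx0, tx0), min(gx1, tx0 + t)
                probs[:, :, sy0 - gy0 : sy1 - gy0, sx0 - gx0 : sx1 - gx0] = pb.probs[
                    :, :, sy0 - ty0 : sy1 - ty0, sx0 - tx0 : sx1 - tx0
                ]
        block = ProbabilityBlock(probs, (gz0, gy0, gx0))
        entry = {
            "anchor": (ax, ay, az),
            "requested": want,
            "extent": got,
            "clipped": want != got,
            "block": block,
            "classes": categorical_from_prob(block),
        }
        results.append(entry)
        if out_dir is not None:
            sub = Path(out_dir) / f"anchor_{idx:03d}"
            sub.mkdir(parents=True, exist_ok=True)
            np.save(sub / "probabilities.npy", probs)
            np.save(sub / "classes.npy", entry["classes"])
    if out_dir is not None:
        manifest = [
            {k: v for k, v in e.items() if k not in ("block", "classes")}
            for e in results
        ]
        (Path(out_dir) / "anchors.json").write_text(json.dumps(manifest, indent=2))
    return results


def read_anchor_file(path: Path | str) -> list[tuple[int, int, int]]:
    """Parse whitespace-separated ``x y z`` anchor coordinates, one per
    line; blank lines and ``#`` comments are skipped."""
    anchors = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 'x y z', got {line!r}")
        anchors.append(tuple(int(float(v)) for v in parts))
    return anchors
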