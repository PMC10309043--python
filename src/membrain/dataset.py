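"""Training-dataset construction from partially annotated EM sections.

Ground truth for EM segmentation is rarely painted wall-to-wall: an
annotator saturates an arbitrarily shaped region of a section and leaves the
rest untouched.  This module turns such pairs (EM image, partial label
image) into an augmented set of pixel-registered training patches whose
label side is guaranteed to be fully annotated ("saturated"), even under
random rotation by any angle.

The trick is the chessboard (Chebyshev, L-infinity) distance transform of
the saturated mask: a pixel whose distance to the nearest unlabeled pixel
is at least ``s // 2 + 1`` carries a fully labeled Chebyshev ball of radius
``s // 2``, so the axis-aligned s x s patch centred there is saturated by
construction.  Rotation is applied to the full images *before* the distance
transform is recomputed, so rotation-introduced void corners are treated as
unlabeled and can never leak into a patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

from .augment import AUGMENTATIONS, augment_pair

UNLABELED = 255  # sentinel class id for pixels without ground truth


class InsufficientAnnotationError(RuntimeError):
    """No patch of the requested size fits in the saturated region."""


# ---------------------------------------------------------------------------
# grayscale preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessParams:
    """Grayscale stretch anchors, persisted so inference can reapply the
    exact correction used while building the training set.

    If ``low``/``high`` are None they are computed per image from the
    percentile anchors and recorded back into the manifest.
    """

    low_percentile: float = 1.0
    high_percentile: float = 99.0
    low: float | None = None
    high: float | None = None

    def resolve(self, image: np.ndarray) -> "PreprocessParams":
        low = self.low if self.low is not None else float(np.percentile(image, self.low_percentile))
        high = self.high if self.high is not None else float(np.percentile(image, self.high_percentile))
        return PreprocessParams(self.low_percentile, self.high_percentile, low, high)


def stretch_grayscale(image: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Linearly stretch gray values so [low, high] maps onto [0, 255].

    Pixels at/below the low anchor map to 0, at/above the high anchor to
    255.  Degenerate images (high <= low, e.g. constant input) are returned
    unchanged.
    """
    params = (params or PreprocessParams()).resolve(image)
    if params.high <= params.low:
        return image.astype(np.uint8, copy=True)
    x = image.astype(np.float64)
    y = (x - params.low) * (255.0 / (params.high - params.low))
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# saturation geometry
# ---------------------------------------------------------------------------

def saturated_mask(labels: np.ndarray, unlabeled_value: int = UNLABELED) -> np.ndarray:
    """True exactly where a ground-truth label is present."""
    return np.asarray(labels) != unlabeled_value


def chessboard_distance(mask: np.ndarray) -> np.ndarray:
    """Chebyshev distance from each labeled pixel to the nearest unlabeled
    pixel, with everything outside the image counting as unlabeled.

    Unlabeled pixels get 0; a labeled pixel bordering the image edge gets 1.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndi.distance_transform_cdt(padded, metric="chessboard")
    return dist[1:-1, 1:-1].astype(np.int32)


def valid_patch_centers(mask: np.ndarray, s: int) -> np.ndarray:
    """Pixels around which an axis-aligned s x s patch is fully labeled.

    The patch centred at c covers rows/cols ``c - s//2 .. c - s//2 + s - 1``
    (everything outside the image counts as unlabeled).  For odd s this is
    exactly the chessboard-distance criterion ``dist(c) >= ceil(s/2)``: the
    window is the Chebyshev ball of radius (s-1)/2.  For even s the window
    sits half a pixel off-centre, so the equivalent erosion is computed
    with a square min-filter of the same alignment.  Returns an (n, 2)
    array of (row, col) coordinates.
    """
    if s < 1:
        raise ValueError(f"patch size must be >= 1, got {s}")
    mask = np.asarray(mask, dtype=bool)
    if s % 2 == 1:
        return np.argwhere(chessboard_distance(mask) >= (s + 1) // 2)
    ok = ndi.minimum_filter(mask, size=s, mode="constant", cval=False)
    return np.argwhere(ok)


def crop_patch(image: np.ndarray, center: tuple[int, int], s: int) -> np.ndarray:
    r, c = center
    r0, c0 = r - s // 2, c - s // 2
    return image[r0 : r0 + s, c0 : c0 + s]


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

@dataclass
class PatchConfig:
    """Knobs of dataset construction.

    patch_size must be a positive multiple of 128 so that a standard
    encoder-decoder network (and tiled 1024-px inference) accepts the
    patches without padding.
    """

    patch_size: int = 256
    patches_per_image: int = 100
    rotation: bool = True
    augmentations: tuple[str, ...] = ()
    augment_probability: float = 0.5
    n_classes: int = 2
    val_fraction: float = 0.1
    max_retries: int = 25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 128 or self.patch_size % 128 != 0:
            raise ValueError(
                f"patch_size must be a multiple of 128 and >= 128, got {self.patch_size}"
            )
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        unknown = set(self.augmentations) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentation(s): {sorted(unknown)}")


@dataclass
class PatchDataset:
    """Paired EM / label patches plus the provenance needed to reproduce
    and to reapply preprocessing at inference time."""

    em: np.ndarray            # (n, s, s) uint8
    labels: np.ndarray        # (n, s, s) uint8 class ids, UNLABELED = no GT
    manifest: list[dict]
    config: PatchConfig
    preprocess: PreprocessParams
    train_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    val_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return len(self.em)

    def class_frequencies(self) -> np.ndarray:
        counts = np.zeros(self.config.n_classes, dtype=np.int64)
        for k in range(self.config.n_classes):
            counts[k] = int((self.labels == k).sum())
        return counts / counts.sum()

    def subset(self, idx: np.ndarray) -> "PatchDataset":
        idx = np.asarray(idx, dtype=int)
        return PatchDataset(
            em=self.em[idx],
            labels=self.labels[idx],
            manifest=[self.manifest[i] for i in idx],
            config=self.config,
            preprocess=self.preprocess,
        )

    def save(self, out_dir: Path | str) -> None:
        out = Path(out_dir)
        (out / "em").mkdir(parents=True, exist_ok=True)
        (out / "labels").mkdir(parents=True, exist_ok=True)
        for i in range(len(self)):
            Image.fromarray(self.em[i], mode="L").save(out / "em" / f"{i:06d}.png")
            Image.fromarray(self.labels[i], mode="L").save(out / "labels" / f"{i:06d}.png")
        meta = {
            "n_patches": len(self),
            "config": asdict(self.config),
            "preprocess": asdict(self.preprocess),
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "manifest": self.manifest,
        }
        meta["config"]["augmentations"] = list(self.config.augmentations)
        (out / "manifest.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, src_dir: Path | str) -> "PatchDataset":
        src = Path(src_dir)
        meta = json.loads((src / "manifest.json").read_text())
        n = meta["n_patches"]
        em = np.stack(
            [np.asarray(Image.open(src / "em" / f"{i:06d}.png")) for i in range(n)]
        )
        labels = np.stack(
            [np.asarray(Image.open(src / "labels" / f"{i:06d}.png")) for i in range(n)]
        )
        cfg_raw = dict(meta["config"])
        cfg_raw["augmentations"] = tuple(cfg_raw["augmentations"])
        return cls(
            em=em,
            labels=labels,
            manifest=meta["manifest"],
            config=PatchConfig(**cfg_raw),
            preprocess=PreprocessParams(**meta["preprocess"]),
            train_idx=np.asarray(meta["train_idx"], dtype=int),
            val_idx=np.asarray(meta["val_idx"], dtype=int),
        )


def _rotate_pair(
    em: np.ndarray, labels: np.ndarray, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate about the image centre: bilinear for EM, nearest for labels.

    Void corners introduced by the rotation are filled with UNLABELED on the
    label side (and 0 on the EM side) so they can never enter a patch.
    """
    if angle_deg % 360.0 == 0.0:
        return em.copy(), labels.copy()
    em_r = ndi.rotate(
        em.astype(np.float32), angle_deg, reshape=False, order=1,
        mode="constant", cval=0.0,
    )
    em_r = np.clip(np.rint(em_r), 0, 255).astype(np.uint8)
    lab_r = ndi.rotate(
        labels, angle_deg, reshape=False, order=0,
        mode="constant", cval=UNLABELED,
    )
    return em_r, lab_r.astype(labels.dtype)


def extract_patches(
    em: np.ndarray,
    labels: np.ndarray,
    cfg: PatchConfig,
    rng: np.random.Generator | None = None,
    preprocess: PreprocessParams | None = None,
) -> PatchDataset:
    """Draw rotation-aware, saturation-guaranteed training patches.

    Per draw: sample an angle uniformly in [0, 360), rotate both images,
    recompute the saturated mask and its chessboard distance on the rotated
    labels, sample a valid centre uniformly, crop the registered pair, then
    apply each configured augmentation with the configured probability.
    Deterministic given ``cfg.rng_seed``.
    """
    em = np.asarray(em)
    labels = np.asarray(labels)
    if em.shape != labels.shape:
        raise ValueError(f"em {em.shape} and labels {labels.shape} differ in footprint")
    if not saturated_mask(labels).any():
        raise InsufficientAnnotationError("label image contains no annotation at all")
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    preprocess = (preprocess or PreprocessParams()).resolve(em)
    em = stretch_grayscale(em, preprocess)

    s = cfg.patch_size
    em_patches: list[np.ndarray] = []
    lab_patches: list[np.ndarray] = []
    manifest: list[dict] = []
    failures = 0
    while len(em_patches) < cfg.patches_per_image:
        angle = float(rng.uniform(0.0, 360.0)) if cfg.rotation else 0.0
        em_r, lab_r = _rotate_pair(em, labels, angle)
        centers = valid_patch_centers(saturated_mask(lab_r), s)
        if len(centers) == 0:
            failures += 1
            if failures > cfg.max_retries:
                raise InsufficientAnnotationError(
                    f"insufficient saturated annotation for patch size {s} "
                    f"(no valid centre after {failures} sampled rotations)"
                )
            if not cfg.rotation:
                raise InsufficientAnnotationError(
                    f"insufficient saturated annotation for patch size {s}"
                )
            continue
        center = tuple(int(v) for v in centers[rng.integers(len(centers))])
        ep = crop_patch(em_r, center, s).copy()
        lp = crop_patch(lab_r, center, s).copy()
        applied = []
        for op in cfg.augmentations:
            if rng.random() < cfg.augment_probability:
                ep, lp = augment_pair(ep, lp, op, rng)
                applied.append(op)
        em_patches.append(ep)
        lab_patches.append(lp.astype(np.uint8))
        manifest.append(
            {"center": list(center), "angle_deg": angle, "augmentations": applied}
        )

    ds = PatchDataset(
        em=np.stack(em_patches),
        labels=np.stack(lab_patches),
        manifest=manifest,
        config=cfg,
        preprocess=preprocess,
    )
    n = len(ds)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    ds.val_idx = np.sort(perm[:n_val])
    ds.train_idx = np.sort(perm[n_val:])
    return ds


def build_dataset(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: PatchConfig,
    preprocess: PreprocessParams | None = None,
) -> PatchDataset:
    """Build one dataset from several (em, labels) source images.

    The per-image preprocessing anchors are resolved independently; the
    manifest records the source image index of every patch.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    parts = []
    for i, (em, labels) in enumerate(pairs):
        part = extract_patches(em, labels, cfg, rng=rng, preprocess=preprocess)
        for entry in part.manifest:
            entry["source_image"] = i
        parts.append(part)
    ds = PatchDataset(
        em=np.concatenate([p.em for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        manifest=[m for p in parts for m in p.manifest],
        config=cfg,
        preprocess=parts[0].preprocess,
    )
    n = len(ds)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    ds.val_idx = np.sort(perm[:n_val])
    ds.train_idx = np.sort(perm[n_val:])
    return ds
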