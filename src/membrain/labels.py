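"""Ground-truth class schemes and label conversions.

Two conversions turn cheaply available annotation into the ground truth a
membrane-detection network needs: filled-in per-cell instance paintings
become membrane/intracellular class maps of a chosen thickness
(erosion/dilation with a user radius), and binary membrane masks become
1-pixel medial-axis skeletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

log = logging.getLogger(__name__)

# canonical class indices
INTRACELLULAR = 0
MEMBRANE = 1
OTHER = 2
UNLABELED = 255

EIGHT_CONN = np.ones((3, 3), dtype=bool)  # 8-connectivity, used throughout


@dataclass(frozen=True)
class ClassScheme:
    """2-class (intracellular/membrane) or 3-class (+ other/extracellular)
    semantic scheme with contiguous indices 0..n_classes-1; 255 = unlabeled.

    ``mapping`` optionally relabels arbitrary source label values onto the
    scheme's class indices for :func:`map_classes`.
    """

    n_classes: int = 2
    unlabeled: int = UNLABELED
    mapping: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if self.mapping is not None:
            for _, dst in self.mapping:
                if not (0 <= dst < self.n_classes):
                    raise ValueError(f"mapping target {dst} outside 0..{self.n_classes - 1}")


@dataclass(frozen=True)
class MembraneParams:
    """Instance->membrane conversion: per-instance erosion depth ``radius``
    (disk structuring element), so two abutting cells share a membrane band
    of width 2*radius; ``fill_ecs`` additionally paints extracellular gaps
    between nearby cells as membrane."""

    radius: int = 1
    fill_ecs: bool = True

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")


def instance_to_membrane(
    instances: np.ndarray,
    params: MembraneParams = MembraneParams(),
    scheme: ClassScheme = ClassScheme(n_classes=2),
) -> np.ndarray:
    """Convert a filled instance painting to a semantic class map.

    A pixel of instance i stays intracellular iff the whole disk of
    ``params.radius`` around it lies inside i (pixels beyond the image edge
    count as background, so instances touching the border get a membrane
    rim).  Eroded-away pixels become membrane.  Background (id 0) becomes:
    membrane where it lies within the radius of two distinct instances (only
    when fill_ecs), otherwise 'other' in a 3-class scheme or membrane in a
    2-class scheme (there is nowhere else to put it).
    """
    instances = np.asarray(instances)
    if instances.ndim != 2:
        raise ValueError("instances must be a 2D map")
    footprint = morphology.disk(params.radius)
    big = np.iinfo(np.int64).max
    inst = instances.astype(np.int64)
    # min/max instance id within the disk; cval picks border = background
    lo = ndi.grey_erosion(np.where(inst > 0, inst, big), footprint=footprint,
                          mode="constant", cval=big)
    hi = ndi.grey_dilation(inst, footprint=footprint, mode="constant", cval=0)
    lo_all = ndi.grey_erosion(inst, footprint=footprint, mode="constant", cval=0)

    inside = inst > 0
    interior = inside & (lo_all == inst) & (hi == inst)  # full disk single id
    membrane = inside & ~interior
    background = ~inside
    if params.fill_ecs:
        # >= 2 distinct instances within the radius: min positive != max
        near_two = background & (hi > 0) & (lo < big) & (lo != hi)
        membrane |= near_two
        background &= ~near_two

    out = np.full(instances.shape, INTRACELLULAR, dtype=np.uint8)
    out[membrane] = MEMBRANE
    if scheme.n_classes == 3:
        out[background] = OTHER
    else:
        out[background] = MEMBRANE
    vanished = sorted(
        set(np.unique(inst[inside]).tolist()) - set(np.unique(inst[interior]).tolist())
    )
    if vanished:
        log.warning(
            "radius %d erased instance(s) %s entirely (pure membrane)",
            params.radius, vanished,
        )
    return out


def membrane_to_skeleton(membrane: np.ndarray) -> np.ndarray:
    """Thin a binary membrane mask to its 1-pixel-wide medial skeleton.

    Topology-preserving (8-connected component count unchanged); the result
    is a subset of the input mask and a fixed point of the operation.
    """
    membrane = np.asarray(membrane, dtype=bool)
    return morphology.skeletonize(membrane)


def map_classes(labels: np.ndarray, scheme: ClassScheme) -> np.ndarray:
    """Relabel arbitrary label values onto the scheme's contiguous class
    indices; the unlabeled sentinel passes through unchanged.

    Without an explicit mapping table the identity map is used (labels must
    then already be class indices).  Unmappable values raise, listing the
    offending ids.
    """
    labels = np.asarray(labels)
    table = dict(scheme.mapping) if scheme.mapping else {
        k: k for k in range(scheme.n_classes)
    }
    out = np.full(labels.shape, scheme.unlabeled, dtype=np.uint8)
    seen = np.zeros(labels.shape, dtype=bool)
    sentinel = labels == scheme.unlabeled
    seen |= sentinel
    for src, dst in table.items():
        hit = labels == src
        out[hit & ~sentinel] = dst
        seen |= hit
    if not seen.all():
        bad = sorted(int(v) for v in np.unique(labels[~seen]))
        raise ValueError(f"label value(s) {bad} not mappable under the scheme")
    return out
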