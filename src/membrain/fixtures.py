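"""Synthetic EM-like mosaics with exact paired ground truth.

Voronoi mosaics of seeded cell centres are the smallest texture with
cell-like topology: every pixel belongs to a cell, boundaries between
adjacent cells form closed membrane networks, and the instance / membrane /
EM triple is mutually consistent by construction (the membrane ground truth
*is* the instance->membrane conversion at the matching radius).  The EM
channel renders membranes dark against brighter cytoplasm, adds Gaussian
texture noise and a mild blur — enough for a small network to have to learn
a real boundary detector, with none of the ultrastructure (organelles,
staining gradients, section artefacts) of real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .labels import ClassScheme, MembraneParams, instance_to_membrane, MEMBRANE
from .store import TileVolume, create_volume


@dataclass(frozen=True)
class MosaicSpec:
    """Study conditions of one synthetic section.

    ``membrane_width`` is the full boundary band width between two adjacent
    cells (converted internally to an erosion radius of ceil(width / 2)).
    ``n_gaps`` > 0 deletes the membrane along short boundary arcs to create
    controlled merge errors; gaps break the instance/membrane consistency
    on purpose.
    """

    size: int = 256
    n_cells: int = 12
    membrane_width: int = 3
    intracellular_gray: float = 160.0
    membrane_gray: float = 60.0
    texture_sigma: float = 10.0
    blur_sigma: float = 1.0
    rng_seed: int = 0
    n_gaps: int = 0
    gap_length: int = 8

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1")

    @property
    def radius(self) -> int:
        return max(1, -(-self.membrane_width // 2))  # ceil(width / 2)


def _voronoi_instances(size: int, centers: np.ndarray) -> np.ndarray:
    """Nearest-centre (Euclidean) partition; ids 1..n_cells."""
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy[..., None] - centers[:, 0]) ** 2 + (xx[..., None] - centers[:, 1]) ** 2
    return (np.argmin(d2, axis=-1) + 1).astype(np.int32)


def _sample_centers(rng: np.random.Generator, size: int, n: int) -> np.ndarray:
    """Cell centres with a soft minimum separation so no cell degenerates."""
    min_sep = 0.35 * size / np.sqrt(n)
    centers: list[np.ndarray] = []
    for _ in range(10_000):
        if len(centers) == n:
            break
        cand = rng.uniform(0, size, size=2)
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    while len(centers) < n:  # pathological rng: fill without the separation
        centers.append(rng.uniform(0, size, size=2))
    return np.array(centers)


def _inject_gaps(membrane: np.ndarray, spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    """Delete membrane pixels in n_gaps Chebyshev squares of side
    ~gap_length centred on random interior membrane pixels."""
    out = membrane.copy()
    half = max(1, spec.gap_length // 2)
    for _ in range(spec.n_gaps):
        # avoid the image frame so the gap connects two real cells
        interior = np.zeros_like(out)
        m = spec.radius + 1
        interior[m:-m, m:-m] = out[m:-m, m:-m]
        cand = np.argwhere(interior)
        if len(cand) == 0:
            break
        r, c = cand[rng.integers(len(cand))]
        out[max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1] = False
    return out


def generate_mosaic(spec: MosaicSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (em_image uint8, instance_gt int32, membrane_gt bool).

    With ``n_gaps == 0`` the membrane ground truth equals
    ``instance_to_membrane(instance_gt, radius=spec.radius)`` exactly.
    """
    rng = np.random.default_rng(spec.rng_seed)
    centers = _sample_centers(rng, spec.size, spec.n_cells)
    return _render(spec, centers, rng)


def _render(
    spec: MosaicSpec, centers: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    instances = _voronoi_instances(spec.size, centers)
    classes = instance_to_membrane(
        instances,
        MembraneParams(radius=spec.radius, fill_ecs=True),
        ClassScheme(n_classes=2),
    )
    membrane = classes == MEMBRANE
    if spec.n_gaps > 0:
        membrane = _inject_gaps(membrane, spec, rng)
    em = np.where(membrane, spec.membrane_gray, spec.intracellular_gray).astype(np.float64)
    em += rng.normal(0.0, spec.texture_sigma, em.shape)
    if spec.blur_sigma > 0:
        em = ndi.gaussian_filter(em, spec.blur_sigma)
    em = np.clip(np.rint(em), 0, 255).astype(np.uint8)
    return em, instances, membrane


def generate_volume(
    spec: MosaicSpec,
    n_sections: int,
    em_root,
    label_root,
    drift: float = 2.0,
    tile_size: int = 1024,
) -> tuple[TileVolume, TileVolume]:
    """Write an n_section fixture volume (EM + instance labels) through the
    tile store.

    Cell centres perform a per-section Gaussian random walk of step
    ``drift`` px so sections are coherent in z, as in a real serial-section
    stack; drift 0 reproduces the same section throughout.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    centers = _sample_centers(rng, spec.size, spec.n_cells)
    shape = (n_sections, spec.size, spec.size)
    em_vol = create_volume(em_root, shape, tile_size=tile_size, dtype="uint8",
                           value_semantics="grayscale")
    lab_vol = create_volume(label_root, shape, tile_size=tile_size, dtype="uint16",
                            value_semantics="instance-id")
    em, instances, _ = _render(spec, centers, rng)
    for z in range(n_sections):
        em_vol.write_block((z, 0, 0), em[None])
        lab_vol.write_block((z, 0, 0), instances.astype(np.uint16)[None])
        if drift > 0 and z + 1 < n_sections:
            centers = np.clip(centers + rng.normal(0.0, drift, centers.shape), 0, spec.size - 1)
            em, instances, _ = _render(spec, centers, rng)
    em_vol.write_vsvi()
    lab_vol.write_vsvi()
    return em_vol, lab_vol
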