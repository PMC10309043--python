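"""Photometric and geometric augmentations for EM/label patch pairs.

Geometric ops (flips) are applied identically to both images so the pair
stays pixel-registered; photometric ops (blurs, histogram equalisation)
touch the EM side only — labels are categorical and must stay crisp.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure

AUGMENTATIONS = ("flip", "flip_h", "flip_v", "gaussian_blur", "motion_blur", "histogram_equalize")

# Blur parameter ranges: strong enough to perturb texture, mild enough to
# keep 2-3 px membranes resolvable.
GAUSSIAN_SIGMA_RANGE = (0.5, 2.0)
MOTION_LENGTH_RANGE = (3, 15)  # px, inclusive


def _motion_kernel(length: int, angle_deg: float) -> np.ndarray:
    """Normalised linear (straight-line) blur kernel."""
    k = np.zeros((length, length), dtype=np.float64)
    c = (length - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    dy, dx = np.sin(theta), np.cos(theta)
    for t in np.linspace(-c, c, 2 * length + 1):
        r, s = int(round(c + t * dy)), int(round(c + t * dx))
        k[r, s] = 1.0
    return k / k.sum()


def augment_pair(
    em: np.ndarray,
    labels: np.ndarray,
    op: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one named augmentation to a registered (em, labels) pair.

    ``flip`` picks horizontal/vertical at random; ``flip_h``/``flip_v`` are
    the deterministic variants.  Output dimensions always equal the input's.
    """
    if op not in AUGMENTATIONS:
        raise ValueError(f"unknown augmentation {op!r}; supported: {AUGMENTATIONS}")
    if op == "flip":
        op = "flip_h" if rng.random() < 0.5 else "flip_v"
    if op == "flip_h":
        return em[:, ::-1].copy(), labels[:, ::-1].copy()
    if op == "flip_v":
        return em[::-1, :].copy(), labels[::-1, :].copy()

    # photometric: EM only
    if op == "gaussian_blur":
        sigma = rng.uniform(*GAUSSIAN_SIGMA_RANGE)
        out = ndi.gaussian_filter(em.astype(np.float64), sigma)
    elif op == "motion_blur":
        length = int(rng.integers(MOTION_LENGTH_RANGE[0], MOTION_LENGTH_RANGE[1] + 1))
        kernel = _motion_kernel(length, rng.uniform(0.0, 180.0))
        out = ndi.convolve(em.astype(np.float64), kernel, mode="reflect")
    else:  # histogram_equalize
        if np.ptp(em) == 0:
            return em.copy(), labels.copy()
        out = exposure.equalize_hist(em) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), labels.copy()
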