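"""Scripted experiments: transfer-learning comparison and the
augmentation benchmark.

These harnesses reproduce, on synthetic fixtures, the two quantitative
protocols around the pipeline: (a) fine-tuning a pretrained membrane
detector on a few images of a new appearance domain versus training from
scratch, measured in epochs needed to reach a validation-accuracy
threshold; (b) training under different augmentation recipes and scoring
the watershed-expanded instance segmentation of held-out images with the
variation of information (mean +/- SEM over test images and over reseeded
retrainings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fixtures as fx
from .dataset import PatchConfig, extract_patches
from .expansion import ExpansionParams, expand_watershed, variation_of_information
from .nn.training import TrainConfig, evaluate, train
from .nn.unet import UNet, UNetConfig, build_unet

# the two synthetic appearance domains used throughout: A is the default
# rendering, B is brighter, lower-contrast and noisier with thicker
# membranes
DOMAIN_A: dict = {}
DOMAIN_B: dict = dict(
    intracellular_gray=185.0, membrane_gray=110.0, texture_sigma=16.0, membrane_width=5
)


def domain_patches(
    n_images: int,
    spec_kw: dict | None = None,
    seed0: int = 0,
    patches_per: int = 8,
    patch_size: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Membrane-class (0 = intracellular, 1 = membrane) training patches
    drawn from ``n_images`` fixture mosaics."""
    cfg = PatchConfig(
        patch_size=patch_size, patches_per_image=patches_per, rotation=True,
        rng_seed=seed0,
    )
    rng = np.random.default_rng(seed0)
    xs, ys = [], []
    for i in range(n_images):
        em, _, memb = fx.generate_mosaic(
            fx.MosaicSpec(rng_seed=seed0 * 1000 + i, **(spec_kw or {}))
        )
        ds = extract_patches(em, memb.astype(np.uint8), cfg, rng=rng)
        xs.append(ds.em)
        ys.append(ds.labels)
    return np.concatenate(xs), np.concatenate(ys)


def membrane_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth != 1)).sum())
    fn = int(((pred != 1) & (truth == 1)).sum())
    return 2 * tp / max(2 * tp + fp + fn, 1)


def epochs_to_accuracy(
    model: UNet,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    threshold: float,
    max_epochs: int,
    base_cfg: TrainConfig,
) -> int:
    """Train epoch by epoch until held-out pixel accuracy reaches the
    threshold; returns the epoch count, or max_epochs + 1 if never."""
    for epoch in range(1, max_epochs + 1):
        cfg = TrainConfig(
            epochs=1, batch_size=base_cfg.batch_size, lr=base_cfg.lr,
            momentum=base_cfg.momentum, mode=base_cfg.mode,
            leaky_factor=base_cfg.leaky_factor,
            class_weights=base_cfg.class_weights,
            rng_seed=base_cfg.rng_seed + epoch,
        )
        train(model, train_data, None, cfg)
        _, acc = evaluate(model, *val_data, batch_size=base_cfg.batch_size)
        if acc >= threshold:
            return epoch
    return max_epochs + 1


@dataclass
class TransferResult:
    per_seed: list[dict] = field(default_factory=list)

    @property
    def wins(self) -> int:
        return sum(1 for r in self.per_seed if r["continuous"] < r["scratch"])


def transfer_comparison(
    pretrained: UNet,
    n_seeds: int = 5,
    n_finetune_images: int = 3,
    threshold: float = 0.97,
    max_epochs: int = 12,
    lr: float = 0.05,
    seed0: int = 0,
) -> TransferResult:
    """Continuous learning from a domain-A-pretrained net vs training from
    scratch, on a few domain-B fixture images, over reseeded repeats.

    For each seed, both arms see the same fine-tune patches and are scored
    on the same held-out domain-B set; the recorded quantity is the number
    of epochs to reach ``threshold`` pixel accuracy.
    """
    val = domain_patches(2, DOMAIN_B, seed0=seed0 + 777)
    result = TransferResult()
    for s in range(n_seeds):
        ft = domain_patches(n_finetune_images, DOMAIN_B, seed0=seed0 + 10 + s)
        cfg = TrainConfig(lr=lr, rng_seed=seed0 + s)
        e_cont = epochs_to_accuracy(
            pretrained.copy(), ft, val, threshold, max_epochs, cfg
        )
        scratch = build_unet(pretrained.config, np.random.default_rng(seed0 + s))
        e_scratch = epochs_to_accuracy(scratch, ft, val, threshold, max_epochs, cfg)
        result.per_seed.append({"seed": s, "continuous": e_cont, "scratch": e_scratch})
    return result


# -- augmentation benchmark -------------------------------------------------

AUGMENTATION_VARIANTS: dict[str, tuple[str, ...]] = {
    "rotation_only": (),
    "rotation_flip": ("flip",),
    "rotation_flip_blur": ("flip", "gaussian_blur", "motion_blur"),
    "full": ("flip", "gaussian_blur", "motion_blur", "histogram_equalize"),
}


def _test_vi(model: UNet, n_images: int, seed0: int) -> list[float]:
    """Segment held-out mosaics end to end and score each with VI against
    the instance ground truth (membrane band excluded)."""
    vis = []
    for i in range(n_images):
        em, inst, memb = fx.generate_mosaic(fx.MosaicSpec(rng_seed=seed0 + i))
        side = 128 * ((em.shape[0] + 127) // 128)
        pad = np.zeros((side, side), dtype=em.dtype)
        pad[: em.shape[0], : em.shape[1]] = em
        prob = model.forward(pad[None, None].astype(np.float32) / 255.0)[0, 1]
        prob = prob[: em.shape[0], : em.shape[1]]
        pred = expand_watershed(prob, ExpansionParams())
        ref = np.where(memb, 0, inst)
        vis.append(variation_of_information(ref, pred).vi)
    return vis


def augmentation_vi_benchmark(
    variants: dict[str, tuple[str, ...]] | None = None,
    n_train_images: int = 6,
    n_test_images: int = 6,
    n_seeds: int = 2,
    epochs: int = 10,
    arch: UNetConfig | None = None,
    seed0: int = 0,
) -> dict[str, dict]:
    """Train a net per augmentation recipe and per seed, expand its test
    predictions to instances, and report test-VI statistics.

    Returns, per variant: mean VI, SEM over test images (of the first
    seed's net) and SEM over reseeded retrainings — the two error bars of
    the protocol.
    """
    variants = variants or AUGMENTATION_VARIANTS
    arch = arch or UNetConfig(depth=2, base_channels=8, n_classes=2)
    out: dict[str, dict] = {}
    for name, augs in variants.items():
        per_seed_means, first_seed_vis = [], None
        for s in range(n_seeds):
            cfg = PatchConfig(
                patch_size=128, patches_per_image=8, rotation=True,
                augmentations=augs, rng_seed=seed0 + s,
            )
            rng = np.random.default_rng(seed0 + s)
            xs, ys = [], []
            for i in range(n_train_images):
                em, _, memb = fx.generate_mosaic(
                    fx.MosaicSpec(rng_seed=seed0 + 100 + i)
                )
                ds = extract_patches(em, memb.astype(np.uint8), cfg, rng=rng)
                xs.append(ds.em)
                ys.append(ds.labels)
            model = build_unet(arch, np.random.default_rng(seed0 + s))
            train(
                model, (np.concatenate(xs), np.concatenate(ys)), None,
                TrainConfig(epochs=epochs, lr=0.05, rng_seed=seed0 + s),
            )
            vis = _test_vi(model, n_test_images, seed0 + 500)
            per_seed_means.append(float(np.mean(vis)))
            if first_seed_vis is None:
                first_seed_vis = vis
        sem_images = float(np.std(first_seed_vis, ddof=1) / np.sqrt(len(first_seed_vis))) if len(first_seed_vis) > 1 else 0.0
        sem_seeds = float(np.std(per_seed_means, ddof=1) / np.sqrt(len(per_seed_means))) if len(per_seed_means) > 1 else 0.0
        out[name] = {
            "mean_vi": float(np.mean(per_seed_means)),
            "sem_over_test_images": sem_images,
            "sem_over_seeds": sem_seeds,
        }
    return out
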