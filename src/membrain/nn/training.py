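"""Training loop: momentum SGD with per-group learning rates.

The transfer-learning modes all reduce to one mechanism — a learning-rate
multiplier per parameter group:

=================  =========================================================
scratch            fresh network, all groups at the base rate
continuous         pretrained network retrained unchanged (all groups 1x)
freeze_last        only the 1x1 classification head trains
freeze_encoder     contracting path + bottleneck frozen
leaky_freeze       encoder trains at ``leaky_factor`` (default 0.1) x the
                   decoder's rate
episodic           continuous, but batches interleave two datasets at a
                   fixed ratio to counter catastrophic forgetting
=================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .unet import UNet

MODES = ("scratch", "continuous", "freeze_last", "freeze_encoder", "leaky_freeze", "episodic")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    lr: float = 0.05
    momentum: float = 0.9
    mode: str = "scratch"
    leaky_factor: float = 0.1
    episodic_ratio: tuple[int, int] = (1, 1)
    class_weights: str | tuple[float, ...] | None = None  # None | "inverse" | explicit
    clip_norm: float | None = 1.0  # global gradient-norm clip; None disables
    ignore_index: int = 255
    rng_seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 < self.leaky_factor <= 1.0:
            raise ValueError(f"leaky_factor must be in (0, 1], got {self.leaky_factor}")
        if min(self.episodic_ratio) < 1:
            raise ValueError("episodic_ratio entries must be positive")

    def group_lr(self) -> dict[str, float]:
        mult = {"encoder": 1.0, "decoder": 1.0, "head": 1.0}
        if self.mode == "freeze_last":
            mult = {"encoder": 0.0, "decoder": 0.0, "head": 1.0}
        elif self.mode == "freeze_encoder":
            mult["encoder"] = 0.0
        elif self.mode == "leaky_freeze":
            mult["encoder"] = self.leaky_factor
        return {g: self.lr * m for g, m in mult.items()}


class SGD:
    """Momentum SGD over a UNet's parameter dict with per-group rates.

    Update: v <- momentum * v + g;  p <- p - lr_group * v.  From zero
    velocity a single step therefore moves each parameter by exactly
    ``-lr_group * gradient``.
    """

    def __init__(self, model: UNet, group_lr: dict[str, float], momentum: float = 0.9):
        self.model = model
        self.group_lr = group_lr
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for name, p in self.model.params.items():
            lr = self.group_lr[UNet.group_of(name)]
            if lr == 0.0:
                continue
            v = self.velocity[name]
            v *= self.momentum
            v += grads[name]
            p -= (lr * v).astype(p.dtype)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> dict[str, np.ndarray]:
    """Scale the whole gradient so its global L2 norm is at most max_norm.

    A tiny CNN under momentum SGD can blow up in the first epochs and die
    into an all-majority constant output (dead ReLUs); clipping makes the
    loop robust to that without changing converged behaviour.
    """
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values())))
    if total <= max_norm or total == 0.0:
        return grads
    scale = max_norm / total
    return {k: g * scale for k, g in grads.items()}


def resolve_class_weights(cfg: TrainConfig, labels: np.ndarray, n_classes: int):
    if cfg.class_weights is None:
        return None
    if cfg.class_weights == "inverse":
        freq = np.array(
            [(labels == k).sum() for k in range(n_classes)], dtype=np.float64
        )
        freq = np.maximum(freq, 1.0)
        w = freq.sum() / (n_classes * freq)
        return w
    return np.asarray(cfg.class_weights, dtype=np.float64)


def evaluate(
    model: UNet,
    X: np.ndarray,
    y: np.ndarray,
    class_weights=None,
    ignore_index: int = 255,
    batch_size: int = 8,
) -> tuple[float, float]:
    """(mean loss, pixel accuracy) over a labeled set."""
    from .layers import cross_entropy

    losses, correct, total = [], 0, 0
    for i in range(0, len(X), batch_size):
        xb = X[i : i + batch_size].astype(np.float32) / 255.0
        yb = y[i : i + batch_size]
        probs = model.forward(xb)
        loss, _ = cross_entropy(probs, yb, class_weights, ignore_index)
        losses.append(loss * len(xb))
        pred = probs.argmax(axis=1)
        valid = yb != ignore_index
        correct += int((pred[valid] == yb[valid]).sum())
        total += int(valid.sum())
    return float(np.sum(losses) / len(X)), correct / max(total, 1)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(
    model: UNet,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig,
    memory_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Train in place; returns the learning-curve history.

    ``train_data`` is (X, y) with X (n, s, s) uint8 gray patches and y
    (n, s, s) integer class maps (``cfg.ignore_index`` = unlabeled).
    ``memory_data`` is the episodic-memory dataset: in ``episodic`` mode
    batches are drawn from the two datasets interleaved at
    ``cfg.episodic_ratio`` (new : memory).
    """
    X, y = train_data
    if len(X) == 0:
        raise ValueError("training dataset is empty")
    if int(y[y != cfg.ignore_index].max(initial=0)) >= model.config.n_classes:
        raise ValueError(
            f"dataset contains class ids >= model n_classes={model.config.n_classes}"
        )
    if cfg.mode == "episodic" and memory_data is None:
        raise ValueError("episodic mode requires memory_data")

    rng = np.random.default_rng(cfg.rng_seed)
    weights = resolve_class_weights(cfg, y, model.config.n_classes)
    opt = SGD(model, cfg.group_lr(), cfg.momentum)
    history: dict[str, list] = {
        "train_loss": [], "val_loss": [], "val_accuracy": [], "epoch": []
    }

    for epoch in range(cfg.epochs):
        epoch_losses = []
        new_batches = list(_batches(len(X), cfg.batch_size, rng))
        schedule: list[tuple[np.ndarray, np.ndarray]] = []
        if cfg.mode == "episodic":
            Xm, ym = memory_data
            mem_batches = list(_batches(len(Xm), cfg.batch_size, rng))
            r_new, r_mem = cfg.episodic_ratio
            i = j = 0
            while i < len(new_batches) or j < len(mem_batches):
                for _ in range(r_new):
                    if i < len(new_batches):
                        schedule.append((X[new_batches[i]], y[new_batches[i]]))
                        i += 1
                for _ in range(r_mem):
                    if j < len(mem_batches):
                        schedule.append((Xm[mem_batches[j]], ym[mem_batches[j]]))
                        j += 1
        else:
            schedule = [(X[b], y[b]) for b in new_batches]

        for xb, yb in schedule:
            loss, _, grads = model.loss_and_grads(
                xb.astype(np.float32) / 255.0, yb, weights, cfg.ignore_index
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            if cfg.clip_norm is not None:
                grads = clip_gradients(grads, cfg.clip_norm)
            opt.step(grads)
            epoch_losses.append(loss)

        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_data is not None and len(val_data[0]):
            vl, va = evaluate(model, *val_data, weights, cfg.ignore_index, cfg.batch_size)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
        if cfg.checkpoint_dir:
            ckdir = Path(cfg.checkpoint_dir)
            ckdir.mkdir(parents=True, exist_ok=True)
            model.save_npz(ckdir / f"epoch{epoch:03d}.npz")
            from ..onnx_io import export_onnx

            export_onnx(model, ckdir / f"epoch{epoch:03d}.onnx")
    return history
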