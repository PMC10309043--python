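"""A small 2D U-net pixel classifier in plain numpy.

Standard topology: a contracting path of double-3x3-conv + ReLU blocks with
2x2 max pooling, a bottleneck, and an expanding path of nearest-neighbour
upsampling + skip concatenation + double conv, closed by a 1x1 conv head
and a channel softmax.  Parameters live in a flat name->array dict and are
grouped into ``encoder`` (contracting path + bottleneck), ``decoder``
(expanding path) and ``head`` — the granularity the freeze / leaky-freeze
transfer-learning modes operate on.

Forward and backward passes are hand-derived; see ``layers``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import layers as L


@dataclass(frozen=True)
class UNetConfig:
    """Architecture knobs.

    ``input_size`` is the nominal training patch side; it must be a
    positive multiple of 128, which guarantees divisibility by 2^depth for
    any depth <= 7.  The network itself is fully convolutional and accepts
    any side divisible by 2^depth.
    """

    depth: int = 2
    base_channels: int = 8
    n_classes: int = 2
    in_channels: int = 1
    input_size: int = 128

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= 7:
            raise ValueError(f"depth must be in 1..7, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        if self.input_size < 128 or self.input_size % 128 != 0:
            raise ValueError(
                f"input_size must be a positive multiple of 128, got {self.input_size}"
            )

    def channels(self, level: int) -> int:
        return self.base_channels * (2**level)


class UNet:
    """Parameter container + forward/backward for the U-net."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        if rng is not None:
            self._init_params(rng)

    # -- construction -----------------------------------------------------
    def _add_conv(self, name: str, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.params[f"{name}.w"] = rng.normal(0.0, std, (c_out, c_in, k, k)).astype(np.float32)
        self.params[f"{name}.b"] = np.zeros(c_out, dtype=np.float32)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        c_prev = cfg.in_channels
        for i in range(cfg.depth):
            c = cfg.channels(i)
            self._add_conv(f"enc{i}.conv1", c_prev, c, 3, rng)
            self._add_conv(f"enc{i}.conv2", c, c, 3, rng)
            c_prev = c
        cb = cfg.channels(cfg.depth)
        self._add_conv("bottleneck.conv1", c_prev, cb, 3, rng)
        self._add_conv("bottleneck.conv2", cb, cb, 3, rng)
        c_prev = cb
        for i in reversed(range(cfg.depth)):
            c = cfg.channels(i)
            self._add_conv(f"dec{i}.conv1", c_prev + c, c, 3, rng)
            self._add_conv(f"dec{i}.conv2", c, c, 3, rng)
            c_prev = c
        self._add_conv("head", c_prev, cfg.n_classes, 1, rng)

    @staticmethod
    def group_of(param_name: str) -> str:
        if param_name.startswith(("enc", "bottleneck")):
            return "encoder"
        if param_name.startswith("dec"):
            return "decoder"
        return "head"

    def copy(self) -> "UNet":
        m = UNet(self.config)
        m.params = {k: v.copy() for k, v in self.params.items()}
        return m

    # -- forward ----------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N,{self.config.in_channels},H,W) input, got {x.shape}")
        f = 2**self.config.depth
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"input sides {x.shape[2:]} must be divisible by 2^depth = {f}"
            )
        return x

    def _conv_relu(self, name, x, tape=None, relu=True):
        y, c_cache = L.conv2d_forward(x, self.params[f"{name}.w"], self.params[f"{name}.b"])
        if relu:
            y, r_cache = L.relu_forward(y)
        else:
            r_cache = None
        if tape is not None:
            tape[name] = (c_cache, r_cache)
        return y

    def _forward(self, x: np.ndarray, tape: dict | None):
        cfg = self.config
        skips = []
        h = x
        pool_caches = []
        for i in range(cfg.depth):
            h = self._conv_relu(f"enc{i}.conv1", h, tape)
            h = self._conv_relu(f"enc{i}.conv2", h, tape)
            skips.append(h)
            h, pc = L.maxpool2_forward(h)
            pool_caches.append(pc)
        h = self._conv_relu("bottleneck.conv1", h, tape)
        h = self._conv_relu("bottleneck.conv2", h, tape)
        split_channels = []
        for i in reversed(range(cfg.depth)):
            h = L.upsample2_forward(h)
            split_channels.append(h.shape[1])
            h = np.concatenate([h, skips[i]], axis=1)
            h = self._conv_relu(f"dec{i}.conv1", h, tape)
            h = self._conv_relu(f"dec{i}.conv2", h, tape)
        logits = self._conv_relu("head", h, tape, relu=False)
        if tape is not None:
            tape["_pools"] = pool_caches
            tape["_splits"] = split_channels
        return logits

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities, shape (N, n_classes, H, W)."""
        x = self._check_input(x)
        return L.softmax_channel(self._forward(x, tape=None))

    # -- backward ---------------------------------------------------------
    def loss_and_grads(
        self,
        x: np.ndarray,
        targets: np.ndarray,
        class_weights: np.ndarray | None = None,
        ignore_index: int = 255,
    ):
        """Cross-entropy loss and d loss / d param for one batch."""
        x = self._check_input(x)
        tape: dict = {}
        logits = self._forward(x, tape)
        probs = L.softmax_channel(logits)
        loss, dh = L.cross_entropy(probs, targets, class_weights, ignore_index)

        grads: dict[str, np.ndarray] = {}

        def back_conv(name, dy, relu=True):
            c_cache, r_cache = tape[name]
            if relu:
                dy = L.relu_backward(dy, r_cache)
            dx, dw, db = L.conv2d_backward(dy, c_cache)
            grads[f"{name}.w"] = dw
            grads[f"{name}.b"] = db
            return dx

        cfg = self.config
        dh = back_conv("head", dh, relu=False)
        splits = tape["_splits"]
        dskips: dict[int, np.ndarray] = {}
        for j, i in enumerate(range(cfg.depth)):  # reverse of the up path
            dh = back_conv(f"dec{i}.conv2", dh)
            dh = back_conv(f"dec{i}.conv1", dh)
            c_up = splits[cfg.depth - 1 - j]
            dskips[i] = dh[:, c_up:]
            dh = L.upsample2_backward(dh[:, :c_up])
        dh = back_conv("bottleneck.conv2", dh)
        dh = back_conv("bottleneck.conv1", dh)
        for i in reversed(range(cfg.depth)):
            dh = L.maxpool2_backward(dh, tape["_pools"][i])
            dh = dh + dskips[i]
            dh = back_conv(f"enc{i}.conv2", dh)
            dh = back_conv(f"enc{i}.conv1", dh)
        return loss, probs, grads

    # -- native serialization --------------------------------------------
    def save_npz(self, path) -> None:
        meta = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load_npz(cls, path) -> "UNet":
        data = np.load(path)
        cfg = UNetConfig(**json.loads(bytes(data["__config__"]).decode()))
        m = cls(cfg)
        m.params = {k: data[k] for k in data.files if k != "__config__"}
        return m


def build_unet(config: UNetConfig, rng: np.random.Generator | int = 0) -> UNet:
    """Seeded, deterministic construction of a U-net."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return UNet(config, rng)
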