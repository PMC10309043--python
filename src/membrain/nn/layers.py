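"""Minimal numpy layer primitives with explicit forward/backward passes.

Everything operates on float32 NCHW tensors.  Convolutions are expressed as
einsum over sliding windows, which numpy lowers to BLAS matmuls — fast
enough for desk-scale 2D networks on one CPU.  Each forward returns
``(y, cache)``; the matching backward consumes the cache.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded stride-1 cross-correlation.  x (N,C,H,W), w (O,C,kh,kw)."""
    kh, kw = w.shape[2:]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    y = np.einsum("nchwuv,ocuv->nohw", win, w, optimize=True)
    y += b[None, :, None, None]
    return y, (win, w, x.shape)


def conv2d_backward(dy: np.ndarray, cache):
    win, w, x_shape = cache
    kh, kw = w.shape[2:]
    ph, pw = kh // 2, kw // 2
    dw = np.einsum("nohw,nchwuv->ocuv", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dyp = np.pad(dy, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else dy
    dwin = sliding_window_view(dyp, (kh, kw), axis=(2, 3))
    wf = w[:, :, ::-1, ::-1]
    dx = np.einsum("nohwuv,ocuv->nchw", dwin, wf, optimize=True)
    return dx.astype(dy.dtype, copy=False), dw, db


def relu_forward(x: np.ndarray):
    return np.maximum(x, 0.0), (x > 0.0)


def relu_backward(dy: np.ndarray, mask) -> np.ndarray:
    return dy * mask


def maxpool2_forward(x: np.ndarray):
    """2x2 stride-2 max pooling; spatial dims must be even."""
    n, c, h, w = x.shape
    xr = (
        x.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)  # ties -> first position
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, (n, c, h, w) = cache
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return (
        dxr.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_channel(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    probs: np.ndarray,
    targets: np.ndarray,
    class_weights: np.ndarray | None = None,
    ignore_index: int = 255,
):
    """Weighted per-pixel cross-entropy and its gradient w.r.t. the logits.

    probs (N,K,H,W) from :func:`softmax_channel`; targets (N,H,W) int with
    ``ignore_index`` pixels excluded from loss and gradient.  Returns
    (loss, dlogits); the softmax Jacobian is folded in analytically
    (d loss / d logits = (p - onehot) * weight / sum(weights)).
    """
    n, k, _, _ = probs.shape
    valid = targets != ignore_index
    tgt = np.where(valid, targets, 0).astype(np.int64)
    pw = (
        class_weights[tgt].astype(np.float64)
        if class_weights is not None
        else np.ones(tgt.shape)
    )
    pw = pw * valid
    denom = pw.sum()
    if denom == 0:
        raise ValueError("batch contains no labeled pixel")
    p_true = np.take_along_axis(probs, tgt[:, None], axis=1)[:, 0]
    loss = float(-(pw * np.log(np.maximum(p_true, 1e-12))).sum() / denom)

    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, tgt[:, None], 1.0, axis=1)
    dlogits = (probs - onehot) * (pw / denom)[:, None]
    return loss, dlogits.astype(np.float32)
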