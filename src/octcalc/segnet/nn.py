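"""Numpy implementation of the UNet-like encoder-decoder.

The network maps a two-channel polar tensor ``(2, H, W)`` to a per-pixel
probability field over the 10 pixel classes.  The contracting path has
four convolutional blocks (two 3x3 convolutions + ReLU each, followed by
2x2 max-pooling and dropout), with 16 filters in the first block and a
doubling at every level (16, 32, 64, 128); a two-convolution bottleneck
sits below.  The expanding path mirrors the pooling steps with 2x
nearest-neighbour upsampling, concatenates the matching encoder feature
bridge, and applies a single 3x3 convolution + ReLU per block; a final
1x1 convolution and channel softmax produce the segmentation map.

Convolutions run as im2col + one BLAS matmul; gradients are computed
analytically (the adjoint of a same-padded correlation is a correlation
with spatially flipped, transposed kernels), so training needs nothing
beyond numpy.  Everything is float32 and fully deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    Filter count at encoder level ``k`` is ``base_filters * 2**k``; input
    spatial dimensions must be divisible by ``2**depth``.
    """

    in_channels: int = 2
    n_classes: int = 10
    base_filters: int = 16
    depth: int = 4
    dropout_rate: float = 0.1
    upsample_mode: str = "nearest"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.upsample_mode != "nearest":
            raise ValueError("only nearest-neighbour upsampling is implemented")

    @property
    def encoder_filters(self) -> Tuple[int, ...]:
        return tuple(self.base_filters * 2**k for k in range(self.depth))


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*9) patches of a same-padded 3x3 window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3) -> (N, H*W, C*9)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)
    return np.ascontiguousarray(col)


def conv3x3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 correlation. weight: (Cout, Cin, 3, 3)."""
    n, c, h, w = x.shape
    co = weight.shape[0]
    col = _im2col(x)  # (N, HW, C*9)
    wmat = weight.reshape(co, c * 9)
    out = col @ wmat.T + bias  # (N, HW, Co)
    return out.transpose(0, 2, 1).reshape(n, co, h, w)


def conv3x3_backward(
    x: np.ndarray, weight: np.ndarray, dout: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padded 3x3 correlation.

    Returns (dx, dweight, dbias).  dx is the correlation of ``dout`` with
    the spatially flipped, in/out-transposed kernels.
    """
    n, c, h, w = x.shape
    co = weight.shape[0]
    dmat = dout.reshape(n, co, h * w).transpose(0, 2, 1)  # (N, HW, Co)
    col = _im2col(x)
    dw = np.einsum("npo,npk->ok", dmat, col, optimize=True).reshape(weight.shape)
    db = dmat.sum(axis=(0, 1))
    w_flip = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, 3, 3)
    dx = conv3x3(dout, np.ascontiguousarray(w_flip), np.zeros(c, dtype=weight.dtype))
    return dx, dw, db


def maxpool2(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns (pooled, argmax mask for backprop)."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    m = xr.max(axis=(3, 5))
    mask = xr == m[:, :, :, None, :, None]
    # Route gradient only to the first maximum of each window.
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return m, mask


def maxpool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, c, hh, ww = dout.shape
    dx = mask * dout[:, :, :, None, :, None]
    return dx.reshape(n, c, 2 * hh, 2 * ww)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def combined_loss(
    probs: np.ndarray,
    target: np.ndarray,
    class_weights: Optional[np.ndarray] = None,
    ce_dice_mix: float = 0.5,
    eps: float = 1e-7,
    return_grad: bool = False,
):
    """Class-weighted mix of cross-entropy and soft-Dice loss.

    ``probs`` is ``(N, C, H, W)`` per-pixel probabilities, ``target``
    ``(N, H, W)`` integer labels.  The loss is
    ``mix * CE + (1 - mix) * (1 - soft Dice)`` where CE is the weighted
    mean of per-pixel ``-log p_target`` (weights normalized, so uniform
    predictions over C classes give exactly ``ln C``) and the soft Dice
    is the weighted mean over classes of ``(2 sum(p t) + eps) /
    (sum(p) + sum(t) + eps)``.  Zero iff the prediction equals the
    one-hot target.  With ``return_grad`` the gradient with respect to
    the pre-softmax logits is also returned.
    """
    probs = np.asarray(probs)
    target = np.asarray(target)
    n, c, h, w = probs.shape
    if target.shape != (n, h, w):
        raise ValueError(
            f"target shape {target.shape} does not match probabilities {(n, h, w)}"
        )
    if class_weights is None:
        class_weights = np.ones(c, dtype=probs.dtype)
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if class_weights.shape != (c,):
        raise ValueError("class_weights must have one entry per class")

    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, target[:, None, :, :], 1.0, axis=1)

    # Cross-entropy, pixel weights normalized to mean 1.
    w_pix = class_weights[target]  # (N, H, W)
    w_sum = w_pix.sum()
    p_t = np.take_along_axis(probs, target[:, None, :, :], axis=1)[:, 0]
    ce = float((w_pix * -np.log(np.clip(p_t, eps, None))).sum() / w_sum)

    # Soft Dice per class over the whole batch.
    inter = (probs * onehot).sum(axis=(0, 2, 3))
    psum = probs.sum(axis=(0, 2, 3))
    tsum = onehot.sum(axis=(0, 2, 3))
    dice_c = (2.0 * inter + eps) / (psum + tsum + eps)
    cw_sum = class_weights.sum()
    dice = float((class_weights * dice_c).sum() / cw_sum)

    loss = ce_dice_mix * ce + (1.0 - ce_dice_mix) * (1.0 - dice)
    if not return_grad:
        return loss

    # d(CE)/d(logits) = w_pix/w_sum * (p - t)
    dce = (w_pix[:, None] / w_sum) * (probs - onehot)
    # d(dice_c)/d(p_c) then chain through the channel softmax.
    den = psum + tsum + eps
    ddice_dp = (2.0 * onehot * den[None, :, None, None] - (2.0 * inter + eps)[None, :, None, None]) / (
        den**2
    )[None, :, None, None]
    g = -(class_weights[None, :, None, None] / cw_sum) * ddice_dp  # dL_dice/dp
    inner = (probs * g).sum(axis=1, keepdims=True)
    ddice = probs * (g - inner)
    dlogits = (ce_dice_mix * dce + (1.0 - ce_dice_mix) * ddice).astype(probs.dtype)
    return loss, dlogits


def soft_dice_per_class(
    probs: np.ndarray, target: np.ndarray, eps: float = 1e-7
) -> np.ndarray:
    """Per-class soft Dice of a batch, used as a validation metric."""
    n, c, h, w = probs.shape
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, np.asarray(target)[:, None, :, :], 1.0, axis=1)
    inter = (probs * onehot).sum(axis=(0, 2, 3))
    psum = probs.sum(axis=(0, 2, 3))
    tsum = onehot.sum(axis=(0, 2, 3))
    return (2.0 * inter + eps) / (psum + tsum + eps)


class UNet:
    """The encoder-decoder network with explicit forward/backward passes.

    Parameters live in ``self.params`` (name -> float32 array); the
    caches needed for backprop are stored on the instance by ``forward``
    and consumed by ``backward``.
    """

    def __init__(self, cfg: NetConfig, rng: Optional[np.random.Generator] = None):
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        self.params: Dict[str, np.ndarray] = {}
        f = cfg.encoder_filters
        c_in = cfg.in_channels
        # Encoder: two 3x3 convolutions per block.
        for k, fk in enumerate(f):
            self._add_conv(f"enc{k}a", c_in, fk, rng)
            self._add_conv(f"enc{k}b", fk, fk, rng)
            c_in = fk
        fb = cfg.base_filters * 2**cfg.depth
        self._add_conv("botA", f[-1], fb, rng)
        self._add_conv("botB", fb, fb, rng)
        # Decoder: one 3x3 convolution per block after concatenation.
        c_up = fb
        for k in reversed(range(cfg.depth)):
            self._add_conv(f"dec{k}", c_up + f[k], f[k], rng)
            c_up = f[k]
        # Final 1x1 projection to class logits.
        scale = np.sqrt(2.0 / c_up)
        self.params["head_w"] = (
            rng.standard_normal((cfg.n_classes, c_up)) * scale
        ).astype(np.float32)
        self.params["head_b"] = np.zeros(cfg.n_classes, dtype=np.float32)

    def _add_conv(self, name: str, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 9))  # He initialization for ReLU
        self.params[f"{name}_w"] = (
            rng.standard_normal((cout, cin, 3, 3)) * scale
        ).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _conv_relu(self, name: str, x: np.ndarray, cache: Dict) -> np.ndarray:
        z = conv3x3(x, self.params[f"{name}_w"], self.params[f"{name}_b"])
        cache[name] = (x, z > 0)
        return np.maximum(z, 0.0)

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Map ``(N, in_channels, H, W)`` to ``(N, n_classes, H, W)`` probabilities."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        n, c, h, w = x.shape
        div = 2**self.cfg.depth
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % div or w % div:
            raise ValueError(
                f"spatial dims ({h}, {w}) must be divisible by {div} for depth "
                f"{self.cfg.depth}"
            )
        cache: Dict = {"shape": x.shape, "train": train}
        skips = []
        cur = x
        for k in range(self.cfg.depth):
            cur = self._conv_relu(f"enc{k}a", cur, cache)
            cur = self._conv_relu(f"enc{k}b", cur, cache)
            skips.append(cur)
            cur, mask = maxpool2(cur)
            cache[f"pool{k}"] = mask
            if train and self.cfg.dropout_rate > 0:
                keep = (
                    (rng or np.random.default_rng(0)).uniform(size=cur.shape)
                    >= self.cfg.dropout_rate
                ).astype(np.float32) / (1.0 - self.cfg.dropout_rate)
                cache[f"drop{k}"] = keep
                cur = cur * keep
        cur = self._conv_relu("botA", cur, cache)
        cur = self._conv_relu("botB", cur, cache)
        for k in reversed(range(self.cfg.depth)):
            up = upsample2(cur)
            cat = np.concatenate([up, skips[k]], axis=1)
            cache[f"split{k}"] = up.shape[1]
            cur = self._conv_relu(f"dec{k}", cat, cache)
        # 1x1 head as a matmul over channels.
        hw = self.params["head_w"]
        logits = np.einsum("nchw,kc->nkhw", cur, hw, optimize=True) + self.params[
            "head_b"
        ][None, :, None, None]
        cache["head_in"] = cur
        probs = softmax(logits, axis=1)
        cache["probs"] = probs
        self._cache = cache
        return probs

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients for every parameter given dLoss/dlogits."""
        cache = self._cache
        grads: Dict[str, np.ndarray] = {}
        cur = cache["head_in"]
        grads["head_w"] = np.einsum("nkhw,nchw->kc", dlogits, cur, optimize=True)
        grads["head_b"] = dlogits.sum(axis=(0, 2, 3))
        dcur = np.einsum("nkhw,kc->nchw", dlogits, self.params["head_w"], optimize=True)

        def back_conv(name: str, dout: np.ndarray) -> np.ndarray:
            x_in, relu_mask = cache[name]
            dz = dout * relu_mask
            dx, dw, db = conv3x3_backward(x_in, self.params[f"{name}_w"], dz)
            grads[f"{name}_w"] = dw
            grads[f"{name}_b"] = db
            return dx

        dskips: List[np.ndarray] = [None] * self.cfg.depth
        for k in range(self.cfg.depth):
            dcat = back_conv(f"dec{k}", dcur)
            split = cache[f"split{k}"]
            dup, dskip = dcat[:, :split], dcat[:, split:]
            dskips[k] = dskip
            dcur = upsample2_backward(dup)
        dcur = back_conv("botB", dcur)
        dcur = back_conv("botA", dcur)
        for k in reversed(range(self.cfg.depth)):
            if cache["train"] and f"drop{k}" in cache:
                dcur = dcur * cache[f"drop{k}"]
            dcur = maxpool2_backward(dcur, cache[f"pool{k}"])
            dcur = dcur + dskips[k]
            dcur = back_conv(f"enc{k}b", dcur)
            dcur = back_conv(f"enc{k}a", dcur)
        return grads


def build_network(cfg: NetConfig, seed: int = 0) -> UNet:
    """Construct a seeded :class:`UNet` from its configuration."""
    return UNet(cfg, np.random.default_rng(seed))
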