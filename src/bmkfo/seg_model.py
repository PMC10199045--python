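"""A small conditioned segmentation CNN.

The network maps a channel stack of (query image, support image, support
mask) to per-pixel 2-class logits, so one forward pass segments the query
conditioned on the labeled support example.  The architecture is deliberately
tiny — a handful of stride-1 convolutions with two pooling/upsampling stages
and a full-resolution head that sees the raw input again — because the
meta-optimizer it serves is model-agnostic: every trainable tensor is just a
named array that can be flattened to a 2-D matrix, which is all the
Kronecker-factored machinery requires.

All arithmetic runs on the :mod:`bmkfo.autodiff` tape in float64.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod

import numpy as np

from .autodiff import (
    Tensor,
    broadcast_to,
    concat1d,
    exp,
    gather,
    matmul,
    relu,
    reshape,
    transpose,
    tsum,
)

__all__ = ["SegModelSpec", "init_params", "forward", "softmax2", "model_input"]


@dataclass(frozen=True)
class SegModelSpec:
    """Architecture description.

    ``channels`` are the widths of the three hidden convolutions (at full,
    half and quarter resolution); all kernels are ``kernel x kernel``; the
    head convolution sees the upsampled features concatenated with the raw
    input channels.
    """

    channels: tuple[int, int, int] = (16, 32, 16)
    kernel: int = 3
    in_channels: int = 3
    n_classes: int = 2
    nonlinearity: str = "relu"
    param_cap: int = 50_000

    def layer_shapes(self) -> dict[str, tuple]:
        c0, c1, c2 = self.channels
        k2 = self.kernel * self.kernel
        shapes = {
            "conv1.weight": (c0, self.in_channels * k2),
            "conv1.bias": (c0,),
            "conv2.weight": (c1, c0 * k2),
            "conv2.bias": (c1,),
            "conv3.weight": (c2, c1 * k2),
            "conv3.bias": (c2,),
            "head.weight": (self.n_classes, (c2 + self.in_channels) * k2),
            "head.bias": (self.n_classes,),
        }
        return shapes

    def n_params(self) -> int:
        return sum(prod(s) for s in self.layer_shapes().values())


def init_params(spec: SegModelSpec, seed: int) -> dict[str, Tensor]:
    """Seeded fan-in-scaled Gaussian initialisation of all trainable tensors."""
    if spec.n_params() > spec.param_cap:
        raise ValueError(
            f"model has {spec.n_params()} parameters, above the cap {spec.param_cap}"
        )
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    for name, shape in spec.layer_shapes().items():
        if name.endswith("bias"):
            data = np.zeros(shape)
        else:
            fan_in = shape[1]
            data = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
        params[name] = Tensor(data, requires_grad=True)
    return params


# ---------------------------------------------------------------------------
# tape-level layers
# ---------------------------------------------------------------------------

_COL_CACHE: dict[tuple, np.ndarray] = {}


def _col_indices(cin: int, h: int, w: int, k: int) -> np.ndarray:
    """im2col gather indices with 'same' zero padding.

    Maps each output pixel to the flat indices of its ``cin*k*k`` receptive
    field in the flattened input; out-of-bounds taps point at an extra zero
    slot appended to the input.
    """
    key = (cin, h, w, k)
    if key in _COL_CACHE:
        return _COL_CACHE[key]
    pad = k // 2
    zero_slot = cin * h * w
    rows = np.arange(h)[:, None] + np.arange(k)[None, :] - pad  # (h, k)
    cols = np.arange(w)[:, None] + np.arange(k)[None, :] - pad  # (w, k)
    valid_r = (rows >= 0) & (rows < h)
    valid_c = (cols >= 0) & (cols < w)
    idx = np.empty((h, w, cin, k, k), dtype=np.int64)
    for c in range(cin):
        base = c * h * w
        rr = np.where(valid_r, rows, 0)
        cc = np.where(valid_c, cols, 0)
        flat = base + rr[:, None, :, None] * w + cc[None, :, None, :]  # (h,w,k,k)
        bad = ~(valid_r[:, None, :, None] & valid_c[None, :, None, :])
        flat = np.where(bad, zero_slot, flat)
        idx[:, :, c] = flat
    out = idx.reshape(h * w, cin * k * k)
    _COL_CACHE[key] = out
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, k: int) -> Tensor:
    """Stride-1 'same' convolution of a (Cin, H, W) tensor."""
    cin, h, w = x.data.shape
    cout = weight.data.shape[0]
    idx = _col_indices(cin, h, w, k)
    xa = concat1d(reshape(x, (-1,)), Tensor(np.zeros(1)))
    cols = gather(xa, idx)  # (H*W, Cin*k*k)
    out = matmul(cols, transpose(weight)) + reshape(bias, (1, cout))
    return reshape(transpose(out), (cout, h, w))


def avg_pool2(x: Tensor) -> Tensor:
    c, h, w = x.data.shape
    y = reshape(x, (c, h // 2, 2, w // 2, 2))
    return tsum(y, axis=(2, 4)) * 0.25


def upsample2(x: Tensor) -> Tensor:
    c, h, w = x.data.shape
    y = broadcast_to(reshape(x, (c, h, 1, w, 1)), (c, h, 2, w, 2))
    return reshape(y, (c, 2 * h, 2 * w))


def channel_concat(a: Tensor, b: Tensor) -> Tensor:
    ca, h, w = a.data.shape
    cb = b.data.shape[0]
    return reshape(concat1d(reshape(a, (-1,)), reshape(b, (-1,))), (ca + cb, h, w))


def softmax2(logits: Tensor) -> Tensor:
    """Per-pixel softmax over the leading class axis (numerically shifted)."""
    shift = Tensor(logits.data.max(axis=0, keepdims=True))
    e = exp(logits - broadcast_to(shift, logits.data.shape))
    denom = tsum(e, axis=0, keepdims=True)
    return e / broadcast_to(denom, e.data.shape)


def model_input(episode) -> np.ndarray:
    """(query image, support image, support mask) channel stack; multi-shot
    support pairs are averaged channelwise."""
    s_img = np.mean([img for img, _ in episode.support], axis=0)
    s_msk = np.mean([msk for _, msk in episode.support], axis=0)
    q_img = episode.query[0]
    return np.stack([q_img, s_img, s_msk]).astype(np.float64)


def forward(spec: SegModelSpec, params: dict[str, Tensor], x: np.ndarray | Tensor) -> Tensor:
    """Per-pixel 2-class logits for a (in_channels, H, W) input stack."""
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float64))
    if x.data.shape[0] != spec.in_channels:
        raise ValueError(
            f"input has {x.data.shape[0]} channels, spec expects {spec.in_channels} (conv1)"
        )
    k = spec.kernel
    try:
        h1 = relu(conv2d(x, params["conv1.weight"], params["conv1.bias"], k))
        h1p = avg_pool2(h1)
        h2 = relu(conv2d(h1p, params["conv2.weight"], params["conv2.bias"], k))
        h2p = avg_pool2(h2)
        h3 = relu(conv2d(h2p, params["conv3.weight"], params["conv3.bias"], k))
        h3u = upsample2(upsample2(h3))
        head_in = channel_concat(h3u, x)
        logits = conv2d(head_in, params["head.weight"], params["head.bias"], k)
    except ValueError as err:  # re-raise with layer context
        raise ValueError(f"shape error in forward pass: {err}") from err
    return logits


def predict_mask(spec: SegModelSpec, params: dict[str, Tensor], x, threshold: float = 0.5):
    """Hard foreground mask from the softmax foreground probability."""
    probs = softmax2(forward(spec, params, x))
    return (probs.data[1] >= threshold).astype(np.uint8)
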