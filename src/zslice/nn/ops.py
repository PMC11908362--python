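"""Differentiable image ops: convolutions (im2col), pooling, warping.

Tensor layout is (N, C, H, W) throughout. Convolution weights are
(C_out, C_in, KH, KW); transposed-convolution weights are
(C_in, C_out, KH, KW). All ops are built from autograd-traceable
primitives (fancy indexing, matmul, reshape), so gradients — including
the second-order gradients needed by a gradient penalty — propagate
through every path, with one deliberate exception: the integer sampling
lattice of :func:`backward_warp` (the floor of the flow) is treated as a
constant, exactly as piecewise-constant indices should be.
"""

from __future__ import annotations

import numpy as onp

import autograd.numpy as np
from autograd.tracer import getval


def leaky_relu(x, slope: float = 0.2):
    return np.where(x > 0, x, slope * x)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _im2col_indices(C: int, H: int, W: int, KH: int, KW: int, stride: int, pad: int):
    OH = (H + 2 * pad - KH) // stride + 1
    OW = (W + 2 * pad - KW) // stride + 1
    i0 = onp.repeat(onp.arange(KH), KW)
    j0 = onp.tile(onp.arange(KW), KH)
    i1 = stride * onp.repeat(onp.arange(OH), OW)
    j1 = stride * onp.tile(onp.arange(OW), OH)
    rows = i0[:, None] + i1[None, :]  # (KH*KW, OH*OW)
    cols = j0[:, None] + j1[None, :]
    return rows, cols, OH, OW


def conv2d(x, W, b, stride: int = 1, pad: int = 1):
    """2-D cross-correlation with square stride/zero-padding."""
    N, C, H, Wd = x.shape
    Cout, Cin, KH, KW = W.shape
    if Cin != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cin}")
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant")
    rows, cols, OH, OW = _im2col_indices(C, H, Wd, KH, KW, stride, pad)
    patches = x[:, :, rows, cols]  # (N, C, KH*KW, OH*OW)
    patches = np.reshape(patches, (N, C * KH * KW, OH * OW))
    Wm = np.reshape(W, (Cout, C * KH * KW))
    out = np.matmul(Wm, patches)  # (N, Cout, OH*OW)
    out = np.reshape(out, (N, Cout, OH, OW))
    return out + np.reshape(b, (1, Cout, 1, 1))


def conv_transpose2d(x, W, b, stride: int = 2, pad: int = 1):
    """Transposed convolution (fractionally-strided), the adjoint of conv2d.

    Realized as zero-stuffing the input by `stride`, then an ordinary
    convolution with the spatially flipped kernel. Output spatial size is
    stride*(H-1) + KH - 2*pad, i.e. exactly 2H for the (k=4, s=2, p=1)
    upsampling blocks used here.
    """
    N, C, H, Wd = x.shape
    Cin, Cout, KH, KW = W.shape
    if Cin != C:
        raise ValueError(f"conv_transpose2d: input has {C} channels, weight expects {Cin}")
    if stride > 1:
        z = np.zeros((N, C, H, Wd, stride - 1))
        xs = np.concatenate([np.reshape(x, (N, C, H, Wd, 1)), z], axis=4)
        xs = np.reshape(xs, (N, C, H, Wd * stride))[:, :, :, : (Wd - 1) * stride + 1]
        z2 = np.zeros((N, C, H, (stride - 1), (Wd - 1) * stride + 1))
        xs = np.concatenate([np.reshape(xs, (N, C, H, 1, -1)), z2], axis=3)
        xs = np.reshape(xs, (N, C, H * stride, -1))[:, :, : (H - 1) * stride + 1, :]
    else:
        xs = x
    Wf = W[:, :, ::-1, ::-1]  # flip taps
    Wf = np.transpose(Wf, (1, 0, 2, 3))  # (Cout, Cin, KH, KW)
    return conv2d(xs, Wf, b, stride=1, pad=KH - 1 - pad)


def avg_pool(x, factor: int):
    """Non-overlapping mean pooling by an integer factor (H, W divisible)."""
    if factor == 1:
        return x
    N, C, H, W = x.shape
    if H % factor or W % factor:
        raise ValueError(f"avg_pool: {H}x{W} not divisible by {factor}")
    x = np.reshape(x, (N, C, H // factor, factor, W // factor, factor))
    return np.mean(x, axis=(3, 5))


def upsample_nearest(x, factor: int):
    """Nearest-neighbour upsampling by an integer factor."""
    if factor == 1:
        return x
    x = np.repeat(x, factor, axis=2)
    return np.repeat(x, factor, axis=3)


def backward_warp(image, flow):
    """Backward warping: out(p) = bilinear sample of image at p + flow(p).

    `image` is (N, C, H, W); `flow` is (N, 2, H, W) with channel 0 the x
    (column) displacement and channel 1 the y (row) displacement, in
    pixels. Out-of-range sample positions are clamped to the border.
    Differentiable w.r.t. both the image (through the gathered values)
    and the flow (through the bilinear weights).
    """
    N, C, H, W = image.shape
    if flow.shape != (N, 2, H, W):
        raise ValueError(f"flow shape {flow.shape} does not match image {image.shape}")
    gy, gx = onp.meshgrid(onp.arange(H, dtype=onp.float64), onp.arange(W, dtype=onp.float64), indexing="ij")
    sx = np.clip(gx[None] + flow[:, 0], 0.0, W - 1.0)  # (N, H, W)
    sy = np.clip(gy[None] + flow[:, 1], 0.0, H - 1.0)
    x0 = onp.floor(getval(sx)).astype(onp.int64)
    y0 = onp.floor(getval(sy)).astype(onp.int64)
    x0 = onp.clip(x0, 0, W - 2) if W > 1 else onp.zeros_like(x0)
    y0 = onp.clip(y0, 0, H - 2) if H > 1 else onp.zeros_like(y0)
    x1 = onp.minimum(x0 + 1, W - 1)
    y1 = onp.minimum(y0 + 1, H - 1)
    wx = sx - x0  # traced
    wy = sy - y0
    bidx = onp.arange(N)[:, None, None, None]
    cidx = onp.arange(C)[None, :, None, None]

    def gather(yi, xi):
        return image[bidx, cidx, yi[:, None], xi[:, None]]  # (N, C, H, W)

    v00 = gather(y0, x0)
    v01 = gather(y0, x1)
    v10 = gather(y1, x0)
    v11 = gather(y1, x1)
    wx = wx[:, None]
    wy = wy[:, None]
    return (
        v00 * (1 - wx) * (1 - wy)
        + v01 * wx * (1 - wy)
        + v10 * (1 - wx) * wy
        + v11 * wx * wy
    )
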