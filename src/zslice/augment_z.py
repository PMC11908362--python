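"""Inference: axial-resolution doubling and continuous-z slice insertion.

One doubling pass interpolates a new plane in each of the n-1 gaps of an
n-slice stack, so the result has 2n-1 slices (the last slice has no
partner; k passes give 2^k (n-1) + 1). Original slices are carried over
verbatim — augmentation never rewrites acquired data. The continuous-z
variant can insert planes at arbitrary relative depths z in (0, 1)
between each adjacent pair, guided by the DPM input channel.

Each input pair is min-max normalized jointly into the network range and
the transform inverted on the output, so inference matches the training
intensity distribution. Planes larger than the training size are
processed in square tiles with end-aligned overlap and feathered (linear
ramp) blending to suppress seams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as onp
from scipy.interpolate import CubicSpline

from .network import NetConfig, student_forward
from .stacks import Stack, _axis_origins
from .triplets import make_dpm


@dataclass
class InterpolatorModel:
    """Trained student weights plus the architecture profile they belong to."""

    student: dict
    net_config: NetConfig

    @classmethod
    def from_state(cls, state) -> "InterpolatorModel":
        return cls(student=state.student, net_config=state.net_config)

    @classmethod
    def from_checkpoint(cls, path) -> "InterpolatorModel":
        from .training import load_checkpoint

        return cls.from_state(load_checkpoint(path))

    @property
    def plus_variant(self) -> bool:
        return self.net_config.plus_variant


def _forward_plane(model: InterpolatorModel, a0: onp.ndarray, a1: onp.ndarray, z: float) -> onp.ndarray:
    dpm = make_dpm(z, a0.shape) if model.plus_variant else None
    out = student_forward(model.student, a0[None], a1[None], dpm=dpm, config=model.net_config)
    return onp.clip(onp.asarray(out.student_frame)[0, 0], 0.0, 1.0)


def _feather_weight(size: int, feather: int) -> onp.ndarray:
    ramp = onp.minimum(onp.arange(size) + 1, onp.arange(size)[::-1] + 1)
    w = onp.minimum(ramp / float(feather + 1), 1.0)
    return onp.outer(w, w)


def interpolate_pair(
    model: InterpolatorModel,
    I0: onp.ndarray,
    I1: onp.ndarray,
    z: float = 0.5,
    tile: Optional[int] = None,
    feather: int = 16,
) -> onp.ndarray:
    """Predict the plane at relative depth z between two adjacent planes.

    The fixed-midpoint model only supports z = 0.5; the continuous-z
    model accepts any z in [0, 1]. `tile` enables patch-wise prediction
    for planes larger than the training size.
    """
    I0 = onp.asarray(I0)
    I1 = onp.asarray(I1)
    if I0.shape != I1.shape:
        raise ValueError("input planes must share one shape")
    if not model.plus_variant and z != 0.5:
        raise ValueError(f"fixed-midpoint model only interpolates z=0.5, got z={z}")
    if not (0.0 <= z <= 1.0):
        raise ValueError(f"z must lie in [0, 1], got {z}")
    lo = float(min(I0.min(), I1.min()))
    hi = float(max(I0.max(), I1.max()))
    span = hi - lo
    if span == 0:
        a0 = onp.zeros(I0.shape, dtype=onp.float64)
        a1 = onp.zeros(I1.shape, dtype=onp.float64)
    else:
        a0 = (I0.astype(onp.float64) - lo) / span
        a1 = (I1.astype(onp.float64) - lo) / span

    h, w = a0.shape
    if tile is None or (tile >= h and tile >= w):
        pred = _forward_plane(model, a0, a1, z)
    else:
        acc = onp.zeros((h, w))
        wsum = onp.zeros((h, w))
        last = onp.zeros((h, w))
        cover = onp.zeros((h, w), dtype=int)
        wt = _feather_weight(tile, feather)
        for oy in _axis_origins(h, tile):
            for ox in _axis_origins(w, tile):
                p = _forward_plane(model, a0[oy : oy + tile, ox : ox + tile], a1[oy : oy + tile, ox : ox + tile], z)
                acc[oy : oy + tile, ox : ox + tile] += wt * p
                wsum[oy : oy + tile, ox : ox + tile] += wt
                last[oy : oy + tile, ox : ox + tile] = p
                cover[oy : oy + tile, ox : ox + tile] += 1
        # feathered blend only where tiles truly overlap; singly covered
        # pixels take the tile value directly (exact, no division artifact)
        pred = onp.where(cover == 1, last, acc / onp.maximum(wsum, 1e-12))

    out = pred * span + lo
    if onp.issubdtype(I0.dtype, onp.integer):
        return onp.clip(onp.rint(out), 0, 255).astype(I0.dtype)
    return out.astype(I0.dtype)


def predicted_stack_length(n: int, k: int) -> int:
    """Slice count after k doubling passes: 2^k (n-1) + 1."""
    if n < 2:
        raise ValueError("need at least 2 slices")
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2**k * (n - 1) + 1


def double_stack(model: InterpolatorModel, stack: Stack, tile: Optional[int] = None) -> Stack:
    """One doubling pass: 2n-1 slices, originals at even indices verbatim."""
    n = stack.n_slices
    planes: List[onp.ndarray] = []
    for i in range(n - 1):
        planes.append(stack.planes[i])
        planes.append(interpolate_pair(model, stack.planes[i], stack.planes[i + 1], 0.5, tile=tile))
    planes.append(stack.planes[n - 1])
    spacing = stack.voxel_spacing
    if spacing is not None:
        spacing = (spacing[0] / 2.0, spacing[1], spacing[2])
    return Stack(onp.stack(planes), voxel_spacing=spacing)


def augment_stack(model: InterpolatorModel, stack: Stack, k: int, tile: Optional[int] = None) -> Stack:
    """k-fold composition of :func:`double_stack` (2^k-fold axial gain)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = stack
    for _ in range(k):
        out = double_stack(model, out, tile=tile)
    return out


def insert_slices_plus(
    model: InterpolatorModel, stack: Stack, zs: Sequence[float], tile: Optional[int] = None
) -> Stack:
    """Insert predicted planes at each z of `zs` into every gap of the stack.

    Requires the continuous-z model; zs must be strictly increasing in
    (0, 1). Output length is n + (n-1) * len(zs), originals verbatim.
    """
    if not model.plus_variant:
        raise ValueError("continuous-z insertion requires a continuous-z (DPM) model")
    zs = list(zs)
    if any(not (0.0 < z < 1.0) for z in zs) or any(b <= a for a, b in zip(zs, zs[1:])):
        raise ValueError("zs must be strictly increasing within (0, 1)")
    if not zs:
        return stack
    n = stack.n_slices
    planes: List[onp.ndarray] = []
    for i in range(n - 1):
        planes.append(stack.planes[i])
        for z in zs:
            planes.append(interpolate_pair(model, stack.planes[i], stack.planes[i + 1], z, tile=tile))
    planes.append(stack.planes[n - 1])
    return Stack(onp.stack(planes), voxel_spacing=stack.voxel_spacing)


def bicubic_z_baseline(stack: Stack, factor: int) -> Stack:
    """Classical cubic interpolation along z onto the doubling slice grid.

    factor must be a power of two >= 2; output length matches
    :func:`predicted_stack_length` for k = log2(factor). Stacks with
    fewer than 4 slices fall back to linear interpolation (with a
    warning) since a cubic needs 4 support points.
    """
    if factor < 2 or (factor & (factor - 1)):
        raise ValueError("factor must be a power of two >= 2")
    k = factor.bit_length() - 1
    n = stack.n_slices
    m = predicted_stack_length(n, k)
    pos = onp.arange(m) / float(factor)
    data = stack.planes.astype(onp.float64)
    if n < 4:
        warnings.warn("fewer than 4 slices: falling back to linear z-interpolation")
        out = onp.empty((m,) + stack.plane_shape)
        for j, p in enumerate(pos):
            i0 = int(onp.floor(p))
            i1 = min(i0 + 1, n - 1)
            t = p - i0
            out[j] = (1 - t) * data[i0] + t * data[i1]
    else:
        out = CubicSpline(onp.arange(n), data, axis=0)(pos)
    # originals are carried over verbatim, like the learned interpolator
    out[::factor] = data
    if onp.issubdtype(stack.planes.dtype, onp.integer):
        out = onp.clip(onp.rint(out), 0, 255)
    spacing = stack.voxel_spacing
    if spacing is not None:
        spacing = (spacing[0] / factor, spacing[1], spacing[2])
    return Stack(out.astype(stack.planes.dtype), voxel_spacing=spacing)
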