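"""3D image stacks: TIFF I/O, 8-bit normalization and lateral patch tiling.

A stack is an ordered series of 2D focal planes (z, y, x). The working
representation is 8-bit grayscale: every pipeline stage downstream assumes
intensities in [0, 255]. Axial spacing is typically coarser than lateral
spacing, which is the whole reason this package exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile


@dataclass
class Stack:
    """An ordered z-series of 2D intensity planes.

    Parameters
    ----------
    planes : ndarray, shape (z, y, x)
        Slice data, z increasing with acquisition order. Working dtype is
        uint8 after :func:`normalize_minmax`.
    voxel_spacing : tuple (dz, dy, dx) in micrometres, optional
    """

    planes: np.ndarray
    voxel_spacing: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError(f"stack must be 3-D (z, y, x), got shape {self.planes.shape}")
        if self.planes.shape[0] < 2:
            raise ValueError("stack needs >=2 slices")

    @property
    def n_slices(self) -> int:
        return self.planes.shape[0]

    @property
    def plane_shape(self) -> Tuple[int, int]:
        return self.planes.shape[1:]

    def __len__(self) -> int:
        return self.n_slices

    def __getitem__(self, i):
        return self.planes[i]


@dataclass
class PatchGrid:
    """Row-major tiling of a (y, x) plane into fixed-size square patches.

    Non-multiple extents are handled by shifting the last row/column of
    patches to end-align with the plane (overlapping the previous patch);
    planes smaller than the patch are edge-padded.
    """

    patch_size: int
    plane_shape: Tuple[int, int]
    origins: Sequence[Tuple[int, int]] = field(default_factory=list)
    padded_shape: Tuple[int, int] = (0, 0)


def _axis_origins(extent: int, patch: int) -> list[int]:
    if extent <= patch:
        return [0]
    starts = list(range(0, extent - patch + 1, patch))
    if starts[-1] + patch < extent:
        starts.append(extent - patch)  # end-aligned, overlaps previous
    return starts


def read_stack(path) -> Stack:
    """Read a multi-page TIFF into a :class:`Stack`.

    Spacing metadata is recovered from ImageJ-style tags when present.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        if arr.ndim == 2:
            raise ValueError("stack needs >=2 slices")
        if arr.ndim != 3:
            raise ValueError(f"unsupported TIFF layout with shape {arr.shape}")
        spacing = None
        try:
            page = tf.pages[0]
            ij = tf.imagej_metadata or {}
            dz = ij.get("spacing")
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if dz is not None and xres is not None and yres is not None:
                xr = xres.value[0] / xres.value[1]
                yr = yres.value[0] / yres.value[1]
                if xr > 0 and yr > 0:
                    spacing = (float(dz), 1.0 / yr, 1.0 / xr)
        except Exception:
            spacing = None
    return Stack(arr, voxel_spacing=spacing)


def write_stack(stack: Stack, path) -> None:
    """Write a stack as a lossless multi-page TIFF (one page per plane)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    kwargs = {}
    if stack.voxel_spacing is not None:
        dz, dy, dx = stack.voxel_spacing
        kwargs = dict(
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
        )
        data = stack.planes
        # ImageJ TIFF only supports a few dtypes; the working dtype is uint8 anyway
        if data.dtype not in (np.uint8, np.uint16, np.float32):
            data = data.astype(np.float32)
        tifffile.imwrite(path, data, **kwargs)
    else:
        tifffile.imwrite(path, stack.planes, photometric="minisblack")


def normalize_minmax(a: np.ndarray | Stack):
    """Min-max normalize intensities onto the 8-bit range [0, 255].

    The minimum maps to 0, the maximum to 255, linearly in between, rounded
    to the nearest integer. A constant (zero-range) input maps to all zeros.
    Accepts a single plane, a (z, y, x) array, or a :class:`Stack`
    (normalized per stack, preserving inter-slice intensity relations).
    """
    if isinstance(a, Stack):
        return Stack(normalize_minmax(a.planes), voxel_spacing=a.voxel_spacing)
    a = np.asarray(a, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values in input")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros(a.shape, dtype=np.uint8)
    out = np.rint((a - lo) / (hi - lo) * 255.0)
    return out.astype(np.uint8)


def patchify(stack: Stack, patch_size: int) -> tuple[list[Stack], PatchGrid]:
    """Cut a stack into fixed-size lateral patches covering every voxel.

    Returns the patches (each a full-depth Stack) and the grid needed to
    reassemble them with :func:`unpatchify`.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    z, h, w = stack.planes.shape
    pad_y = max(0, patch_size - h)
    pad_x = max(0, patch_size - w)
    planes = stack.planes
    if pad_y or pad_x:
        planes = np.pad(planes, ((0, 0), (0, pad_y), (0, pad_x)), mode="edge")
    ph, pw = planes.shape[1:]
    origins = [(oy, ox) for oy in _axis_origins(ph, patch_size) for ox in _axis_origins(pw, patch_size)]
    grid = PatchGrid(patch_size=patch_size, plane_shape=(h, w), origins=origins, padded_shape=(ph, pw))
    patches = [
        Stack(planes[:, oy : oy + patch_size, ox : ox + patch_size].copy(), voxel_spacing=stack.voxel_spacing)
        for oy, ox in origins
    ]
    return patches, grid


def unpatchify(patches: Sequence[Stack], grid: PatchGrid) -> Stack:
    """Reassemble patches produced by :func:`patchify` (last writer wins)."""
    if len(patches) != len(grid.origins):
        raise ValueError("number of patches does not match grid")
    z = patches[0].n_slices
    ps = grid.patch_size
    out = np.zeros((z, *grid.padded_shape), dtype=patches[0].planes.dtype)
    for patch, (oy, ox) in zip(patches, grid.origins):
        if patch.planes.shape != (z, ps, ps):
            raise ValueError("patch shape does not match grid")
        out[:, oy : oy + ps, ox : ox + ps] = patch.planes
    h, w = grid.plane_shape
    return Stack(out[:, :h, :w], voxel_spacing=patches[0].voxel_spacing)
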