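"""Image-quality metrics: RMSE, PSNR, SSIM, FID and the inter-stack protocol.

All pixel metrics operate on the 8-bit working scale (dynamic range 255).
SSIM follows the original windowed formulation: 11x11 Gaussian window
(sigma = 1.5, truncated at 3.5 sigma), k1 = 0.01, k2 = 0.03, population
covariances, border crop of half a window.

FID fits a Gaussian to embedded features of each image set and reports
the Fréchet distance  ||mu_a - mu_b||^2 + Tr(Sa + Sb - 2 (Sa Sb)^{1/2}).
The feature embedder is injectable; the shipped default is a fixed,
seeded random projection of the (optionally resized) pixels, which keeps
the statistic self-contained and deterministic. Absolute values are then
not comparable to Inception-based FID numbers, but orderings of similar
sets against a common reference are preserved in practice.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy import linalg, ndimage

from .stacks import Stack


def _check_pair(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(a, b) -> float:
    """Root-mean-square error on the 8-bit scale."""
    a, b = _check_pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a, b, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    r = rmse(a, b)
    if r == 0:
        return math.inf
    return 20.0 * math.log10(max_val / r)


def ssim(a, b, data_range: float = 255.0, sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with the reference Gaussian-window setup."""
    a, b = _check_pair(a, b)
    truncate = 3.5
    r = int(truncate * sigma + 0.5)  # 11x11 window for sigma 1.5
    win = 2 * r + 1
    if min(a.shape) < win:
        raise ValueError(f"images smaller than the {win}x{win} SSIM window")

    def filt(x):
        return ndimage.gaussian_filter(x, sigma, truncate=truncate, mode="nearest")

    ux, uy = filt(a), filt(b)
    uxx, uyy, uxy = filt(a * a), filt(b * b), filt(a * b)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    return float(s[r:-r, r:-r].mean())


class RandomProjectionEmbedder:
    """Deterministic pixel-space embedding: fixed Gaussian random projection.

    Images are flattened (resampled to `input_size` squared if needed) and
    projected to `dim` features with a matrix drawn once from `seed`.
    """

    def __init__(self, dim: int = 64, input_size: int = 64, seed: int = 0):
        self.dim = dim
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        n = input_size * input_size
        self.matrix = rng.standard_normal((n, dim)) / np.sqrt(n)

    def __call__(self, images: Sequence[np.ndarray]) -> np.ndarray:
        feats = []
        for im in images:
            im = np.asarray(im, dtype=np.float64)
            if im.shape != (self.input_size, self.input_size):
                zy = self.input_size / im.shape[0]
                zx = self.input_size / im.shape[1]
                im = ndimage.zoom(im, (zy, zx), order=1)[: self.input_size, : self.input_size]
            feats.append(im.ravel() @ self.matrix)
        return np.stack(feats)


def fid(set_a: Sequence[np.ndarray], set_b: Sequence[np.ndarray], embedder: Optional[Callable] = None) -> float:
    """Fréchet distance between Gaussian fits of embedded image sets."""
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each set needs >=2 images for a covariance estimate")
    embedder = embedder or RandomProjectionEmbedder()
    fa = np.asarray(embedder(set_a), dtype=np.float64)
    fb = np.asarray(embedder(set_b), dtype=np.float64)
    mu_a, mu_b = fa.mean(0), fb.mean(0)
    ca = np.cov(fa, rowvar=False)
    cb = np.cov(fb, rowvar=False)
    ca = np.atleast_2d(ca)
    cb = np.atleast_2d(cb)
    covmean = linalg.sqrtm(ca @ cb)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    d2 = float(np.sum((mu_a - mu_b) ** 2) + np.trace(ca + cb - 2.0 * covmean))
    return max(d2, 0.0)


def interstack_error(pred: Stack, truth: Stack, stride: int) -> Dict[str, float]:
    """Average error over generated (non-original) slices only.

    Every stride-th slice of `pred` is an original acquisition and is
    excluded; e.g. stride 8 evaluates the 7 generated planes per gap.
    Returns means of rmse/psnr/ssim and the evaluated slice count.
    """
    if pred.n_slices != truth.n_slices:
        raise ValueError("stacks must have equal length")
    if stride < 2:
        raise ValueError("stride must be >= 2")
    idx = [i for i in range(pred.n_slices) if i % stride != 0]
    if not idx:
        raise ValueError("no generated slices to evaluate")
    r = [rmse(pred.planes[i], truth.planes[i]) for i in idx]
    p = [psnr(pred.planes[i], truth.planes[i]) for i in idx]
    s = [ssim(pred.planes[i], truth.planes[i]) for i in idx]
    return {
        "rmse": float(np.mean(r)),
        "psnr": float(np.mean(p)),
        "ssim": float(np.mean(s)),
        "n_slices_evaluated": len(idx),
    }
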