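"""Synthetic 3D phantoms with known geometry for end-to-end testing.

Three object classes emulate the sample types the interpolator targets:

* ``shell`` — a bright membrane drawn at a (possibly harmonically
  perturbed) star-convex surface R(theta, phi) = R0 (1 + eps Y_lm),
  mimicking membrane-stained embryos;
* ``blob`` — the same surface filled, mimicking stained nuclei;
* ``filaments`` — random smooth 3D curves with a Gaussian profile,
  mimicking cytoskeletal networks.

Stacks are rendered on an anisotropic grid (slice spacing `dz` in units
of the lateral voxel), blurred with an elongated axial PSF and corrupted
with noise — the degradations that motivate axial super-resolution. The
noiseless integer label mask and the prescribed harmonic perturbation
are returned as ground truth, so the morphometrics pipeline's parameter
recovery can be tested against known coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .morphometrics import real_sph_harm
from .stacks import Stack, normalize_minmax


@dataclass
class PhantomSpec:
    """Geometry, optics and noise of one synthetic stack."""

    kind: str = "shell"  # shell | blob | filaments
    size: int = 64  # lateral extent (pixels)
    n_slices: int = 64
    dz: float = 1.0  # slice spacing in lateral-voxel units
    radius: float = 20.0
    center: Optional[Tuple[float, float, float]] = None  # (z, y, x), physical z
    drift: Tuple[float, float] = (0.0, 0.0)  # lateral (dy, dx) per slice
    harmonic: Optional[Tuple[int, int, float]] = None  # (l, m, eps)
    membrane_sigma: float = 1.5  # shell thickness (voxels)
    psf_sigma: Tuple[float, float] = (2.0, 0.8)  # (axial, lateral) blur in voxels
    noise_sigma: float = 4.0  # additive Gaussian on the 8-bit scale
    poisson: bool = False
    n_filaments: int = 12
    filament_radius: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("shell", "blob", "filaments"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.n_slices < 3:
            raise ValueError("phantoms need >= 3 slices")
        if self.harmonic is not None:
            l, m, eps = self.harmonic
            if abs(eps) > 0.3:
                raise ValueError("harmonic amplitude must stay <= 0.3 (star-convex surface)")
            if not (-l <= m <= l):
                raise ValueError("harmonic order must satisfy |m| <= l")
        if self.kind in ("shell", "blob"):
            if self.radius >= self.size / 2:
                raise ValueError("radius must fit inside the lateral extent")
            if max(abs(d) for d in self.drift) * self.n_slices > self.radius:
                raise ValueError("total center drift exceeds the radius")


@dataclass
class PhantomTruth:
    """Noise-free ground truth accompanying a rendered phantom."""

    label_mask: np.ndarray  # (z, y, x) integer labels, 0 background
    harmonic: Optional[Tuple[int, int, float]]
    center: Optional[Tuple[float, float, float]]
    radius: Optional[float]


def _surface_radius(spec: PhantomSpec, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    R = np.full(theta.shape, spec.radius)
    if spec.harmonic is not None:
        l, m, eps = spec.harmonic
        R = spec.radius * (1.0 + eps * real_sph_harm(l, m, theta, phi))
    return R


def _render_surface_object(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    n, s = spec.n_slices, spec.size
    if spec.center is None:
        cz = (n - 1) / 2.0 * spec.dz
        cy = cx = (s - 1) / 2.0
    else:
        cz, cy, cx = spec.center
    zs = np.arange(n)[:, None, None] * spec.dz
    ys = np.arange(s)[None, :, None].astype(float)
    xs = np.arange(s)[None, None, :].astype(float)
    dy_drift = np.arange(n)[:, None, None] * spec.drift[0]
    dx_drift = np.arange(n)[:, None, None] * spec.drift[1]
    dzv = zs - cz
    dyv = ys - (cy + dy_drift)
    dxv = xs - (cx + dx_drift)
    r = np.sqrt(dzv**2 + dyv**2 + dxv**2)
    r_safe = np.maximum(r, 1e-12)
    theta = np.arccos(np.clip(np.broadcast_to(dzv, r.shape) / r_safe, -1, 1))
    phi = np.mod(np.arctan2(dyv, dxv), 2 * np.pi)
    Rsurf = _surface_radius(spec, theta, phi)
    label = (r <= Rsurf).astype(np.int32)
    if spec.kind == "shell":
        vol = 255.0 * np.exp(-((r - Rsurf) ** 2) / (2.0 * spec.membrane_sigma**2))
    else:  # blob: filled with a soft edge half a voxel wide
        vol = 255.0 / (1.0 + np.exp((r - Rsurf) / 0.5))
    return vol, label


def _render_filaments(spec: PhantomSpec, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    n, s = spec.n_slices, spec.size
    depth = (n - 1) * spec.dz
    skel = np.zeros((n, s, s), dtype=bool)
    for _ in range(spec.n_filaments):
        p = np.array([rng.uniform(0, depth), rng.uniform(0, s - 1), rng.uniform(0, s - 1)])
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        steps = int(rng.integers(s // 2, 2 * s))
        for _ in range(steps):
            turn = rng.standard_normal(3) * 0.15
            d = d + turn
            d /= np.linalg.norm(d)
            p = p + 0.5 * d
            if not (0 <= p[0] <= depth and 0 <= p[1] <= s - 1 and 0 <= p[2] <= s - 1):
                break
            iz = int(round(p[0] / spec.dz))
            if 0 <= iz < n:
                skel[iz, int(round(p[1])), int(round(p[2]))] = True
    label = ndimage.binary_dilation(skel, iterations=max(1, int(spec.filament_radius))).astype(np.int32)
    vol = 255.0 * ndimage.gaussian_filter(skel.astype(float), spec.filament_radius) * 8.0
    return np.clip(vol, 0, 255), label


def make_phantom(spec: PhantomSpec) -> Tuple[Stack, PhantomTruth]:
    """Render one phantom stack; deterministic given spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "filaments":
        vol, label = _render_filaments(spec, rng)
    else:
        vol, label = _render_surface_object(spec)
    sz, sl = spec.psf_sigma
    img = ndimage.gaussian_filter(vol, (sz / max(spec.dz, 1e-9), sl, sl))
    if spec.poisson:
        img = rng.poisson(np.maximum(img, 0)).astype(float)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)
    planes = normalize_minmax(img)
    stack = Stack(planes, voxel_spacing=(spec.dz, 1.0, 1.0))
    if spec.center is None and spec.kind != "filaments":
        center = ((spec.n_slices - 1) / 2.0 * spec.dz, (spec.size - 1) / 2.0, (spec.size - 1) / 2.0)
    else:
        center = spec.center
    truth = PhantomTruth(
        label_mask=label,
        harmonic=spec.harmonic,
        center=None if spec.kind == "filaments" else center,
        radius=None if spec.kind == "filaments" else spec.radius,
    )
    return stack, truth


def make_training_pair(stack: Stack) -> Tuple[Stack, Stack]:
    """Drop every second slice: (low-resolution stack, full stack).

    The low-resolution stack keeps the even-index slices; for odd n one
    doubling pass of the low stack recovers exactly n slices.
    """
    if stack.n_slices < 3:
        raise ValueError("need >= 3 slices to build a training pair")
    low_planes = stack.planes[::2]
    spacing = stack.voxel_spacing
    low_spacing = (spacing[0] * 2, spacing[1], spacing[2]) if spacing else None
    return Stack(low_planes.copy(), voxel_spacing=low_spacing), stack


def make_interp_testbed(
    spec: Optional[PhantomSpec] = None, n_stacks: int = 20, seed: int = 0
) -> List[Tuple[Tuple[Stack, Stack], PhantomTruth]]:
    """A dataset of smoothly varying shell stacks for end-to-end tests.

    Each stack perturbs the base spec's radius, center and lateral drift
    (kept <= 1 voxel per slice so mid-slice prediction is learnable at
    toy scale) with stack-specific seeds; fully deterministic in `seed`.
    Returns [((low_res, full), truth), ...].
    """
    base = spec or PhantomSpec(
        kind="shell", size=64, n_slices=9, dz=4.0, radius=20.0, noise_sigma=3.0, psf_sigma=(1.5, 0.8)
    )
    base.validate()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_stacks):
        r = base.radius * rng.uniform(0.85, 1.15)
        drift = tuple(rng.uniform(-1.0, 1.0, size=2))
        c = (
            (base.n_slices - 1) / 2.0 * base.dz + rng.uniform(-2, 2),
            (base.size - 1) / 2.0 + rng.uniform(-3, 3),
            (base.size - 1) / 2.0 + rng.uniform(-3, 3),
        )
        s = replace(base, radius=r, drift=drift, center=c, seed=int(rng.integers(2**31 - 1)))
        stack, truth = make_phantom(s)
        out.append((make_training_pair(stack), truth))
    return out
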