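"""Surface morphometrics: harmonic shape spectra, roughness, label matching.

For a labeled 3D object the outer surface voxels (six-connected boundary)
are expressed in spherical coordinates (theta, phi, R) about the object's
centroid, assuming a star-convex surface so the radius function
R(theta, phi) is single-valued. The radius is expanded on real
orthonormal spherical harmonics up to degree lmax,

    R(theta, phi) = sum_{l,m} f_lm Y_lm(theta, phi),

by least squares. The per-degree power, normalized by the mean radius
(<R> = f00 / sqrt(4 pi), since Y00 = 1/(2 sqrt(pi))), is

    P_l = 4 pi / ((2l + 1) f00^2) * sum_m f_lm^2,

which is rotation-invariant and scale-free. The roughness statistic

    Ro = sum_{l >= 3} (2l + 1) P_l

collects the power of fine-scale (short-wavelength) deformations only,
excluding translation-like (l=1) and ellipsoidal (l=2) modes.

Mask comparison utilities implement the max-overlap label matching used
to pair segmented objects across two masks and the per-pair volume
(voxel-count) comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import sph_harm_y


@dataclass
class SurfacePointCloud:
    """Boundary voxels of one labeled object, in cartesian and spherical form."""

    points: np.ndarray  # (n, 3) as (x, y, z) voxel coordinates
    center: np.ndarray  # (3,) centroid of ALL voxels of the label
    theta: np.ndarray  # polar angle in [0, pi]
    phi: np.ndarray  # azimuth in [0, 2 pi)
    radius: np.ndarray  # distance to center, > 0


@dataclass
class HarmonicSpectrum:
    """Real spherical-harmonic expansion of a surface radius function."""

    flm: np.ndarray  # ((lmax+1)^2,) coefficients, ordered (l, m) m=-l..l
    lmax: int

    def coefficient(self, l: int, m: int) -> float:
        if not (0 <= l <= self.lmax and -l <= m <= l):
            raise ValueError(f"invalid (l={l}, m={m})")
        return float(self.flm[l * l + (m + l)])

    @property
    def f00(self) -> float:
        return float(self.flm[0])

    @property
    def mean_radius(self) -> float:
        return self.f00 / np.sqrt(4.0 * np.pi)

    def relative_amplitude(self, l: int, m: int) -> float:
        """f_lm / <R>: the dimensionless amplitude of one deformation mode.

        For a surface R0 (1 + eps Y_lm) this recovers eps (the raw ratio
        f_lm/f00 would carry the extra 1/(2 sqrt(pi)) of Y00).
        """
        return self.coefficient(l, m) / self.mean_radius


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonic Y_lm (integral of Y^2 over the
    sphere is 1), built from the complex harmonics of scipy."""
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(sph_harm_y(l, m, theta, phi))
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(sph_harm_y(l, -m, theta, phi))


def harmonic_design_matrix(theta: np.ndarray, phi: np.ndarray, lmax: int) -> np.ndarray:
    cols = [real_sph_harm(l, m, theta, phi) for l in range(lmax + 1) for m in range(-l, l + 1)]
    return np.stack(cols, axis=1)


def extract_surface_points(mask: np.ndarray, label: int) -> SurfacePointCloud:
    """Outer-boundary voxels of `label`: voxels with a six-connected
    background (or out-of-volume) neighbour, in spherical coordinates
    about the centroid of all voxels of the label."""
    mask = np.asarray(mask)
    sel = mask == label
    if not sel.any():
        raise ValueError(f"label {label} not present in mask")
    interior = ndimage.binary_erosion(sel, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    surface = sel & ~interior
    zyx = np.argwhere(surface).astype(np.float64)
    center_zyx = np.argwhere(sel).astype(np.float64).mean(axis=0)
    if len(zyx) < 10:
        warnings.warn(f"label {label} has only {len(zyx)} surface voxels; spectrum unreliable")
    d = zyx - center_zyx
    r = np.linalg.norm(d, axis=1)
    r = np.maximum(r, 1e-12)
    theta = np.arccos(np.clip(d[:, 0] / r, -1.0, 1.0))  # polar from +z
    phi = np.mod(np.arctan2(d[:, 1], d[:, 2]), 2.0 * np.pi)  # azimuth about z
    points = zyx[:, ::-1].copy()  # (x, y, z)
    center = center_zyx[::-1].copy()
    return SurfacePointCloud(points=points, center=center, theta=theta, phi=phi, radius=r)


def fit_spherical_harmonics(cloud: SurfacePointCloud, lmax: int = 5) -> HarmonicSpectrum:
    """Least-squares fit of R(theta, phi) on real harmonics up to lmax."""
    n_coeff = (lmax + 1) ** 2
    if len(cloud.radius) < n_coeff:
        raise ValueError(f"need >= {n_coeff} surface points for lmax={lmax}")
    A = harmonic_design_matrix(cloud.theta, cloud.phi, lmax)
    flm, *_ = np.linalg.lstsq(A, cloud.radius, rcond=None)
    return HarmonicSpectrum(flm=flm, lmax=lmax)


def power_spectrum(spectrum: HarmonicSpectrum) -> np.ndarray:
    """Normalized radial-deformation power P_l for l = 0..lmax.

    P_l = 4 pi / ((2l + 1) f00^2) * sum_m f_lm^2; invariant to rotations
    of the shape and to uniform scaling.
    """
    if spectrum.f00 == 0:
        raise ValueError("f00 is zero; power spectrum undefined")
    out = np.empty(spectrum.lmax + 1)
    for l in range(spectrum.lmax + 1):
        s = float(np.sum(spectrum.flm[l * l : (l + 1) ** 2] ** 2))
        out[l] = 4.0 * np.pi / ((2 * l + 1) * spectrum.f00**2) * s
    return out


def roughness(spectrum: HarmonicSpectrum) -> float:
    """Total fine-scale power Ro = sum_{l>=3} (2l+1) P_l."""
    if spectrum.lmax < 3:
        raise ValueError("roughness needs lmax >= 3")
    P = power_spectrum(spectrum)
    ls = np.arange(3, spectrum.lmax + 1)
    return float(np.sum((2 * ls + 1) * P[3:]))


def roughness_of_label(mask: np.ndarray, label: int, lmax: int = 5) -> Dict[str, object]:
    """Full pipeline for one label: surface -> spectrum -> P_l -> Ro."""
    cloud = extract_surface_points(mask, label)
    spec = fit_spherical_harmonics(cloud, lmax)
    P = power_spectrum(spec)
    return {
        "label": int(label),
        "f00": spec.f00,
        "mean_radius": spec.mean_radius,
        "Pl": P.tolist(),
        "Ro": roughness(spec),
        "n_surface_voxels": int(len(cloud.radius)),
    }


def match_labels_by_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> Dict[int, Optional[int]]:
    """Map each nonzero label of mask_a to the mask_b label with maximal
    voxel overlap (ties broken by the smaller b label); labels whose
    overlap with every b label is zero map to None."""
    mask_a = np.asarray(mask_a)
    mask_b = np.asarray(mask_b)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share one shape")
    fa = mask_a.ravel()
    fb = mask_b.ravel()
    both = (fa > 0) & (fb > 0)
    mapping: Dict[int, Optional[int]] = {int(a): None for a in np.unique(fa) if a > 0}
    if both.any():
        pairs, counts = np.unique(np.stack([fa[both], fb[both]]), axis=1, return_counts=True)
        best: Dict[int, tuple] = {}
        for (a, b), c in zip(pairs.T, counts):
            a, b, c = int(a), int(b), int(c)
            # higher count wins; at equal counts the smaller b label wins
            key = (c, -b)
            if a not in best or key > best[a][0]:
                best[a] = (key, b)
        for a, (_, b) in best.items():
            mapping[a] = b
    return mapping


def compare_volumes(mask_a: np.ndarray, mask_b: np.ndarray, mapping: Dict[int, Optional[int]]) -> pd.DataFrame:
    """Voxel counts of every matched label pair; unmatched a-labels get
    vol_b = 0. Columns: label_a, vol_a, label_b, vol_b."""
    mask_a = np.asarray(mask_a)
    mask_b = np.asarray(mask_b)
    rows = []
    for a, b in sorted(mapping.items()):
        vol_a = int(np.count_nonzero(mask_a == a))
        vol_b = int(np.count_nonzero(mask_b == b)) if b is not None else 0
        rows.append({"label_a": a, "vol_a": vol_a, "label_b": b, "vol_b": vol_b})
    return pd.DataFrame(rows, columns=["label_a", "vol_a", "label_b", "vol_b"])


def relabel_2d_by_3d(mask2d_stack: np.ndarray, mask3d: np.ndarray) -> np.ndarray:
    """Give z-consistent identities to per-slice 2D labels using a 3D mask.

    Each 2D-segmented object in each slice is renamed to the 3D label
    with the highest pixel overlap in that slice (the same max-overlap
    primitive, applied slice by slice); objects with no overlap become
    background.
    """
    mask2d_stack = np.asarray(mask2d_stack)
    mask3d = np.asarray(mask3d)
    if mask2d_stack.shape != mask3d.shape:
        raise ValueError("masks must share one shape")
    out = np.zeros_like(mask3d)
    for z in range(mask2d_stack.shape[0]):
        m2 = mask2d_stack[z][None]
        m3 = mask3d[z][None]
        mapping = match_labels_by_overlap(m2, m3)
        for a, b in mapping.items():
            if b is not None:
                out[z][mask2d_stack[z] == a] = b
    return out
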