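"""Self-supervised training triplets and the constant-z DPM input plane.

The training signal is built without annotation: dropping intermediate
slices from an acquired high-resolution stack yields (I0, Izg, I1) triples
where the dropped slice Izg is ground truth for interpolation at relative
depth z = (n2 - n1) / (n3 - n1).

Two extraction regimes exist: the fixed-midpoint regime takes all
consecutive index triples (z = 0.5 exactly) and trains the plain
interpolator; the windowed regime enumerates all strictly increasing
triples inside every sliding window of 8 slices, yielding varied z in
(0, 1) for the continuous-z variant, which receives the target depth as a
constant Digital Propagation Matrix (DPM) input channel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .stacks import Stack


@dataclass
class SliceTriplet:
    """Two bracketing planes, the in-between ground truth, and its depth z."""

    I0: np.ndarray
    Izg: np.ndarray
    I1: np.ndarray
    z: float
    source: Optional[Tuple[str, int, int, int]] = None  # (stack id, n1, n2, n3)

    def __post_init__(self) -> None:
        if not (self.I0.shape == self.I1.shape == self.Izg.shape):
            raise ValueError("triplet planes must share one shape")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"z must lie in (0, 1), got {self.z}")


@dataclass
class DPMPlane:
    """Constant plane encoding the requested relative depth z in [0, 1].

    z = 0 is the first input focal plane, z = 1 the second.
    """

    values: np.ndarray
    z: float


@dataclass
class AugmentSpec:
    """Paired photometric/geometric augmentation for one triplet.

    One transform is sampled per triplet and applied identically to all
    three planes; z is never altered. Rotations are restricted to right
    angles (lossless on square rasters); contrast is a multiplicative
    factor, brightness an additive offset on the 8-bit scale.
    """

    contrast_range: Tuple[float, float] = (0.9, 1.1)
    brightness_range: Tuple[float, float] = (-10.0, 10.0)
    rotations: Tuple[int, ...] = (0, 90, 180, 270)
    p_hflip: float = 0.5

    @classmethod
    def identity(cls) -> "AugmentSpec":
        return cls(contrast_range=(1.0, 1.0), brightness_range=(0.0, 0.0), rotations=(0,), p_hflip=0.0)


def extract_fixed_triplets(stack: Stack, stack_id: str = "stack") -> List[SliceTriplet]:
    """All consecutive (i, i+1, i+2) triples of a stack, each with z = 0.5.

    A stack of n slices yields n - 2 triplets; n < 3 yields none.
    """
    planes = stack.planes
    out: List[SliceTriplet] = []
    for i in range(len(planes) - 2):
        out.append(
            SliceTriplet(planes[i], planes[i + 1], planes[i + 2], 0.5, source=(stack_id, i, i + 1, i + 2))
        )
    return out


def extract_plus_triplets(stack: Stack, window: int = 8, stack_id: str = "stack") -> List[SliceTriplet]:
    """Windowed enumeration of strictly increasing index triples.

    For every window of `window` consecutive slices, all n1 < n2 < n3
    inside it are taken; triples appearing in several overlapping windows
    are emitted once. Each triplet carries z = (n2 - n1) / (n3 - n1).
    Stacks shorter than the window degrade to all C(N, 3) triples.
    """
    n = stack.n_slices
    seen = set()
    for t in range(min(window, n) - 1, n):
        lo = t - window + 1
        idx = range(max(0, lo), t + 1)
        for a in idx:
            for b in range(a + 1, t + 1):
                for c in range(b + 1, t + 1):
                    seen.add((a, b, c))
    out = []
    for n1, n2, n3 in sorted(seen):
        z = (n2 - n1) / (n3 - n1)
        out.append(SliceTriplet(stack.planes[n1], stack.planes[n2], stack.planes[n3], z, source=(stack_id, n1, n2, n3)))
    return out


def make_dpm(z: float, shape: Tuple[int, int]) -> DPMPlane:
    """Constant plane of value z (relative depth toward the second plane)."""
    if not (0.0 <= z <= 1.0):
        raise ValueError(f"z must lie in [0, 1], got {z}")
    return DPMPlane(np.full(shape, float(z)), float(z))


def augment_triplet(triplet: SliceTriplet, spec: AugmentSpec, rng: np.random.Generator) -> SliceTriplet:
    """Apply one sampled paired transform to all three planes of a triplet."""
    gain = rng.uniform(*spec.contrast_range)
    offset = rng.uniform(*spec.brightness_range)
    rot = int(rng.choice(spec.rotations))
    flip = rng.uniform() < spec.p_hflip

    def tf(plane: np.ndarray) -> np.ndarray:
        out = plane.astype(np.float64) * gain + offset
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        k = rot // 90
        if k:
            out = np.rot90(out, k)
        if flip:
            out = np.fliplr(out)
        return np.ascontiguousarray(out)

    return SliceTriplet(tf(triplet.I0), tf(triplet.Izg), tf(triplet.I1), triplet.z, source=triplet.source)


def save_triplets(triplets: Sequence[SliceTriplet], directory) -> Path:
    """Serialize a triplet cache: per-triplet .npz files + a TSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["file", "stack_id", "n1", "n2", "n3", "z"])
        for i, t in enumerate(triplets):
            name = f"triplet_{i:06d}.npz"
            np.savez(directory / name, I0=t.I0, Izg=t.Izg, I1=t.I1, z=t.z)
            sid, n1, n2, n3 = t.source if t.source else ("", -1, -1, -1)
            w.writerow([name, sid, n1, n2, n3, f"{t.z:.8g}"])
    return manifest


def load_triplets(directory) -> List[SliceTriplet]:
    """Load a triplet cache written by :func:`save_triplets`."""
    directory = Path(directory)
    out = []
    with open(directory / "manifest.tsv") as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            data = np.load(directory / row["file"])
            src = (row["stack_id"], int(row["n1"]), int(row["n2"]), int(row["n3"]))
            out.append(SliceTriplet(data["I0"], data["Izg"], data["I1"], float(row["z"]), source=src))
    return out
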