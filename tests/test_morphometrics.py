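"""Surface extraction, harmonic fitting, roughness, and label matching."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from zslice.morphometrics import (
    SurfacePointCloud,
    compare_volumes,
    extract_surface_points,
    fit_spherical_harmonics,
    match_labels_by_overlap,
    power_spectrum,
    real_sph_harm,
    relabel_2d_by_3d,
    roughness,
    roughness_of_label,
)


def _angular_grid(nt=60, np_=120):
    th = np.linspace(0.05, np.pi - 0.05, nt)
    ph = np.linspace(0, 2 * np.pi, np_, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    return T.ravel(), P.ravel()


def _cloud(theta, phi, r):
    return SurfacePointCloud(points=None, center=np.zeros(3), theta=theta, phi=phi, radius=np.asarray(r, float))


def _ball_mask(radius, size):
    c = (size - 1) / 2
    z, y, x = np.ogrid[:size, :size, :size]
    return ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius**2).astype(np.int32)


class TestSurfaceExtraction:
    def test_cube_surface_voxel_count(self):
        mask = np.zeros((5, 5, 5), dtype=int)
        mask[1:4, 1:4, 1:4] = 1
        cloud = extract_surface_points(mask, 1)
        assert len(cloud.radius) == 26  # all but the center voxel

    def test_single_voxel_warns(self):
        mask = np.zeros((3, 3, 3), dtype=int)
        mask[1, 1, 1] = 1
        with pytest.warns(UserWarning, match="unreliable"):
            cloud = extract_surface_points(mask, 1)
        assert len(cloud.radius) == 1

    def test_ball_centroid_accuracy(self):
        mask = _ball_mask(10, 31)
        cloud = extract_surface_points(mask, 1)
        assert np.all(np.abs(cloud.center - 15.0) < 0.1)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            extract_surface_points(np.zeros((4, 4, 4), dtype=int), 3)

    def test_angles_in_range(self):
        cloud = extract_surface_points(_ball_mask(8, 25), 1)
        assert np.all((cloud.theta >= 0) & (cloud.theta <= np.pi))
        assert np.all((cloud.phi >= 0) & (cloud.phi < 2 * np.pi))
        assert np.all(cloud.radius > 0)


class TestHarmonicFit:
    def test_sphere_coefficients_analytic(self):
        th, ph = _angular_grid()
        spec = fit_spherical_harmonics(_cloud(th, ph, np.full(th.size, 10.0)), 5)
        assert spec.f00 == pytest.approx(10.0 * 2 * np.sqrt(np.pi), rel=1e-10)
        assert np.max(np.abs(spec.flm[1:])) < 1e-8
        assert spec.mean_radius == pytest.approx(10.0, rel=1e-10)

    def test_l2_mode_relative_amplitude_recovered(self):
        th, ph = _angular_grid()
        r = 10.0 * (1 + 0.1 * real_sph_harm(2, 0, th, ph))
        spec = fit_spherical_harmonics(_cloud(th, ph, r), 5)
        assert spec.relative_amplitude(2, 0) == pytest.approx(0.1, abs=1e-6)

    def test_projector_exact_on_spanned_functions(self, rng):
        th, ph = _angular_grid(30, 60)
        r = np.zeros(th.size)
        coeffs = {}
        for l, m in [(0, 0), (1, 1), (3, -2), (5, 4)]:
            c = float(rng.normal())
            coeffs[(l, m)] = c
            r += c * real_sph_harm(l, m, th, ph)
        spec = fit_spherical_harmonics(_cloud(th, ph, r), 5)
        for (l, m), c in coeffs.items():
            assert spec.coefficient(l, m) == pytest.approx(c, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_spherical_harmonics(_cloud(np.array([1.0]), np.array([1.0]), np.array([5.0])), 5)


class TestPowerAndRoughness:
    def test_sphere_power_spectrum(self):
        th, ph = _angular_grid()
        spec = fit_spherical_harmonics(_cloud(th, ph, np.full(th.size, 7.0)), 5)
        P = power_spectrum(spec)
        assert P[0] == pytest.approx(4 * np.pi)
        assert np.all(P[1:] < 1e-20)
        assert roughness(spec) == pytest.approx(0.0, abs=1e-18)

    def test_l2_deformation_excluded_from_roughness(self):
        th, ph = _angular_grid()
        r = 10.0 * (1 + 0.1 * real_sph_harm(2, 0, th, ph))
        spec = fit_spherical_harmonics(_cloud(th, ph, r), 5)
        assert roughness(spec) == pytest.approx(0.0, abs=1e-12)

    def test_l4_roughness_closed_form(self):
        th, ph = _angular_grid()
        eps = 0.1
        r = 10.0 * (1 + eps * real_sph_harm(4, 0, th, ph))
        spec = fit_spherical_harmonics(_cloud(th, ph, r), 5)
        P = power_spectrum(spec)
        # P4 = (4 pi / (9 f00^2)) f40^2 with f40 = eps * R0, f00 = R0 2 sqrt(pi)
        expected_P4 = (4 * np.pi / 9) * (eps / (2 * np.sqrt(np.pi))) ** 2
        assert P[4] == pytest.approx(expected_P4, rel=1e-6)
        assert roughness(spec) == pytest.approx(9 * P[4], rel=1e-6)

    def test_scale_invariance(self):
        th, ph = _angular_grid()
        r = 10.0 * (1 + 0.05 * real_sph_harm(4, 2, th, ph))
        P1 = power_spectrum(fit_spherical_harmonics(_cloud(th, ph, r), 5))
        P2 = power_spectrum(fit_spherical_harmonics(_cloud(th, ph, 3.7 * r), 5))
        assert np.allclose(P1, P2, rtol=1e-10)

    def test_rotation_invariance_of_roughness(self):
        th, ph = _angular_grid()
        r = 10.0 * (1 + 0.08 * real_sph_harm(4, 0, th, ph))
        spec = fit_spherical_harmonics(_cloud(th, ph, r), 5)
        R = Rotation.from_euler("zyx", [33, 21, 48], degrees=True).as_matrix()
        d = np.stack([np.cos(th), np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph)], 1)
        v = d * r[:, None] @ R.T
        rr = np.linalg.norm(v, axis=1)
        th2 = np.arccos(np.clip(v[:, 0] / rr, -1, 1))
        ph2 = np.mod(np.arctan2(v[:, 1], v[:, 2]), 2 * np.pi)
        spec2 = fit_spherical_harmonics(_cloud(th2, ph2, rr), 5)
        assert roughness(spec2) == pytest.approx(roughness(spec), rel=1e-6)

    def test_lmax_below_three_rejected(self):
        th, ph = _angular_grid(20, 40)
        spec = fit_spherical_harmonics(_cloud(th, ph, np.full(th.size, 5.0)), 2)
        with pytest.raises(ValueError):
            roughness(spec)


class TestLabelMatching:
    def test_identity_mapping(self, rng):
        mask = rng.integers(0, 4, (6, 6, 6))
        mapping = match_labels_by_overlap(mask, mask)
        assert mapping == {l: l for l in np.unique(mask) if l > 0}

    def test_max_overlap_wins(self):
        a = np.zeros((1, 5, 8), dtype=int)
        b = np.zeros((1, 5, 8), dtype=int)
        a[0, :, :8] = 1
        b[0, :3, :6] = 2  # 18 voxels of overlap (trimmed below to 30/10 split)
        a[:] = 0
        a[0, :5, :8] = 1  # 40 voxels
        b[:] = 0
        b[0, :5, :6] = 2  # overlap 30
        b[0, :5, 6:8] = 7  # overlap 10
        assert match_labels_by_overlap(a, b) == {1: 2}

    def test_tie_breaks_to_smaller_label(self):
        a = np.zeros((1, 1, 4), dtype=int)
        a[0, 0, :2] = 1
        b = np.zeros((1, 1, 4), dtype=int)
        b[0, 0, 0] = 9
        b[0, 0, 1] = 4
        assert match_labels_by_overlap(a, b) == {1: 4}

    def test_disjoint_masks_map_to_none(self):
        a = np.zeros((1, 2, 2), dtype=int)
        b = np.zeros((1, 2, 2), dtype=int)
        a[0, 0, 0] = 1
        b[0, 1, 1] = 2
        assert match_labels_by_overlap(a, b) == {1: None}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_labels_by_overlap(np.zeros((2, 2, 2), int), np.zeros((3, 2, 2), int))


class TestVolumeComparison:
    def test_identical_masks_conserve_volumes(self, rng):
        mask = rng.integers(0, 3, (5, 5, 5))
        table = compare_volumes(mask, mask, match_labels_by_overlap(mask, mask))
        assert (table["vol_a"] == table["vol_b"]).all()

    def test_known_counts_fixture(self):
        a = np.zeros((2, 3, 3), dtype=int)
        a[0] = 1
        a[1, 0, :] = 2
        b = np.zeros((2, 3, 3), dtype=int)
        b[0, :, :2] = 5
        table = compare_volumes(a, b, match_labels_by_overlap(a, b))
        row1 = table[table.label_a == 1].iloc[0]
        assert row1.vol_a == 9 and row1.label_b == 5 and row1.vol_b == 6
        row2 = table[table.label_a == 2].iloc[0]
        assert row2.vol_a == 3 and row2.vol_b == 0  # unmatched


def test_relabel_2d_by_3d_consistency():
    # two slices where per-slice labels disagree but the 3D mask links them
    m2d = np.zeros((2, 4, 4), dtype=int)
    m2d[0, :2, :2] = 1
    m2d[1, :2, :2] = 7  # same object, different per-slice id
    m3d = np.zeros((2, 4, 4), dtype=int)
    m3d[:, :2, :2] = 3
    out = relabel_2d_by_3d(m2d, m3d)
    assert np.all(out[m2d > 0] == 3)
    assert np.all(out[m2d == 0] == 0)


def test_full_pipeline_on_voxelized_ball():
    mask = _ball_mask(20, 64)
    result = roughness_of_label(mask, 1)
    assert result["Ro"] < 1e-3
    assert result["mean_radius"] == pytest.approx(20.0, abs=1.0)
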