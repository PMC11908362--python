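"""Generator/critic forward contracts, warping oracle, parameter fingerprint."""

import numpy as np
import pytest

from zslice.network import (
    NetConfig,
    count_parameters,
    critic_score,
    fuse,
    init_critic_params,
    init_student_params,
    init_teacher_params,
    student_forward,
    teacher_forward,
    zero_like_params,
)
from zslice.nn.ops import backward_warp, conv2d, conv_transpose2d
from zslice.triplets import make_dpm


class TestBackwardWarp:
    def test_zero_flow_is_identity_exact(self, rng):
        img = rng.random((2, 1, 8, 8))
        out = backward_warp(img, np.zeros((2, 2, 8, 8)))
        assert np.array_equal(out, img)

    def test_integer_flow_takes_right_neighbor(self):
        img = np.arange(4.0).reshape(1, 1, 2, 2)
        flow = np.zeros((1, 2, 2, 2))
        flow[0, 0] = 1.0  # dx = 1
        out = backward_warp(img, flow)
        # right column clamps to the border
        assert np.array_equal(out[0, 0], [[1.0, 1.0], [3.0, 3.0]])

    def test_fractional_flow_bilinear_average(self):
        img = np.array([[[[0.0, 10.0]]]])
        flow = np.zeros((1, 2, 1, 2))
        flow[0, 0] = 0.5
        out = backward_warp(img, flow)
        assert out[0, 0, 0, 0] == pytest.approx(5.0)
        assert out[0, 0, 0, 1] == pytest.approx(10.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            backward_warp(np.zeros((1, 1, 4, 4)), np.zeros((1, 2, 8, 8)))


class TestConvOps:
    def test_conv_transpose_matches_naive_scatter(self, rng):
        x = rng.random((2, 3, 5, 6))
        W = rng.random((3, 2, 4, 4))
        b = rng.random(2)
        out = conv_transpose2d(x, W, b, stride=2, pad=1)

        N, C, H, Wd = x.shape
        OH, OW = 2 * H, 2 * Wd
        ref = np.zeros((N, 2, OH + 2, OW + 2))
        for n in range(N):
            for ci in range(C):
                for i in range(H):
                    for j in range(Wd):
                        ref[n, :, 2 * i : 2 * i + 4, 2 * j : 2 * j + 4] += x[n, ci, i, j] * W[ci]
        ref = ref[:, :, 1 : 1 + OH, 1 : 1 + OW] + b.reshape(1, -1, 1, 1)
        assert np.allclose(out, ref)

    def test_conv2d_matches_direct_sum(self, rng):
        x = rng.random((1, 2, 5, 5))
        W = rng.random((3, 2, 3, 3))
        out = conv2d(x, W, np.zeros(3), stride=1, pad=1)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        ref = np.zeros((1, 3, 5, 5))
        for co in range(3):
            for i in range(5):
                for j in range(5):
                    ref[0, co, i, j] = np.sum(xp[0, :, i : i + 3, j : j + 3] * W[co])
        assert np.allclose(out, ref)


class TestFuse:
    def test_extremes_select_one_frame(self, rng):
        f0, f1 = rng.random((4, 4)), rng.random((4, 4))
        assert np.array_equal(fuse(np.ones((4, 4)), f0, f1), f0)
        assert np.array_equal(fuse(np.zeros((4, 4)), f0, f1), f1)

    def test_halfway_average(self):
        out = fuse(np.full((2, 2), 0.5), np.full((2, 2), 10.0), np.full((2, 2), 30.0))
        assert np.all(out == 20.0)

    def test_bounded_by_inputs(self, rng):
        f0, f1 = rng.random((6, 6)), rng.random((6, 6))
        out = fuse(rng.random((6, 6)), f0, f1)
        assert np.all(out >= np.minimum(f0, f1) - 1e-12)
        assert np.all(out <= np.maximum(f0, f1) + 1e-12)

    def test_mask_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.full((2, 2), 1.5), np.zeros((2, 2)), np.zeros((2, 2)))


class TestStudentForward:
    def test_zero_weights_give_plane_average(self, reduced_config, rng):
        params = zero_like_params(init_student_params(reduced_config))
        I0, I1 = rng.random((1, 64, 64)), rng.random((1, 64, 64))
        out = student_forward(params, I0, I1, config=reduced_config)
        assert np.allclose(out.student_frame[:, 0], 0.5 * (I0 + I1))
        for st in out.stages:
            assert np.all(st.F_to0 == 0) and np.all(st.F_to1 == 0)
            assert np.all(st.M == 0.5)

    def test_output_shape_and_stage_count(self, reduced_config, rng):
        params = init_student_params(reduced_config, 7)
        out = student_forward(params, rng.random((2, 64, 64)), rng.random((2, 64, 64)), config=reduced_config)
        assert out.student_frame.shape == (2, 1, 64, 64)
        assert len(out.stages) == 3
        assert out.teacher_frame is None

    def test_deterministic_given_weights(self, reduced_config, rng):
        params = init_student_params(reduced_config, 7)
        I0, I1 = rng.random((1, 64, 64)), rng.random((1, 64, 64))
        a = student_forward(params, I0, I1, config=reduced_config).student_frame
        b = student_forward(params, I0, I1, config=reduced_config).student_frame
        assert np.array_equal(a, b)

    def test_plus_variant_requires_dpm(self, rng):
        cfg = NetConfig.reduced_profile(plus_variant=True)
        params = init_student_params(cfg, 0)
        with pytest.raises(ValueError, match="DPM"):
            student_forward(params, rng.random((1, 64, 64)), rng.random((1, 64, 64)), config=cfg)

    def test_plus_variant_matches_fixed_io_contract(self, rng):
        cfg = NetConfig.reduced_profile(plus_variant=True)
        params = init_student_params(cfg, 0)
        I0, I1 = rng.random((1, 64, 64)), rng.random((1, 64, 64))
        out = student_forward(params, I0, I1, dpm=make_dpm(0.5, (64, 64)), config=cfg)
        assert out.student_frame.shape == (1, 1, 64, 64)


class TestTeacherForward:
    def test_zero_weight_teacher_keeps_plane_average(self, reduced_config, rng):
        sp = zero_like_params(init_student_params(reduced_config))
        tp = zero_like_params(init_teacher_params(reduced_config))
        I0, I1, Ig = (rng.random((1, 64, 64)) for _ in range(3))
        s_out = student_forward(sp, I0, I1, config=reduced_config)
        out = teacher_forward(tp, I0, I1, s_out, Ig, config=reduced_config)
        assert np.allclose(out.teacher_frame[:, 0], 0.5 * (I0 + I1))
        assert out.teacher_stage is not None
        assert out.teacher_frame.shape == (1, 1, 64, 64)

    def test_requires_student_stages(self, reduced_config, rng):
        tp = init_teacher_params(reduced_config)
        with pytest.raises(ValueError):
            teacher_forward(tp, rng.random((1, 64, 64)), rng.random((1, 64, 64)), None, rng.random((1, 64, 64)), config=reduced_config)


class TestCritic:
    def test_zero_weights_score_zero(self, reduced_config, rng):
        params = zero_like_params(init_critic_params(reduced_config))
        s = critic_score(params, rng.random((3, 64, 64)), reduced_config)
        assert s.shape == (3,) and np.all(s == 0)

    def test_finite_scores_on_random_input(self, reduced_config, rng):
        params = init_critic_params(reduced_config, 5)
        s = critic_score(params, rng.random((2, 64, 64)), reduced_config)
        assert np.all(np.isfinite(s))

    def test_wrong_input_size_rejected(self, reduced_config, rng):
        params = init_critic_params(reduced_config, 5)
        with pytest.raises(ValueError):
            critic_score(params, rng.random((1, 32, 32)), reduced_config)


class TestParameterFingerprint:
    def test_full_profile_student_count(self):
        assert round(count_parameters(NetConfig.full(), "student"), 1) == 10.6

    def test_full_profile_critic_count(self):
        assert round(count_parameters(NetConfig.full(), "critic"), 2) == 11.19

    def test_continuous_z_variant_rounds_to_same_student_count(self):
        assert round(count_parameters(NetConfig.full(plus_variant=True), "student"), 1) == 10.6

    def test_reduced_profile_strictly_smaller(self):
        for part in ("student", "critic", "teacher"):
            assert count_parameters(NetConfig.reduced_profile(), part) < count_parameters(NetConfig.full(), part)
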