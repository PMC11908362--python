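"""The interpolation generator (student + teacher) and the Wasserstein critic.

The generator estimates, coarse to fine, the two intermediate optical
flows F_{z->0} and F_{z->1} from the unknown in-between plane toward each
input plane, plus a fusion mask M. Three student stages operate at
downsample factors (4, 2, 1); each stage predicts a residual added to the
running flow estimate and a fresh mask logit. The interpolated frame is
the mask-weighted blend of the two backward-warped inputs:

    I_hat = M * warp(I0, F_{z->0}) + (1 - M) * warp(I1, F_{z->1})

At training time a privileged fourth stage (the teacher) additionally
sees the ground-truth plane and produces a refined flow/mask whose output
frame and flows supervise the student (knowledge distillation); only the
student runs at inference.

The critic is a plain strided-convolution stack with LeakyReLU (no
normalization layers, as is standard under a gradient penalty) ending in
a linear head that emits one unbounded score per image.

Each stage block is three convolutional layers (the first stride-2)
followed by one transposed convolutional layer emitting 5 channels:
4 flow components + 1 mask logit. With everything zeroed the flows and
logits vanish, the mask is sigmoid(0) = 1/2, and the generator output
degenerates to the plane average (I0 + I1) / 2 — a useful analytic trace.

The full profile's channel widths are pinned so the architecture
fingerprint (trainable parameter counts: 10.6 M student generator,
11.19 M critic) is reproducible; the reduced profile is a narrow
configuration of the same topology for CPU-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as onp

import autograd.numpy as np

from .nn.ops import (
    avg_pool,
    backward_warp,
    conv2d,
    conv_transpose2d,
    leaky_relu,
    sigmoid,
    upsample_nearest,
)
from autograd.tracer import getval

from .nn.optim import tree_size
from .triplets import DPMPlane


@dataclass
class FlowFieldSet:
    """Bidirectional intermediate flows and the fusion mask of one stage."""

    F_to0: np.ndarray  # (N, 2, H, W), pixels
    F_to1: np.ndarray
    M: np.ndarray  # (N, 1, H, W) in [0, 1]
    stage: int


@dataclass
class GeneratorOutput:
    student_frame: np.ndarray
    stages: List[FlowFieldSet]
    warped0: List[np.ndarray]
    warped1: List[np.ndarray]
    teacher_frame: Optional[np.ndarray] = None
    teacher_stage: Optional[FlowFieldSet] = None


@dataclass
class NetConfig:
    """Architecture profile for the generator stages and the critic.

    stage_widths pins one conv width per student stage (the teacher stage
    reuses the last width); critic_widths are the channel progression of
    the strided conv stack. The full profile reproduces the printed
    parameter fingerprint; the reduced profile is for CPU-scale tests.
    """

    stage_widths: Tuple[int, ...] = (440, 440, 440)
    stage_scales: Tuple[int, ...] = (4, 2, 1)
    critic_widths: Tuple[int, ...] = (64, 128, 260, 512, 512, 512)
    critic_input_size: int = 256
    plus_variant: bool = False
    reduced: bool = False

    @classmethod
    def full(cls, plus_variant: bool = False) -> "NetConfig":
        return cls(plus_variant=plus_variant)

    @classmethod
    def reduced_profile(cls, plus_variant: bool = False, input_size: int = 64) -> "NetConfig":
        return cls(
            stage_widths=(8, 8, 8),
            stage_scales=(4, 2, 1),
            critic_widths=(8, 16, 16, 32),
            critic_input_size=input_size,
            plus_variant=plus_variant,
            reduced=True,
        )

    @property
    def n_stages(self) -> int:
        return len(self.stage_widths)

    def stage_in_channels(self, i: int, teacher: bool = False) -> int:
        if teacher:
            return 6  # I0, I1, warp0, warp1, M, Izg
        if i == 0:
            return 3 if self.plus_variant else 2
        return 5  # I0, I1, warp0, warp1, M


# ---------------------------------------------------------------------------
# parameter initialization

def _he(rng: onp.random.Generator, shape, fan_in: int) -> onp.ndarray:
    return (rng.standard_normal(shape) * onp.sqrt(2.0 / fan_in)).astype(onp.float64)


def _block_params(rng, c_in: int, c: int) -> dict:
    return {
        "conv1_W": _he(rng, (c, c_in, 3, 3), 9 * c_in),
        "conv1_b": onp.zeros(c),
        "conv2_W": _he(rng, (c, c, 3, 3), 9 * c),
        "conv2_b": onp.zeros(c),
        "conv3_W": _he(rng, (c, c, 3, 3), 9 * c),
        "conv3_b": onp.zeros(c),
        "deconv_W": _he(rng, (c, 5, 4, 4), 16 * c),
        "deconv_b": onp.zeros(5),
    }


def init_student_params(config: NetConfig, seed: int = 0) -> dict:
    rng = onp.random.default_rng(seed)
    return {
        "stages": [
            _block_params(rng, config.stage_in_channels(i), c)
            for i, c in enumerate(config.stage_widths)
        ]
    }


def init_teacher_params(config: NetConfig, seed: int = 0) -> dict:
    rng = onp.random.default_rng(seed + 1)
    return {"t3": _block_params(rng, config.stage_in_channels(0, teacher=True), config.stage_widths[-1])}


def init_critic_params(config: NetConfig, seed: int = 0) -> dict:
    rng = onp.random.default_rng(seed + 2)
    params = {"convs": [], "head_W": None, "head_b": None}
    c_in = 1
    size = config.critic_input_size
    for c in config.critic_widths:
        params["convs"].append(
            {"W": _he(rng, (c, c_in, 4, 4), 16 * c_in), "b": onp.zeros(c)}
        )
        c_in = c
        size //= 2
    feat = c_in * size * size
    params["head_W"] = _he(rng, (feat, 1), feat)
    params["head_b"] = onp.zeros(1)
    return params


def zero_like_params(params):
    if isinstance(params, dict):
        return {k: zero_like_params(v) for k, v in params.items()}
    if isinstance(params, list):
        return [zero_like_params(v) for v in params]
    return onp.zeros_like(onp.asarray(params))


# ---------------------------------------------------------------------------
# forward passes

def fuse(M, frame0, frame1):
    """Elementwise convex blend M*frame0 + (1 - M)*frame1."""
    Mv = onp.asarray(getval(M))
    lo = onp.min(Mv) if Mv.size else 0.0
    hi = onp.max(Mv) if Mv.size else 0.0
    if lo < -1e-9 or hi > 1 + 1e-9:
        raise ValueError("fusion mask must lie in [0, 1]")
    return M * frame0 + (1.0 - M) * frame1


def _block_forward(bp: dict, x):
    h = leaky_relu(conv2d(x, bp["conv1_W"], bp["conv1_b"], stride=2, pad=1))
    h = leaky_relu(conv2d(h, bp["conv2_W"], bp["conv2_b"], stride=1, pad=1))
    h = leaky_relu(conv2d(h, bp["conv3_W"], bp["conv3_b"], stride=1, pad=1))
    return conv_transpose2d(h, bp["deconv_W"], bp["deconv_b"], stride=2, pad=1)


def _as_batch(plane):
    a = np.asarray(plane) if not hasattr(plane, "_value") else plane
    if a.ndim == 2:
        return np.reshape(a, (1, 1) + a.shape)
    if a.ndim == 3:
        return np.reshape(a, (a.shape[0], 1) + a.shape[1:])
    return a


def student_forward(params: dict, I0, I1, dpm: Optional[DPMPlane] = None, config: NetConfig = None) -> GeneratorOutput:
    """Run the three student stages; returns frame, per-stage flows and warps.

    Inputs are planes (H, W), batches (N, H, W) or tensors (N, 1, H, W) in
    the network range [0, 1]. In the continuous-z variant a DPM plane must
    be supplied and enters the first stage as an extra channel.
    """
    config = config or NetConfig.full()
    if config.plus_variant and dpm is None:
        raise ValueError("continuous-z variant requires a DPM input")
    I0 = _as_batch(I0)
    I1 = _as_batch(I1)
    if I0.shape != I1.shape:
        raise ValueError("input planes must share one shape")
    N, _, H, W = I0.shape
    flow = np.zeros((N, 4, H, W))
    mask = 0.5 * np.ones((N, 1, H, W))
    w0, w1 = I0, I1
    stages: List[FlowFieldSet] = []
    warped0: List[np.ndarray] = []
    warped1: List[np.ndarray] = []
    for i, (bp, scale) in enumerate(zip(params["stages"], config.stage_scales)):
        if i == 0:
            feats = [I0, I1]
            if config.plus_variant:
                dv = dpm.values if isinstance(dpm, DPMPlane) else np.asarray(dpm, dtype=float)
                if dv.ndim == 2:
                    d = np.reshape(dv, (1, 1, H, W)) * np.ones((N, 1, H, W))
                else:
                    d = np.reshape(dv, (N, 1, H, W))
                feats.append(d)
        else:
            feats = [I0, I1, w0, w1, mask]
        x = np.concatenate(feats, axis=1)
        out = _block_forward(bp, avg_pool(x, scale))
        res = upsample_nearest(out[:, :4], scale) * float(scale)
        logit = upsample_nearest(out[:, 4:5], scale)
        flow = flow + res
        mask = sigmoid(logit)
        w0 = backward_warp(I0, flow[:, 0:2])
        w1 = backward_warp(I1, flow[:, 2:4])
        stages.append(FlowFieldSet(flow[:, 0:2], flow[:, 2:4], mask, stage=i + 1))
        warped0.append(w0)
        warped1.append(w1)
    frame = fuse(mask, w0, w1)
    return GeneratorOutput(student_frame=frame, stages=stages, warped0=warped0, warped1=warped1)


def teacher_forward(params: dict, I0, I1, student_output: GeneratorOutput, Izg, config: NetConfig = None) -> GeneratorOutput:
    """Run the privileged teacher stage on top of the student's stage-3 state.

    The teacher block sees the ground truth plane; its flows start from the
    student's final flows (residual refinement). Student activations are
    reused, not recomputed, and the teacher shares no weights with S0-S2.
    """
    config = config or NetConfig.full()
    if student_output is None or not student_output.stages:
        raise ValueError("student stages required before the teacher stage")
    I0 = _as_batch(I0)
    I1 = _as_batch(I1)
    Izg = _as_batch(Izg)
    if Izg.shape != I0.shape:
        raise ValueError("ground-truth plane must match the input shape")
    last = student_output.stages[-1]
    x = np.concatenate([I0, I1, student_output.warped0[-1], student_output.warped1[-1], last.M, Izg], axis=1)
    out = _block_forward(params["t3"], avg_pool(x, config.stage_scales[-1]))
    scale = config.stage_scales[-1]
    res = upsample_nearest(out[:, :4], scale) * float(scale)
    logit = upsample_nearest(out[:, 4:5], scale)
    flow0 = last.F_to0 + res[:, 0:2]
    flow1 = last.F_to1 + res[:, 2:4]
    mask = sigmoid(logit)
    w0 = backward_warp(I0, flow0)
    w1 = backward_warp(I1, flow1)
    frame = fuse(mask, w0, w1)
    tstage = FlowFieldSet(flow0, flow1, mask, stage=config.n_stages + 1)
    return GeneratorOutput(
        student_frame=student_output.student_frame,
        stages=student_output.stages,
        warped0=student_output.warped0 + [w0],
        warped1=student_output.warped1 + [w1],
        teacher_frame=frame,
        teacher_stage=tstage,
    )


def critic_score(params: dict, image, config: NetConfig = None):
    """Unbounded Wasserstein critic score, one scalar per image."""
    config = config or NetConfig.full()
    x = _as_batch(image)
    size = config.critic_input_size
    if x.shape[2] != size or x.shape[3] != size:
        raise ValueError(
            f"critic configured for {size}x{size} input, got {x.shape[2]}x{x.shape[3]}"
        )
    for layer in params["convs"]:
        x = leaky_relu(conv2d(x, layer["W"], layer["b"], stride=2, pad=1), 0.2)
    N = x.shape[0]
    x = np.reshape(x, (N, -1))
    return np.reshape(np.matmul(x, params["head_W"]) + params["head_b"], (N,))


def count_parameters(config: NetConfig, part: str) -> float:
    """Trainable parameter count, in millions, of one network part.

    part: 'student' (the three generator stages), 'teacher' (the
    privileged stage alone), or 'critic'.
    """
    if part == "student":
        n = tree_size(init_student_params(config))
    elif part == "teacher":
        n = tree_size(init_teacher_params(config))
    elif part == "critic":
        n = tree_size(init_critic_params(config))
    else:
        raise ValueError(f"unknown part {part!r}")
    return n / 1e6


def count_parameters_exact(config: NetConfig, part: str) -> int:
    """Exact integer parameter count (same parts as count_parameters)."""
    return round(count_parameters(config, part) * 1e6)
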