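"""Training objectives: reconstruction, distillation, adversarial, penalty.

Generator total:

    L_G = Lrec(I_hat_S, Izg) + Lrec(I_hat_T, Izg) + lambda_d * L_dis
          - lambda_adv * E[D(I_hat_S)]

with Lrec a Laplacian-pyramid L1 loss (4 levels, 5-tap binomial kernel,
equal level weights), L_dis the per-pixel mean squared deviation of each
student stage's flows from the (stop-gradient) teacher flows, and D the
Wasserstein critic. Setting lambda_adv = 0 gives the generator-only
("direct") training mode.

Critic total (WGAN-GP):

    L_D = E[D(fake)] - E[D(real)]
          + lambda_GP * E[(||grad_x D(x_tilde)||_2 - 1)^2]

with x_tilde = alpha*real + (1-alpha)*fake, one alpha ~ U[0,1] per
sample, and the gradient norm taken over all pixels of one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as onp

import autograd.numpy as np
from autograd import grad
from autograd.tracer import getval

from .network import FlowFieldSet, GeneratorOutput


@dataclass
class LossWeights:
    """Scale factors balancing the generator/critic loss components."""

    lambda_d: float = 0.01
    lambda_adv: float = 0.001
    lambda_gp: float = 10.0

    def __post_init__(self) -> None:
        if self.lambda_d < 0 or self.lambda_adv < 0 or self.lambda_gp < 0:
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def direct(cls) -> "LossWeights":
        """Generator-only configuration (no adversarial term)."""
        return cls(lambda_adv=0.0)


@dataclass
class LossReport:
    """Scalar values of every loss component of one iteration."""

    total_G: float = onp.nan
    rec: float = onp.nan
    rec_teacher: float = onp.nan
    dis: float = onp.nan
    adv: float = onp.nan
    total_D: float = onp.nan
    gp: float = onp.nan


_BINOMIAL5 = onp.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
_BLUR_K = onp.outer(_BINOMIAL5, _BINOMIAL5)  # 5x5 separable binomial


def _blur(x):
    # fixed-kernel conv, applied per channel; reflect-free zero padding is
    # acceptable for loss purposes (bands stay zero for equal inputs)
    from .nn.ops import conv2d

    N, C, H, W = x.shape
    k = _BLUR_K[None, None]
    out = [conv2d(x[:, c : c + 1], k, onp.zeros(1), stride=1, pad=2) for c in range(C)]
    return np.concatenate(out, axis=1) if C > 1 else out[0]


def _pyramid(x, levels: int):
    """Laplacian pyramid: band-pass levels plus the final low-pass residual."""
    from .nn.ops import upsample_nearest

    bands = []
    g = x
    for _ in range(levels - 1):
        low = _blur(g)
        down = low[:, :, ::2, ::2]
        up = _blur(upsample_nearest(down, 2))
        bands.append(g - up)
        g = down
    bands.append(g)
    return bands


def _as_nchw(a):
    if hasattr(a, "ndim") and a.ndim == 2:
        return np.reshape(a, (1, 1) + a.shape)
    if hasattr(a, "ndim") and a.ndim == 3:
        return np.reshape(a, (a.shape[0], 1) + a.shape[1:])
    return a


def laplacian_pyramid_loss(a, b, levels: int = 4):
    """Sum over pyramid levels of the mean absolute band difference.

    With levels=1 the sole band is the image itself, so the loss reduces
    to the plain mean absolute difference. Zero iff the inputs are equal.
    """
    a = _as_nchw(a) * 1.0  # promote integer planes to float
    b = _as_nchw(b) * 1.0
    if getval(a).shape != getval(b).shape:
        raise ValueError("planes must share one shape")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    pa = _pyramid(a, levels)
    pb = _pyramid(b, levels)
    total = 0.0
    for ba, bb in zip(pa, pb):
        total = total + np.mean(np.abs(ba - bb))
    return total


def distillation_loss(student_stages: List[FlowFieldSet], teacher_stage: FlowFieldSet):
    """Flow-supervision loss transferring teacher knowledge to the student.

    Sum over student stages of the per-pixel mean squared L2 deviation of
    both flows from the teacher's; the teacher flow is a stop-gradient
    target.
    """
    if teacher_stage is None or not student_stages:
        raise ValueError("both student stages and a teacher stage are required")
    t0 = getval(teacher_stage.F_to0)
    t1 = getval(teacher_stage.F_to1)
    total = 0.0
    for s in student_stages:
        d0 = s.F_to0 - t0
        d1 = s.F_to1 - t1
        # mean over pixels/batch of the squared 2-vector norm
        total = total + np.mean(np.sum(d0 * d0, axis=1)) + np.mean(np.sum(d1 * d1, axis=1))
    return total


def generator_loss(
    output: GeneratorOutput,
    Izg,
    weights: LossWeights,
    critic_fn: Optional[Callable] = None,
    levels: int = 4,
):
    """Total generator loss and its component report.

    critic_fn maps a batch of frames to per-sample scores; it is only
    consulted when lambda_adv > 0 (direct mode never touches the critic).
    Returns (total, LossReport) where total stays inside autograd's trace.
    """
    Izg = _as_nchw(Izg)
    rec = laplacian_pyramid_loss(output.student_frame, Izg, levels)
    rec_t = laplacian_pyramid_loss(output.teacher_frame, Izg, levels) if output.teacher_frame is not None else 0.0
    dis = (
        distillation_loss(output.stages, output.teacher_stage)
        if output.teacher_stage is not None
        else 0.0
    )
    adv = 0.0
    if weights.lambda_adv > 0:
        if critic_fn is None:
            raise ValueError("critic_fn required when lambda_adv > 0")
        adv = np.mean(critic_fn(output.student_frame))
    total = rec + rec_t + weights.lambda_d * dis - weights.lambda_adv * adv
    report = LossReport(
        total_G=float(getval(total)),
        rec=float(getval(rec)),
        rec_teacher=float(getval(rec_t)),
        dis=float(getval(dis)),
        adv=float(getval(adv)),
    )
    return total, report


def gradient_penalty(critic_fn: Callable, real, fake, alpha, lambda_gp: float = 10.0):
    """WGAN gradient penalty at interpolates between real and fake samples.

    alpha is one uniform draw per sample (scalar or shape (N,)); the
    penalty is lambda_gp * mean_i (||grad_x D(x_i)||_2 - 1)^2 with the
    gradient norm over all pixels of sample i.
    """
    real = _as_nchw(real)
    fake = _as_nchw(fake)
    N = getval(real).shape[0]
    a = np.reshape(np.asarray(alpha, dtype=float) * np.ones(N), (N, 1, 1, 1))
    x = a * real + (1.0 - a) * fake

    def total_score(xi):
        return np.sum(critic_fn(xi))

    g = grad(total_score)(x)  # (N, 1, H, W); rows independent, so sum is safe
    norms = np.sqrt(np.sum(np.reshape(g * g, (N, -1)), axis=1) + 1e-24)
    return lambda_gp * np.mean((norms - 1.0) ** 2)


def critic_loss(
    critic_fn: Callable,
    real,
    fake,
    lambda_gp: float = 10.0,
    rng: Optional[onp.random.Generator] = None,
    alpha=None,
):
    """WGAN-GP critic loss: E[D(fake)] - E[D(real)] + gradient penalty.

    One alpha per sample is drawn from rng unless given explicitly.
    Returns (total, LossReport).
    """
    real = _as_nchw(real)
    fake = _as_nchw(fake)
    N = getval(real).shape[0]
    if N == 0:
        raise ValueError("empty batch")
    if alpha is None:
        rng = rng or onp.random.default_rng(0)
        alpha = rng.uniform(size=N)
    fake_s = np.mean(critic_fn(fake))
    real_s = np.mean(critic_fn(real))
    gp = gradient_penalty(critic_fn, real, getval(fake), alpha, lambda_gp)
    total = fake_s - real_s + gp
    report = LossReport(total_D=float(getval(total)), gp=float(getval(gp)))
    return total, report
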