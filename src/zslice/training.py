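"""Alternating generator/critic optimization.

Each iteration draws a batch of triplets; when adversarial training is on
(lambda_adv > 0) the critic is first updated `critic_steps` times on
(ground-truth vs generated) planes with the gradient penalty, then the
generator (student stages + teacher stage jointly) takes one Adam step on
its total loss. With lambda_adv = 0 ("direct" mode) the critic is never
built nor evaluated.

Everything random — initialization, batch order, gradient-penalty alpha
draws — flows from one seeded generator whose state is serialized into
checkpoints, so a run split across resume() reproduces the uninterrupted
run bit-for-bit on the same device.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as onp

from autograd import grad
from autograd.tracer import getval

from .losses import LossReport, LossWeights, critic_loss, generator_loss
from .network import (
    NetConfig,
    critic_score,
    init_critic_params,
    init_student_params,
    init_teacher_params,
    student_forward,
    teacher_forward,
)
from .nn.optim import AdamState, adam_step, tree_flatten, tree_size, tree_unflatten
from .triplets import SliceTriplet

HISTORY_FIELDS = ["iteration", "total_G", "rec", "rec_teacher", "dis", "adv", "total_D", "gp"]


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published training protocol."""

    epochs: int = 100
    batch_size: int = 128
    lr: float = 1e-4
    betas: tuple = (0.5, 0.999)
    weights: LossWeights = field(default_factory=LossWeights)
    critic_steps: int = 1
    seed: int = 0
    reduced: bool = False
    plus_variant: bool = False
    pyramid_levels: int = 4
    max_iterations: Optional[int] = None
    checkpoint_dir: Optional[str] = None
    log_csv: Optional[str] = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("invalid training configuration")

    def net_config(self, input_size: int) -> NetConfig:
        if self.reduced:
            return NetConfig.reduced_profile(self.plus_variant, input_size)
        cfg = NetConfig.full(self.plus_variant)
        return NetConfig(
            stage_widths=cfg.stage_widths,
            stage_scales=cfg.stage_scales,
            critic_widths=cfg.critic_widths,
            critic_input_size=input_size,
            plus_variant=self.plus_variant,
        )


@dataclass
class TrainState:
    """Everything needed to continue training exactly where it stopped."""

    config: TrainConfig
    net_config: NetConfig
    student: dict
    teacher: dict
    critic: Optional[dict]
    opt_G: AdamState
    opt_D: Optional[AdamState]
    rng_state: dict
    epoch: int = 0
    iteration: int = 0
    history: List[dict] = field(default_factory=list)
    critic_evaluations: int = 0
    # remaining batch index lists of the current epoch, so a mid-epoch
    # checkpoint resumes the very same batch sequence
    pending: List[List[int]] = field(default_factory=list)


def _to_float(plane: onp.ndarray) -> onp.ndarray:
    return onp.asarray(plane, dtype=onp.float64) / 255.0


def init_state(triplets: Sequence[SliceTriplet], config: TrainConfig) -> TrainState:
    if not triplets:
        raise ValueError("at least one training triplet is required")
    h, w = triplets[0].I0.shape
    if h != w:
        raise ValueError("training planes must be square")
    net = config.net_config(h)
    rng = onp.random.default_rng(config.seed)
    init_seed = int(rng.integers(2**31 - 1))
    student = init_student_params(net, init_seed)
    teacher = init_teacher_params(net, init_seed)
    adversarial = config.weights.lambda_adv > 0
    critic = init_critic_params(net, init_seed) if adversarial else None
    nG = tree_size(student) + tree_size(teacher)
    return TrainState(
        config=config,
        net_config=net,
        student=student,
        teacher=teacher,
        critic=critic,
        opt_G=AdamState.zeros(nG),
        opt_D=AdamState.zeros(tree_size(critic)) if adversarial else None,
        rng_state=rng.bit_generator.state,
    )


def _batches(n: int, batch_size: int, rng: onp.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_step(state: TrainState, batch: Sequence[SliceTriplet], rng: onp.random.Generator) -> LossReport:
    """One optimization iteration on one batch; mutates `state` in place."""
    cfg = state.config
    net = state.net_config
    I0 = onp.stack([_to_float(t.I0) for t in batch])
    I1 = onp.stack([_to_float(t.I1) for t in batch])
    Ig = onp.stack([_to_float(t.Izg) for t in batch])
    dpm = None
    if cfg.plus_variant:
        zs = onp.array([t.z for t in batch])
        dpm = zs[:, None, None] * onp.ones((1,) + batch[0].I0.shape)
    adversarial = cfg.weights.lambda_adv > 0
    report = LossReport()

    if adversarial:
        fake = getval(
            student_forward(state.student, I0, I1, dpm=dpm, config=net).student_frame
        )
        for _ in range(cfg.critic_steps):
            alpha = rng.uniform(size=len(batch))

            def closs(cparams):
                def fn(x):
                    state.critic_evaluations += 1
                    return critic_score(cparams, x, net)

                total, rep = critic_loss(fn, Ig, fake, cfg.weights.lambda_gp, alpha=alpha)
                closs.report = rep
                return total

            gvec = tree_flatten(grad(closs)(state.critic))
            pvec, state.opt_D = adam_step(tree_flatten(state.critic), gvec, state.opt_D, cfg.lr, cfg.betas)
            state.critic = tree_unflatten(state.critic, pvec)
            report.total_D = closs.report.total_D
            report.gp = closs.report.gp

    def gloss(gparams):
        out = student_forward(gparams["s"], I0, I1, dpm=dpm, config=net)
        out = teacher_forward(gparams["t"], I0, I1, out, Ig, config=net)
        critic_fn = None
        if adversarial:
            def critic_fn(x):
                state.critic_evaluations += 1
                return critic_score(state.critic, x, net)

        total, rep = generator_loss(out, Ig, cfg.weights, critic_fn, cfg.pyramid_levels)
        gloss.report = rep
        return total

    gparams = {"s": state.student, "t": state.teacher}
    gvec = tree_flatten(grad(gloss)(gparams))
    pvec, state.opt_G = adam_step(tree_flatten(gparams), gvec, state.opt_G, cfg.lr, cfg.betas)
    new = tree_unflatten(gparams, pvec)
    state.student, state.teacher = new["s"], new["t"]

    rep = gloss.report
    report.total_G, report.rec = rep.total_G, rep.rec
    report.rec_teacher, report.dis, report.adv = rep.rec_teacher, rep.dis, rep.adv
    if not onp.isfinite(report.total_G):
        raise RuntimeError(f"non-finite generator loss at iteration {state.iteration}: {report}")
    state.iteration += 1
    return report


def _log_row(state: TrainState, report: LossReport) -> None:
    row = {"iteration": state.iteration}
    for f in HISTORY_FIELDS[1:]:
        v = getattr(report, f)
        # absent components (e.g. critic terms in direct mode) log as None,
        # which serializes cleanly and compares equal across round-trips
        row[f] = None if v is None or onp.isnan(v) else float(v)
    state.history.append(row)


def _write_log(state: TrainState) -> None:
    if state.config.log_csv is None:
        return
    with open(state.config.log_csv, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=HISTORY_FIELDS)
        w.writeheader()
        w.writerows(state.history)


def train(triplets: Sequence[SliceTriplet], config: TrainConfig, state: Optional[TrainState] = None) -> TrainState:
    """Train on a triplet dataset; returns the final state (weights + history).

    Training runs for config.epochs epochs or until config.max_iterations
    generator updates, whichever comes first. A checkpoint is written per
    epoch when config.checkpoint_dir is set.
    """
    if state is None:
        state = init_state(triplets, config)
    rng = onp.random.default_rng(config.seed)
    rng.bit_generator.state = state.rng_state
    while True:
        if config.max_iterations is not None and state.iteration >= config.max_iterations:
            break
        if not state.pending:
            if state.epoch >= config.epochs:
                break
            state.pending = [list(map(int, b)) for b in _batches(len(triplets), config.batch_size, rng)]
        idx = state.pending.pop(0)
        batch = [triplets[i] for i in idx]
        report = train_step(state, batch, rng)
        _log_row(state, report)
        if not state.pending:
            state.epoch += 1
            state.rng_state = rng.bit_generator.state
            if config.checkpoint_dir is not None:
                save_checkpoint(state, Path(config.checkpoint_dir) / f"epoch_{state.epoch:04d}.npz")
    state.rng_state = rng.bit_generator.state
    _write_log(state)
    return state


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(state: TrainState, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(state.config)
    cfg["weights"] = asdict(state.config.weights)
    meta = {
        "config": cfg,
        "net_config": asdict(state.net_config),
        "rng_state": state.rng_state,
        "epoch": state.epoch,
        "iteration": state.iteration,
        "history": state.history,
        "critic_evaluations": state.critic_evaluations,
        "has_critic": state.critic is not None,
        "pending": state.pending,
    }
    arrays = {
        "student": tree_flatten(state.student),
        "teacher": tree_flatten(state.teacher),
        "optG_m": state.opt_G.m,
        "optG_v": state.opt_G.v,
        "optG_t": onp.array(state.opt_G.t),
    }
    if state.critic is not None:
        arrays["critic"] = tree_flatten(state.critic)
        arrays["optD_m"] = state.opt_D.m
        arrays["optD_v"] = state.opt_D.v
        arrays["optD_t"] = onp.array(state.opt_D.t)
    onp.savez(path, meta=onp.frombuffer(json.dumps(meta, default=int).encode(), dtype=onp.uint8), **arrays)


def load_checkpoint(path) -> TrainState:
    data = onp.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    cfgd = dict(meta["config"])
    cfgd["weights"] = LossWeights(**cfgd["weights"])
    cfgd["betas"] = tuple(cfgd["betas"])
    config = TrainConfig(**cfgd)
    ncd = dict(meta["net_config"])
    for k in ("stage_widths", "stage_scales", "critic_widths"):
        ncd[k] = tuple(ncd[k])
    net = NetConfig(**ncd)
    student = tree_unflatten(init_student_params(net, 0), data["student"])
    teacher = tree_unflatten(init_teacher_params(net, 0), data["teacher"])
    critic = None
    opt_D = None
    if meta["has_critic"]:
        critic = tree_unflatten(init_critic_params(net, 0), data["critic"])
        opt_D = AdamState(data["optD_m"], data["optD_v"], int(data["optD_t"]))
    rng_state = meta["rng_state"]
    # JSON round-trip turns the uint64 state integers into Python ints; numpy accepts them
    return TrainState(
        config=config,
        net_config=net,
        student=student,
        teacher=teacher,
        critic=critic,
        opt_G=AdamState(data["optG_m"], data["optG_v"], int(data["optG_t"])),
        opt_D=opt_D,
        rng_state=rng_state,
        epoch=meta["epoch"],
        iteration=meta["iteration"],
        history=meta["history"],
        critic_evaluations=meta["critic_evaluations"],
        pending=meta.get("pending", []),
    )


def resume(checkpoint_path, triplets: Sequence[SliceTriplet], config: Optional[TrainConfig] = None) -> TrainState:
    """Continue a checkpointed run (optionally with a new epoch/iteration cap).

    The architecture is taken from the checkpoint; a config whose profile
    disagrees with the stored one is rejected.
    """
    state = load_checkpoint(checkpoint_path)
    if config is not None:
        stored = state.config.net_config(state.net_config.critic_input_size)
        wanted = config.net_config(state.net_config.critic_input_size)
        if (stored.stage_widths, stored.critic_widths) != (wanted.stage_widths, wanted.critic_widths):
            raise ValueError("checkpoint architecture does not match the requested configuration")
        state.config = config
    return train(triplets, state.config, state=state)
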