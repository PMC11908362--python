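"""Parameter pytrees and the Adam optimizer.

Parameters live in nested dict/list structures of numpy arrays. Training
flattens them to one vector, applies Adam, and unflattens; the flatten
order is the deterministic depth-first traversal with sorted dict keys,
so checkpoints are portable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, List, Tuple

import numpy as np


def tree_leaves(tree) -> List[np.ndarray]:
    if isinstance(tree, dict):
        out = []
        for k in sorted(tree):
            out.extend(tree_leaves(tree[k]))
        return out
    if isinstance(tree, (list, tuple)):
        out = []
        for v in tree:
            out.extend(tree_leaves(v))
        return out
    return [tree]


def tree_flatten(tree) -> np.ndarray:
    leaves = tree_leaves(tree)
    return np.concatenate([np.ravel(np.asarray(leaf)) for leaf in leaves])


def tree_unflatten(tree, vec: np.ndarray):
    """Rebuild a pytree with `tree`'s structure/shapes from a flat vector."""

    pos = 0

    def rebuild(node):
        nonlocal pos
        if isinstance(node, dict):
            return {k: rebuild(node[k]) for k in sorted(node)}
        if isinstance(node, (list, tuple)):
            seq = [rebuild(v) for v in node]
            return type(node)(seq) if isinstance(node, tuple) else seq
        arr = np.asarray(node)
        flat = vec[pos : pos + arr.size]
        pos += arr.size
        return np.reshape(flat, arr.shape).astype(arr.dtype, copy=False)

    out = rebuild(tree)
    if pos != vec.size:
        raise ValueError("flat vector size does not match tree")
    return out


def tree_size(tree) -> int:
    return int(sum(np.asarray(leaf).size for leaf in tree_leaves(tree)))


@dataclass
class AdamState:
    """First/second moment estimates and the step counter."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n: int) -> "AdamState":
        return cls(np.zeros(n), np.zeros(n), 0)


def adam_step(
    params_vec: np.ndarray,
    grad_vec: np.ndarray,
    state: AdamState,
    lr: float = 1e-4,
    betas: Tuple[float, float] = (0.5, 0.999),
    eps: float = 1e-8,
) -> Tuple[np.ndarray, AdamState]:
    b1, b2 = betas
    t = state.t + 1
    m = b1 * state.m + (1 - b1) * grad_vec
    v = b2 * state.v + (1 - b2) * grad_vec**2
    mhat = m / (1 - b1**t)
    vhat = v / (1 - b2**t)
    new = params_vec - lr * mhat / (np.sqrt(vhat) + eps)
    return new, AdamState(m, v, t)
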