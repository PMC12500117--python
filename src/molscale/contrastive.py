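"""Hierarchical InfoNCE objective with a momentum key encoder and FIFO queues.

Each scale k contrasts a graph's scale embedding z_k against the key
encoder's embedding of a scale-k augmented view (positive) and a per-scale
FIFO queue of past key embeddings (negatives):

    L_k = −log  exp(z·z⁺/τ) / (exp(z·z⁺/τ) + Σ_n exp(z·z⁻_n/τ)),

combined as  L = Σ_k λ_k L_k  with learnable simplex weights λ (softmax
parametrization).  By the InfoNCE bound, −L_k + log N lower-bounds the
mutual information I(z_k; z_k⁺), which is what the bookkeeping helper
:func:`mi_lower_bound` reports.

The denominator includes the positive term (the standard form, and the one
under which the log N bound holds); ``include_positive=False`` gives the
negatives-only variant.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, tensor, concat, stack

__all__ = [
    "ContrastiveConfig", "NegativeQueue", "info_nce", "hierarchical_loss",
    "momentum_update", "queue_update", "mi_lower_bound", "update_lambdas",
    "lambdas_from_logits",
]


@dataclass
class ContrastiveConfig:
    temperature: float = 0.07
    queue_size: int = 65536
    momentum: float = 0.999
    lambda_init: tuple = (1 / 3, 1 / 3, 1 / 3)
    include_positive_in_denominator: bool = True

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.queue_size < 1:
            raise ValueError("queue_size must be ≥ 1")
        if not (0.0 <= self.momentum <= 1.0):
            raise ValueError("momentum must be in [0, 1]")


class NegativeQueue:
    """FIFO buffer of L2-normalized key embeddings for one scale."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be ≥ 1")
        self.capacity = capacity
        self._buf = deque(maxlen=capacity)

    def __len__(self):
        return len(self._buf)

    def as_array(self) -> np.ndarray:
        return np.array(self._buf) if self._buf else np.empty((0, 0))

    def push(self, keys: np.ndarray):
        keys = np.atleast_2d(np.asarray(keys, float))
        norms = np.linalg.norm(keys, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-4):
            raise ValueError("queue keys must be L2-normalized")
        for k in keys:
            self._buf.append(k.copy())


def queue_update(queue: NegativeQueue, new_keys) -> NegativeQueue:
    """Push keys with FIFO eviction; returns the (mutated) queue."""
    queue.push(new_keys)
    return queue


def info_nce(z, z_pos, negatives, tau: float = 0.07,
             include_positive: bool = True):
    """InfoNCE loss for one anchor.

    ``z`` and ``z_pos`` are d-vectors, ``negatives`` an (N, d) matrix;
    similarities are dot products (callers supply L2-normalized embeddings).
    Returns a scalar Tensor (differentiable when inputs are Tensors).
    """
    z = tensor(z)
    z_pos = tensor(z_pos)
    negatives = tensor(negatives)
    if z.shape != z_pos.shape or (negatives.data.size and
                                  negatives.shape[-1] != z.shape[-1]):
        raise ValueError("embedding dimension mismatch")
    s_pos = (z * z_pos).sum() * (1.0 / tau)
    if negatives.data.size:
        s_neg = (negatives @ z) * (1.0 / tau)
        if include_positive:
            logits = concat([s_pos.reshape((1,)), s_neg], axis=0)
        else:
            logits = s_neg
    else:
        logits = s_pos.reshape((1,))
    return logits.logsumexp(axis=0) - s_pos


def hierarchical_loss(per_scale_losses, lambdas):
    """Σ_k λ_k L_k with λ on the probability simplex."""
    lambdas_arr = lambdas.data if isinstance(lambdas, Tensor) else np.asarray(lambdas, float)
    if len(per_scale_losses) != 3 or len(lambdas_arr) != 3:
        raise ValueError("three scales expected")
    if abs(float(lambdas_arr.sum()) - 1.0) > 1e-6 or np.any(lambdas_arr < -1e-12):
        raise ValueError("lambda weights must lie on the simplex")
    lam = tensor(lambdas)
    losses = stack([tensor(l).reshape(()) for l in per_scale_losses])
    return (lam * losses).sum()


def momentum_update(online_params: dict, key_params: dict, m: float) -> dict:
    """key ← m·key + (1−m)·online, elementwise over congruent parameter dicts."""
    if set(online_params) != set(key_params):
        raise ValueError("parameter sets differ")
    for name, onl in online_params.items():
        kp = key_params[name]
        if kp.data.shape != onl.data.shape:
            raise ValueError(f"shape mismatch for {name}")
        kp.data *= m
        kp.data += (1.0 - m) * onl.data
    return key_params


def mi_lower_bound(loss_k: float, n_negatives: int) -> float:
    """InfoNCE bound on I(z; z⁺):  −L + ln N  (nats)."""
    if n_negatives < 1:
        raise ValueError("N must be ≥ 1")
    return -float(loss_k) + math.log(n_negatives)


def lambdas_from_logits(logits) -> np.ndarray:
    logits = logits.data if isinstance(logits, Tensor) else np.asarray(logits, float)
    e = np.exp(logits - logits.max())
    return e / e.sum()


def update_lambdas(lambda_logits: Tensor, lr: float = 0.0) -> np.ndarray:
    """Current simplex weights after any optimizer step on the logits.

    The weights are the softmax of free logits, so they stay on the simplex
    no matter what gradient step the optimizer took.  With ``lr > 0`` and a
    populated ``.grad``, applies one SGD step first.
    """
    if lr and lambda_logits.grad is not None:
        lambda_logits.data -= lr * lambda_logits.grad
    return lambdas_from_logits(lambda_logits)
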