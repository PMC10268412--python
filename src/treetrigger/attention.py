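"""Softmax/LeakyReLU neighborhood attention shared by both encoders.

A member k of a node's child set (dependency side) or neighborhood
(graph side) is scored as

    e_k = LeakyReLU( a . [ W q  ||  W h_k ] )

and the weights are softmax(e) over the member set.  The query q is the
node's projected input embedding on the dependency side and its
previous-layer hidden state on the graph side; both are supplied by the
caller already in hidden space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AttentionParams",
    "AttentionMap",
    "attention_coefficients",
    "attentive_aggregate",
]


@dataclass
class AttentionParams:
    """Projection W (d_h x d_h), score vector a (2*d_h), LeakyReLU slope."""

    W: Tensor
    a: Tensor
    negative_slope: float = 0.2

    def __post_init__(self):
        self.W = ad.as_tensor(self.W)
        self.a = ad.as_tensor(self.a)
        d_h = self.W.shape[0]
        if self.W.shape != (d_h, d_h):
            raise ValueError(f"W must be square, got {self.W.shape}")
        if self.a.shape != (2 * d_h,):
            raise ValueError(
                f"score vector must have length {2 * d_h}, got {self.a.shape}"
            )

    @classmethod
    def init(cls, d_h: int, rng: np.random.Generator, scale: float = 0.1,
             negative_slope: float = 0.2) -> "AttentionParams":
        return cls(
            W=Tensor(rng.normal(0, scale, (d_h, d_h)), requires_grad=True),
            a=Tensor(rng.normal(0, scale, 2 * d_h), requires_grad=True),
            negative_slope=negative_slope,
        )

    def tensors(self) -> list[Tensor]:
        return [self.W, self.a]


@dataclass
class AttentionMap:
    """Weights over a node's members; rows are valid distributions."""

    node: int
    members: list[int]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not self.members:
            raise ValueError("attention map needs at least one member")
        if len(self.members) != len(self.weights):
            raise ValueError("member/weight length mismatch")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be a probability vector")


def attention_coefficients(
    query, members: Sequence, params: AttentionParams
) -> Tensor:
    """Softmax attention weights of ``query`` over ``members``.

    Both query and members are d_h vectors; the result is a weight
    vector of length ``len(members)`` summing to 1.
    """
    if len(members) == 0:
        raise ValueError("attention over an empty member set is undefined")
    wq = ad.matmul(params.W, ad.as_tensor(query))
    scores = []
    for h_k in members:
        wh = ad.matmul(params.W, ad.as_tensor(h_k))
        score = ad.dot(params.a, ad.concat([wq, wh]))
        scores.append(ad.leaky_relu(score, params.negative_slope))
    return ad.softmax(_stack_scalars(scores))


def _stack_scalars(scalars: Sequence[Tensor]) -> Tensor:
    """Concatenate scalar tensors into a 1-d tensor (autodiff-aware)."""
    out = Tensor(np.array([s.data for s in scalars]), tuple(scalars))

    def backward(g):
        for i, s in enumerate(scalars):
            ad._accum(s, g[i])

    out._backward = backward if out.requires_grad else None
    return out


def attentive_aggregate(weights, member_states: Sequence) -> Tensor:
    """Weighted sum of member state vectors: sum_k a_k h_k."""
    weights = ad.as_tensor(weights)
    if weights.shape != (len(member_states),):
        raise ValueError(
            f"{len(member_states)} states but weight vector of shape {weights.shape}"
        )
    terms = [
        ad.mul(ad.pick(weights, k), ad.as_tensor(h))
        for k, h in enumerate(member_states)
    ]
    return ad.sum_tensors(terms)
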