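"""Recursive encoders over dependency trees.

Contains the fully-connected recursive baseline, the Child-Sum
Tree-LSTM cell (per-child forget gates, summed child hidden states) and
post-order tree encoding in two modes:

* ``plain``      — the child aggregate is the unweighted sum of child
                   hidden states;
* ``attentive``  — the aggregate is a softmax-weighted sum, scored
                   against the parent's projected input embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import autodiff as ad
from .attention import AttentionMap, AttentionParams, attention_coefficients, attentive_aggregate
from .autodiff import Tensor
from .data_model import DependencyTree

__all__ = [
    "CellParams",
    "NodeState",
    "TreeEncoderParams",
    "recurnn_update",
    "child_sum_cell",
    "encode_tree",
]

GATES = ("f", "i", "o", "u")


@dataclass
class NodeState:
    """Per-node (cell, hidden) pair."""

    c: Tensor
    h: Tensor


@dataclass
class CellParams:
    """Gate parameters: input matrix W, recurrent matrix U and bias b for
    each of the forget/input/output/update gates."""

    W: dict[str, Tensor]
    U: dict[str, Tensor]
    b: dict[str, Tensor]

    def __post_init__(self):
        for g in GATES:
            if g not in self.W or g not in self.U or g not in self.b:
                raise ValueError(f"missing parameters for gate {g!r}")
        d_h, d_x = self.W["f"].shape
        for g in GATES:
            if self.W[g].shape != (d_h, d_x):
                raise ValueError(f"W[{g}] shape {self.W[g].shape} != ({d_h}, {d_x})")
            if self.U[g].shape != (d_h, d_h):
                raise ValueError(f"U[{g}] shape {self.U[g].shape} != ({d_h}, {d_h})")
            if self.b[g].shape != (d_h,):
                raise ValueError(f"b[{g}] shape {self.b[g].shape} != ({d_h},)")

    @property
    def d_x(self) -> int:
        return self.W["f"].shape[1]

    @property
    def d_h(self) -> int:
        return self.W["f"].shape[0]

    @classmethod
    def init(cls, d_x: int, d_h: int, rng: np.random.Generator, scale: float = 0.1) -> "CellParams":
        return cls(
            W={g: Tensor(rng.normal(0, scale, (d_h, d_x)), requires_grad=True) for g in GATES},
            U={g: Tensor(rng.normal(0, scale, (d_h, d_h)), requires_grad=True) for g in GATES},
            b={g: Tensor(np.zeros(d_h), requires_grad=True) for g in GATES},
        )

    def tensors(self) -> list[Tensor]:
        return [self.W[g] for g in GATES] + [self.U[g] for g in GATES] + [self.b[g] for g in GATES]


@dataclass
class TreeEncoderParams:
    """Cell parameters plus (for attentive mode) attention parameters and
    the query projection applied to the parent's input embedding."""

    cell: CellParams
    attn: AttentionParams | None = None
    query_proj: Tensor | None = None  # d_h x d_x

    @classmethod
    def init(cls, d_x: int, d_h: int, rng: np.random.Generator,
             attentive: bool = True, scale: float = 0.1) -> "TreeEncoderParams":
        cell = CellParams.init(d_x, d_h, rng, scale)
        if not attentive:
            return cls(cell=cell)
        return cls(
            cell=cell,
            attn=AttentionParams.init(d_h, rng, scale),
            query_proj=Tensor(rng.normal(0, scale, (d_h, d_x)), requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        out = self.cell.tensors()
        if self.attn is not None:
            out += self.attn.tensors()
        if self.query_proj is not None:
            out.append(self.query_proj)
        return out


def recurnn_update(
    child_embeddings: Sequence[np.ndarray],
    weights: np.ndarray,
    max_arity: int | None = None,
) -> np.ndarray:
    """Fully-connected recursive baseline: sigmoid(W . concat(children)).

    Child vectors are concatenated in order and zero-padded up to the
    arity implied by the weight matrix; exceeding it is a capacity error.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim == 1:
        weights = weights[None, :]
    children = [np.atleast_1d(np.asarray(c, dtype=np.float64)) for c in child_embeddings]
    d = children[0].shape[0] if children else weights.shape[1]
    cap = max_arity if max_arity is not None else weights.shape[1] // d
    if len(children) > cap:
        raise ValueError(f"arity {len(children)} exceeds capacity {cap}")
    stacked = np.zeros(weights.shape[1])
    for i, c in enumerate(children):
        stacked[i * d : i * d + d] = c
    z = weights @ stacked
    out = 1.0 / (1.0 + np.exp(-z))
    return out[0] if out.shape == (1,) else out


def child_sum_cell(
    x_j,
    child_states: Sequence[NodeState],
    params: CellParams,
    aggregate_override=None,
) -> NodeState:
    """One Child-Sum Tree-LSTM cell update.

    The child aggregate is the plain sum of child hidden states unless
    ``aggregate_override`` (an attention-weighted sum) is supplied.
    Forget gates are computed per child from that child's own hidden
    state; leaves degenerate to c = i * u.
    """
    x_j = ad.as_tensor(x_j)
    d_h = params.d_h
    if aggregate_override is not None:
        h_tilde = ad.as_tensor(aggregate_override)
    elif child_states:
        h_tilde = ad.sum_tensors([s.h for s in child_states])
    else:
        h_tilde = Tensor(np.zeros(d_h))

    # the input projection W.x_j is shared by every per-child forget gate
    wx = {g: ad.add(ad.matmul(params.W[g], x_j), params.b[g]) for g in GATES}

    def gate(g: str, recurrent, activation):
        return activation(ad.add(wx[g], ad.matmul(params.U[g], recurrent)))

    i_j = gate("i", h_tilde, ad.sigmoid)
    o_j = gate("o", h_tilde, ad.sigmoid)
    u_j = gate("u", h_tilde, ad.tanh)
    c_j = ad.mul(i_j, u_j)
    for state in child_states:
        f_jk = gate("f", state.h, ad.sigmoid)
        c_j = ad.add(c_j, ad.mul(f_jk, state.c))
    h_j = ad.mul(o_j, ad.tanh(c_j))
    return NodeState(c=c_j, h=h_j)


def encode_tree(
    tree: DependencyTree,
    embeddings,
    params: TreeEncoderParams,
    mode: str = "plain",
) -> tuple[dict[int, NodeState], list[AttentionMap]]:
    """Encode every token of ``tree`` bottom-up.

    ``embeddings`` is an (n, d_x) array (row i = token i+1) or a mapping
    from token index to vector; rows may be plain arrays or tensors.
    Returns the per-node states and, in attentive mode, one AttentionMap
    per internal node.
    """
    if mode not in ("plain", "attentive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "attentive" and (params.attn is None or params.query_proj is None):
        raise ValueError("attentive mode requires attention parameters")

    def embed(j: int):
        if isinstance(embeddings, Mapping):
            return embeddings[j]
        return embeddings[j - 1]

    states: dict[int, NodeState] = {}
    maps: list[AttentionMap] = []
    for j in tree.postorder():
        kids = tree.children(j)
        child_states = [states[k] for k in kids]
        override = None
        if mode == "attentive" and kids:
            query = ad.matmul(params.query_proj, ad.as_tensor(embed(j)))
            weights = attention_coefficients(
                query, [s.h for s in child_states], params.attn
            )
            override = attentive_aggregate(weights, [s.h for s in child_states])
            maps.append(AttentionMap(node=j, members=kids, weights=weights.data.copy()))
        states[j] = child_sum_cell(embed(j), child_states, params.cell, override)
    return states, maps
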