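"""Attentive encoder over predicate-argument graphs, and fusion with the
dependency-tree representation.

The graph may be cyclic, so the gated update runs as K synchronous
message-passing layers with self-loops: at each layer every node attends
over its neighborhood plus itself using previous-layer hidden states,
aggregates, and applies the same gate family as the tree cell, with
forget gates consuming the neighbors' previous-layer (cell, hidden)
pairs.  Layer 0 states are zero, matching the leaf convention on the
tree side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import autodiff as ad
from .attention import AttentionMap, AttentionParams, attention_coefficients, attentive_aggregate
from .autodiff import Tensor
from .data_model import PASGraph
from .tree_encoders import CellParams, NodeState

__all__ = ["PasEncoderParams", "encode_pas", "fuse"]


@dataclass
class PasEncoderParams:
    cell: CellParams
    attn: AttentionParams | None = None
    n_layers: int = 2
    rho: Tensor | None = None  # optional learned scalar gate on the fused hidden

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("layer count must be >= 1")

    @classmethod
    def init(cls, d_x: int, d_h: int, rng: np.random.Generator,
             attentive: bool = True, n_layers: int = 2, scale: float = 0.1,
             learn_rho: bool = False) -> "PasEncoderParams":
        return cls(
            cell=CellParams.init(d_x, d_h, rng, scale),
            attn=AttentionParams.init(d_h, rng, scale) if attentive else None,
            n_layers=n_layers,
            rho=Tensor(1.0, requires_grad=True) if learn_rho else None,
        )

    def tensors(self) -> list[Tensor]:
        out = self.cell.tensors()
        if self.attn is not None:
            out += self.attn.tensors()
        if self.rho is not None:
            out.append(self.rho)
        return out


def encode_pas(
    graph: PASGraph,
    embeddings,
    params: PasEncoderParams,
    mode: str = "attentive",
    n_tokens: int | None = None,
) -> tuple[dict[int, NodeState], list[AttentionMap]]:
    """Encode every token against the PAS neighborhood structure.

    ``embeddings`` as in :func:`treetrigger.tree_encoders.encode_tree`.
    Nodes outside any edge attend only to their self-loop (weight 1).
    In ``uniform`` mode attention is replaced by equal weights over the
    member set.  Returns final-layer states and final-layer attention
    maps (one per node).
    """
    if mode not in ("attentive", "uniform"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "attentive" and params.attn is None:
        raise ValueError("attentive mode requires attention parameters")

    def embed(j: int):
        if isinstance(embeddings, Mapping):
            return embeddings[j]
        return embeddings[j - 1]

    if n_tokens is None:
        n_tokens = len(embeddings)
    nodes = list(range(1, n_tokens + 1))
    members = {j: sorted(graph.neighbors(j) | {j}) for j in nodes}
    for j in nodes:
        for k in members[j]:
            if k < 1 or k > n_tokens:
                raise ValueError(f"{graph.sentence_id}: node {k} outside 1..{n_tokens}")

    d_h = params.cell.d_h
    zero = Tensor(np.zeros(d_h))
    prev: dict[int, NodeState] = {j: NodeState(c=zero, h=zero) for j in nodes}
    maps: list[AttentionMap] = []
    for layer in range(params.n_layers):
        last = layer == params.n_layers - 1
        cur: dict[int, NodeState] = {}
        if layer == 0 and not last:
            # all previous states are zero: attention is uniform over zeros
            # and forget-gate terms vanish, so the update is exactly
            # c = i*u, h = o*tanh(c) with zero recurrent input.
            for j in nodes:
                cur[j] = _gated_update(embed(j), zero, [], params.cell)
            prev = cur
            continue
        for j in nodes:
            mem = members[j]
            mem_states = [prev[k] for k in mem]
            if mode == "attentive":
                weights = attention_coefficients(
                    prev[j].h, [s.h for s in mem_states], params.attn
                )
            else:
                weights = Tensor(np.full(len(mem), 1.0 / len(mem)))
            h_tilde = attentive_aggregate(weights, [s.h for s in mem_states])
            cur[j] = _gated_update(embed(j), h_tilde, mem_states, params.cell)
            if last:
                maps.append(AttentionMap(node=j, members=list(mem),
                                         weights=np.asarray(weights).copy()))
        prev = cur
    return prev, maps


def _gated_update(x_j, h_tilde, mem_states, cell: CellParams) -> NodeState:
    x_j = ad.as_tensor(x_j)
    wx = {g: ad.add(ad.matmul(cell.W[g], x_j), cell.b[g]) for g in "fiou"}

    def gate(g, recurrent, act):
        return act(ad.add(wx[g], ad.matmul(cell.U[g], recurrent)))

    i_j = gate("i", h_tilde, ad.sigmoid)
    o_j = gate("o", h_tilde, ad.sigmoid)
    u_j = gate("u", h_tilde, ad.tanh)
    c_j = ad.mul(i_j, u_j)
    for state in mem_states:
        f_jk = gate("f", state.h, ad.sigmoid)
        c_j = ad.add(c_j, ad.mul(f_jk, state.c))
    return NodeState(c=c_j, h=ad.mul(o_j, ad.tanh(c_j)))


def fuse(
    dep_states: dict[int, NodeState] | None,
    pas_states: dict[int, NodeState] | None,
    d_h: int,
    rho: Tensor | None = None,
) -> dict[int, Tensor]:
    """Per-token concatenation [h_dep ; h_pas] of length 2*d_h.

    A disabled branch (None) or a token absent from one side contributes
    a zero block.  ``rho`` optionally scales the PAS hidden first.
    """
    if dep_states is None and pas_states is None:
        raise ValueError("at least one branch must be present")
    keys = set(dep_states or ()) | set(pas_states or ())
    if dep_states and pas_states and not set(pas_states) <= set(dep_states):
        extra = sorted(set(pas_states) - set(dep_states))
        raise ValueError(f"PAS tokens {extra} missing from the dependency side")
    zero = Tensor(np.zeros(d_h))
    fused: dict[int, Tensor] = {}
    for j in keys:
        h_dep = dep_states[j].h if dep_states and j in dep_states else zero
        h_pas = pas_states[j].h if pas_states and j in pas_states else zero
        if rho is not None and pas_states and j in pas_states:
            h_pas = ad.mul(rho, h_pas)
        fused[j] = ad.concat([h_dep, h_pas])
    return fused
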