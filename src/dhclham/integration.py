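"""View gating, multi-head inter-view attention, decoding, and losses.

Each view's embeddings pass through a squeeze-and-excitation style gate
(global average pooling over nodes, a two-layer FNN with ReLU then sigmoid,
per-feature multiplicative gate, ReLU).  The two gated views are then fused
per node by a 2x2 inter-view attention: queries/keys are split into
per-head sub-blocks, each head's attention is applied to the full value
vectors, the head outputs are averaged, and the row-concatenated pair is
mapped back to d dimensions.  Decoding is an inner product of the two
entities' affine-mapped embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import NodeEmbeddings
from .nn import Tensor, concat, glorot_uniform

__all__ = [
    "IntegrationParams",
    "view_gate",
    "interview_attention",
    "decode_scores",
    "reconstruction_loss",
    "total_loss",
]


@dataclass
class IntegrationParams:
    """Gates, inter-view attention projections, fusion map, and decoder for one entity."""

    gate_w1: list  # per view: (d, d)
    gate_b1: list
    gate_w2: list
    gate_b2: list
    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    Wh: Tensor  # (2d, d)
    bh: Tensor
    dec_w: Tensor  # (d, d)
    dec_b: Tensor
    n_heads: int = 1

    @classmethod
    def init(cls, rng: np.random.Generator, d: int, n_heads: int = 1, n_views: int = 2) -> "IntegrationParams":
        return cls(
            gate_w1=[glorot_uniform(rng, d, d) for _ in range(n_views)],
            gate_b1=[Tensor(np.zeros(d), requires_grad=True) for _ in range(n_views)],
            gate_w2=[glorot_uniform(rng, d, d) for _ in range(n_views)],
            gate_b2=[Tensor(np.zeros(d), requires_grad=True) for _ in range(n_views)],
            Wq=glorot_uniform(rng, d, d),
            Wk=glorot_uniform(rng, d, d),
            Wv=glorot_uniform(rng, d, d),
            Wh=glorot_uniform(rng, 2 * d, d),
            bh=Tensor(np.zeros(d), requires_grad=True),
            dec_w=glorot_uniform(rng, d, d),
            dec_b=Tensor(np.zeros(d), requires_grad=True),
            n_heads=n_heads,
        )

    def parameters(self) -> list:
        return [
            *self.gate_w1,
            *self.gate_b1,
            *self.gate_w2,
            *self.gate_b2,
            self.Wq,
            self.Wk,
            self.Wv,
            self.Wh,
            self.bh,
            self.dec_w,
            self.dec_b,
        ]


def view_gate(Z: NodeEmbeddings | Tensor, params: IntegrationParams, view: int = 0) -> Tensor:
    """Per-feature multiplicative gate computed from the node-pooled embedding."""
    Z = Z.Z if isinstance(Z, NodeEmbeddings) else Z
    pooled = Z.mean(axis=0)  # (d,) global average pool over nodes
    hidden = (pooled @ params.gate_w1[view] + params.gate_b1[view]).relu()
    gate = (hidden @ params.gate_w2[view] + params.gate_b2[view]).sigmoid()
    return (Z * gate).relu()


def _softmax2(s1: Tensor, s2: Tensor) -> tuple[Tensor, Tensor]:
    """Stable pairwise softmax over two (N,) score vectors."""
    m = np.maximum(s1.data, s2.data)
    e1 = (s1 - m).exp()
    e2 = (s2 - m).exp()
    tot = e1 + e2
    return e1 / tot, e2 / tot


def interview_attention(Z_v1, Z_v2, params: IntegrationParams) -> Tensor:
    """Fuse the two views per node with multi-head 2x2 attention.

    Per head, queries/keys use disjoint feature sub-blocks (near-equal
    splits, so d need not divide the head count); the 2x2 attention of each
    head acts on the full value vectors and head outputs are averaged.  The
    score divisor is d, the embedding dimension, as in the printed score.
    """
    Z1 = Z_v1.Z if isinstance(Z_v1, NodeEmbeddings) else Z_v1
    Z2 = Z_v2.Z if isinstance(Z_v2, NodeEmbeddings) else Z_v2
    d = params.Wq.data.shape[1]
    q1, q2 = Z1 @ params.Wq, Z2 @ params.Wq
    k1, k2 = Z1 @ params.Wk, Z2 @ params.Wk
    v1, v2 = Z1 @ params.Wv, Z2 @ params.Wv
    n = Z1.shape[0]
    blocks = np.array_split(np.arange(d), params.n_heads)
    out1_sum = Tensor(np.zeros((n, d)))
    out2_sum = Tensor(np.zeros((n, d)))
    for idx in blocks:
        sl = np.s_[:, idx]
        s11 = (q1[sl] * k1[sl]).sum(axis=1) * (1.0 / d)
        s12 = (q1[sl] * k2[sl]).sum(axis=1) * (1.0 / d)
        s21 = (q2[sl] * k1[sl]).sum(axis=1) * (1.0 / d)
        s22 = (q2[sl] * k2[sl]).sum(axis=1) * (1.0 / d)
        a11, a12 = _softmax2(s11, s12)
        a21, a22 = _softmax2(s21, s22)
        out1_sum = out1_sum + a11.reshape(n, 1) * v1 + a12.reshape(n, 1) * v2
        out2_sum = out2_sum + a21.reshape(n, 1) * v1 + a22.reshape(n, 1) * v2
    scale = 1.0 / params.n_heads
    fused = concat([out1_sum * scale, out2_sum * scale], axis=1)  # (N, 2d)
    return fused @ params.Wh + params.bh


def interview_attention_weights(Z_v1, Z_v2, params: IntegrationParams) -> np.ndarray:
    """Per-node, per-head 2x2 attention matrices (for inspection/tests)."""
    Z1 = Z_v1.Z if isinstance(Z_v1, NodeEmbeddings) else Z_v1
    Z2 = Z_v2.Z if isinstance(Z_v2, NodeEmbeddings) else Z_v2
    d = params.Wq.data.shape[1]
    q = np.stack([Z1.data @ params.Wq.data, Z2.data @ params.Wq.data])  # (2, N, d)
    k = np.stack([Z1.data @ params.Wk.data, Z2.data @ params.Wk.data])
    blocks = np.array_split(np.arange(d), params.n_heads)
    n = q.shape[1]
    out = np.empty((params.n_heads, n, 2, 2))
    for h, idx in enumerate(blocks):
        s = np.einsum("ind,jnd->nij", q[:, :, idx], k[:, :, idx]) / d
        e = np.exp(s - s.max(axis=2, keepdims=True))
        out[h] = e / e.sum(axis=2, keepdims=True)
    return out


def decode_scores(Hm: Tensor, Hd: Tensor, params_m: IntegrationParams, params_d: IntegrationParams) -> Tensor:
    """Association scores As = FNN(Hm) FNN(Hd)^T, shape (Nm, Nd)."""
    Ym = Hm @ params_m.dec_w + params_m.dec_b
    Yd = Hd @ params_d.dec_w + params_d.dec_b
    return Ym @ Yd.T


def reconstruction_loss(
    A: np.ndarray,
    As: Tensor | np.ndarray,
    observed_mask: np.ndarray,
    unobserved_mask: np.ndarray,
    alpha: float,
) -> Tensor:
    """Weighted Frobenius reconstruction loss over disjoint entry masks.

    L = (1-alpha)/2 ||P_obs(A - As)||_F^2 + alpha/2 ||P_unobs(A - As)||_F^2.
    Entries in neither mask (e.g. held-out test pairs) contribute nothing.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0,1]")
    observed_mask = np.asarray(observed_mask, dtype=bool)
    unobserved_mask = np.asarray(unobserved_mask, dtype=bool)
    if (observed_mask & unobserved_mask).any():
        raise ValueError("observed and unobserved masks overlap")
    As = As if isinstance(As, Tensor) else Tensor(np.asarray(As, dtype=float))
    R = Tensor(np.asarray(A, dtype=float)) - As
    obs_term = ((R * observed_mask) ** 2).sum()
    unobs_term = ((R * unobserved_mask) ** 2).sum()
    return obs_term * ((1.0 - alpha) / 2.0) + unobs_term * (alpha / 2.0)


def total_loss(L_RE, L_cl_m, L_cl_d, lambda_m: float = 1.0, gamma_d: float = 1.0):
    """L = L_RE + lambda * L_cl(m) + gamma * L_cl(d)."""
    return L_RE + L_cl_m * lambda_m + L_cl_d * gamma_d
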