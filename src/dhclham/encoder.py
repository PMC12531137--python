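"""Hierarchical attention encoder and hypergraph convolution.

The encoder aggregates in two stages: hyperedge-level attention pools
member-node features into hyperedge representations; node-level attention
pools a node's incident hyperedges back into an updated node embedding,
passed through a two-layer ELU MLP.  The result feeds a spectral hypergraph
convolution (HGCN) with symmetric degree normalization.

Attention scores use the scaled dot product q.k / D with divisor D (the
feature dimension, not sqrt(D)); weights are normalized by softmax by
default, or by the literal ratio of raw scores when ``norm="ratio"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypergraph import FeatureMatrix, Hypergraph, degree_matrices
from .nn import Tensor, glorot_uniform

__all__ = [
    "EncoderParams",
    "NodeEmbeddings",
    "scaled_dot_score",
    "hyperedge_attention",
    "node_attention",
    "hgcn_forward",
    "encode",
    "propagation_matrix",
]


@dataclass(frozen=True)
class NodeEmbeddings:
    Z: Tensor
    entity: str
    view_tag: str


@dataclass
class EncoderParams:
    """Trainable parameters of one (entity, view) encoder."""

    w1: Tensor  # feature projection F -> d
    u: Tensor  # context vector (d,)
    w2: Tensor  # hyperedge projection d -> d
    w3: Tensor  # node projection d -> d
    phi_w1: Tensor
    phi_b1: Tensor
    phi_w2: Tensor
    phi_b2: Tensor
    theta: list  # HGCN layer weights, each d -> d

    @classmethod
    def init(cls, rng: np.random.Generator, n_features: int, d: int, n_layers: int = 2) -> "EncoderParams":
        return cls(
            w1=glorot_uniform(rng, n_features, d),
            u=Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), size=d), requires_grad=True),
            w2=glorot_uniform(rng, d, d),
            w3=glorot_uniform(rng, d, d),
            phi_w1=glorot_uniform(rng, d, d),
            phi_b1=Tensor(np.zeros(d), requires_grad=True),
            phi_w2=glorot_uniform(rng, d, d),
            phi_b2=Tensor(np.zeros(d), requires_grad=True),
            theta=[glorot_uniform(rng, d, d) for _ in range(n_layers)],
        )

    def parameters(self) -> list:
        return [self.w1, self.u, self.w2, self.w3, self.phi_w1, self.phi_b1, self.phi_w2, self.phi_b2, *self.theta]


def scaled_dot_score(q: np.ndarray, k: np.ndarray, D: int | None = None) -> float:
    """q.k / D with divisor D = feature dimension (kept as printed)."""
    q = np.asarray(q, dtype=float)
    k = np.asarray(k, dtype=float)
    if q.shape != k.shape:
        raise ValueError("score vectors must have equal length")
    D = q.size if D is None else D
    return float(q @ k) / D


def _masked_normalize(scores: Tensor, mask: np.ndarray, norm: str) -> Tensor:
    """Normalize `scores` over the True entries of each row of `mask`.

    softmax: exponentiate (stably) then divide by the masked row sum.
    ratio:   divide raw scores by the masked row sum, as printed.
    """
    if norm == "softmax":
        masked = np.where(mask, scores.data, -np.inf)
        rowmax = masked.max(axis=1, keepdims=True)  # constant shift, exact
        z = (scores - rowmax).exp() * mask
        return z / z.sum(axis=1, keepdims=True)
    if norm == "ratio":
        z = scores * mask
        return z / z.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown attention norm {norm!r}")


def hyperedge_attention(
    hg: Hypergraph,
    X: FeatureMatrix | np.ndarray | Tensor,
    params: EncoderParams,
    norm: str = "softmax",
) -> Tensor:
    """Attend over each hyperedge's member nodes; returns (E, d) representations.

    Member scores are scaled dot products of the projected node features
    against the shared context vector u; weights over each hyperedge's
    members are a probability vector; e_j = sum_i a_ji (w1 n_i).
    """
    X = X.X if isinstance(X, FeatureMatrix) else X
    X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=float))
    proj = X @ params.w1  # (N, d)
    d = params.w1.data.shape[1]
    scores = (proj @ params.u) * (1.0 / d)  # (N,), node-wise
    mask = hg.H.T.astype(bool)  # (E, N): row j = members of hyperedge j
    # broadcast node scores across hyperedges, then normalize within members
    a = _masked_normalize(scores + Tensor(np.zeros((hg.n_edges, 1))), mask, norm)
    return a @ proj  # (E, d)


def node_attention(
    hg: Hypergraph,
    E: Tensor,
    X: FeatureMatrix | np.ndarray | Tensor,
    params: EncoderParams,
    norm: str = "softmax",
    entity: str = "microbe",
    view_tag: str = "View1",
) -> NodeEmbeddings:
    """Attend over each node's incident hyperedges and apply the update MLP.

    Z_i = phi(sum_j b_ij (w2 e_j)) with phi = affine -> ELU -> affine.
    """
    X = X.X if isinstance(X, FeatureMatrix) else X
    X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=float))
    d = params.w2.data.shape[1]
    Ew = E @ params.w2  # (E, d)
    Xn = (X @ params.w1) @ params.w3  # node side of the score, (N, d)
    scores = (Xn @ Ew.T) * (1.0 / d)  # (N, E)
    mask = hg.H.astype(bool)
    if (~mask.any(axis=1)).any():
        bad = int(np.flatnonzero(~mask.any(axis=1))[0])
        raise ValueError(f"node {bad} has no incident hyperedge")
    b = _masked_normalize(scores, mask, norm)
    agg = b @ Ew  # (N, d)
    Z = (agg @ params.phi_w1 + params.phi_b1).elu() @ params.phi_w2 + params.phi_b2
    return NodeEmbeddings(Z=Z, entity=entity, view_tag=view_tag)


def propagation_matrix(hg: Hypergraph) -> np.ndarray:
    """Dense HGCN propagation matrix Dv^-1/2 H W De^-1 H^T Dv^-1/2."""
    d_v, d_e = degree_matrices(hg)
    Hs = hg.H * np.sqrt(1.0 / d_v)[:, None]  # Dv^-1/2 H
    return (Hs * (hg.W / d_e)[None, :]) @ Hs.T


def hgcn_forward(hg: Hypergraph, Z0: NodeEmbeddings | Tensor, params: EncoderParams, L: int | None = None) -> NodeEmbeddings:
    """L layers of hypergraph convolution; ReLU on hidden layers, identity last."""
    entity = getattr(Z0, "entity", "microbe")
    view_tag = getattr(Z0, "view_tag", hg.view_tag)
    Z = Z0.Z if isinstance(Z0, NodeEmbeddings) else Z0
    if L is None:
        L = len(params.theta)
    if L < 1 or L > len(params.theta):
        raise ValueError(f"L must lie in [1, {len(params.theta)}]")
    P = Tensor(propagation_matrix(hg))
    for layer in range(L):
        Z = P @ Z @ params.theta[layer]
        if layer < L - 1:
            Z = Z.relu()
    return NodeEmbeddings(Z=Z, entity=entity, view_tag=view_tag)


def encode(
    hg: Hypergraph,
    X: FeatureMatrix | np.ndarray,
    params: EncoderParams,
    norm: str = "softmax",
    entity: str = "microbe",
    use_attention: bool = True,
) -> NodeEmbeddings:
    """Full encoder for one (entity, view): hierarchical attention then HGCN.

    With ``use_attention=False`` (the NoDHA ablation) the attention stages
    are replaced by the direct feature projection X w1.
    """
    if use_attention:
        E = hyperedge_attention(hg, X, params, norm=norm)
        Z0 = node_attention(hg, E, X, params, norm=norm, entity=entity, view_tag=hg.view_tag)
    else:
        Xt = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        Z0 = NodeEmbeddings(Z=Tensor(Xt) @ params.w1, entity=entity, view_tag=hg.view_tag)
    return hgcn_forward(hg, Z0, params)
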