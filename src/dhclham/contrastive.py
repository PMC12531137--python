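"""Dual-view InfoNCE contrastive objective.

For each entity (microbes, drugs) the two hypergraph views yield two
embeddings of every node.  The same node's pair across views is the
positive; every other node — in the anchor's own view and in the other
view — is a negative.  Similarities are cosine on embeddings passed
through a two-layer projection head, scaled by a temperature tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import NodeEmbeddings
from .nn import Tensor, glorot_uniform

__all__ = ["ProjectionHead", "info_nce", "dual_view_contrastive_loss"]

_EPS = 1e-12


@dataclass
class ProjectionHead:
    """Two affine maps with an ELU between (d -> d -> d)."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, d: int) -> "ProjectionHead":
        return cls(
            w1=glorot_uniform(rng, d, d),
            b1=Tensor(np.zeros(d), requires_grad=True),
            w2=glorot_uniform(rng, d, d),
            b2=Tensor(np.zeros(d), requires_grad=True),
        )

    def __call__(self, Z: Tensor) -> Tensor:
        return (Z @ self.w1 + self.b1).elu() @ self.w2 + self.b2

    def parameters(self) -> list:
        return [self.w1, self.b1, self.w2, self.b2]


def _row_normalize(Z: Tensor) -> Tensor:
    norms = (Z * Z).sum(axis=1, keepdims=True).sqrt() + _EPS
    return Z / norms


def info_nce(V: Tensor | np.ndarray, U: Tensor | np.ndarray, head: ProjectionHead | None = None, tau: float = 0.5) -> Tensor:
    """Summed InfoNCE loss anchored on the rows of V against U.

    loss(i) = -log exp(s_ii/tau) / (exp(s_ii/tau)
              + sum_{k!=i} exp(s_vv(i,k)/tau) + sum_{k!=i} exp(s_vu(i,k)/tau))
    where s is cosine similarity of the projected embeddings.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    V = V if isinstance(V, Tensor) else Tensor(np.asarray(V, dtype=float))
    U = U if isinstance(U, Tensor) else Tensor(np.asarray(U, dtype=float))
    if V.shape != U.shape:
        raise ValueError("view embeddings must share shape")
    P = _row_normalize(head(V) if head is not None else V)
    Q = _row_normalize(head(U) if head is not None else U)
    n = P.shape[0]
    pos = (P * Q).sum(axis=1)  # cosine of the positive pair, (N,)
    off = 1.0 - np.eye(n)
    neg_vv = ((P @ P.T) * (1.0 / tau)).exp() * off
    neg_vu = ((P @ Q.T) * (1.0 / tau)).exp() * off
    denom = (pos * (1.0 / tau)).exp() + neg_vv.sum(axis=1) + neg_vu.sum(axis=1)
    return (denom.log() - pos * (1.0 / tau)).sum()


def dual_view_contrastive_loss(
    Zm1: NodeEmbeddings,
    Zm2: NodeEmbeddings,
    Zd1: NodeEmbeddings,
    Zd2: NodeEmbeddings,
    head_m: ProjectionHead,
    head_d: ProjectionHead,
    tau: float = 0.5,
    normalize: bool = True,
) -> tuple[Tensor, Tensor]:
    """Symmetric-anchor contrastive losses for microbes and drugs.

    With ``normalize`` (default) each direction's loss is averaged over
    anchors, so the contrastive terms stay commensurate with the
    reconstruction loss regardless of entity counts; otherwise the raw
    anchor sums are returned.
    """
    sm = 1.0 / Zm1.Z.shape[0] if normalize else 1.0
    sd = 1.0 / Zd1.Z.shape[0] if normalize else 1.0
    L_m = (info_nce(Zm1.Z, Zm2.Z, head_m, tau) + info_nce(Zm2.Z, Zm1.Z, head_m, tau)) * sm
    L_d = (info_nce(Zd1.Z, Zd2.Z, head_d, tau) + info_nce(Zd2.Z, Zd1.Z, head_d, tau)) * sd
    return L_m, L_d
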