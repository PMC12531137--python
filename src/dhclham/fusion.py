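"""Gaussian interaction profile kernels and non-linear similarity fusion.

Multiple similarity views of the same entity type (e.g. curated functional
similarity and the GIP kernel derived from the association matrix) are
integrated by cross-diffusion: each view's normalized state is smoothed
through every other view via its own k-nearest-neighbor local kernel until
the states stop changing, then averaged and symmetrized.  This captures
non-linear agreement between views that a plain average would wash out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import SimilarityView

logger = logging.getLogger("dhclham")

__all__ = [
    "FusedSimilarity",
    "gip_kernel",
    "normalize_weights",
    "local_kernel",
    "snf_fuse",
    "linear_fuse",
    "default_snf_k",
]


@dataclass(frozen=True)
class FusedSimilarity:
    """Final integrated similarity matrix for one entity type."""

    S_final: np.ndarray
    n_iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.S_final.shape[0]


def gip_kernel(A: np.ndarray, axis: str = "rows", entity: str | None = None) -> SimilarityView:
    """Gaussian interaction profile kernel similarity from association profiles.

    Profiles are the rows (microbes) or columns (drugs) of the binary
    association matrix A.  S(i,j) = exp(-eta * ||p_i - p_j||^2) with the
    bandwidth eta = eta' / mean_i ||p_i||^2 and raw bandwidth eta' = 1.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty association matrix")
    if axis == "rows":
        P = A
        entity = entity or "microbe"
    elif axis == "columns":
        P = A.T
        entity = entity or "drug"
    else:
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    sq_norms = (P**2).sum(axis=1)
    denom = sq_norms.mean()
    if denom == 0.0:
        raise ValueError(
            "GIP bandwidth denominator (mean squared profile norm) is zero: "
            "all association profiles are empty"
        )
    eta = 1.0 / denom
    # ||p_i - p_j||^2 via the Gram matrix; clip tiny negatives from rounding
    gram = P @ P.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.clip(d2, 0.0, None, out=d2)
    S = np.exp(-eta * d2)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityView(S=S, entity=entity, source_tag="gip")


def normalize_weights(S: np.ndarray) -> np.ndarray:
    """Row-stochastic weight normalization with diagonal fixed at 1/2.

    Off-diagonal entries are divided by twice the row's off-diagonal sum so
    every row sums to 1.  A row whose off-diagonal entries are all zero is
    left with zero off-diagonals (diagonal stays 1/2) and logged.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValueError("normalization requires N >= 2")
    off = S.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    dead = row_sums == 0.0
    if dead.any():
        logger.warning("normalize_weights: %d row(s) with all-zero off-diagonal", int(dead.sum()))
    safe = np.where(dead, 1.0, row_sums)
    out = off / (2.0 * safe[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def local_kernel(S: np.ndarray, k: int) -> np.ndarray:
    """K-nearest-neighbor local affinity kernel (row-normalized, sparse).

    Row i keeps the k most-similar neighbors of i (excluding i, ties broken
    by lowest index), each divided by their sum; all other entries are 0.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    off = S.copy()
    np.fill_diagonal(off, -np.inf)
    # stable argsort on (-sim) -> ties broken by lowest index
    order = np.argsort(-off, axis=1, kind="stable")
    nbrs = order[:, :k]
    K = np.zeros_like(S)
    rows = np.repeat(np.arange(n), k)
    K[rows, nbrs.ravel()] = S[rows, nbrs.ravel()]
    sums = K.sum(axis=1)
    pos = sums > 0.0
    K[pos] /= sums[pos, None]
    return K


def default_snf_k(n: int) -> int:
    """Default SNF neighbor count: floor(N/10), at least 1."""
    return max(1, n // 10)


def snf_fuse(
    views: list[SimilarityView],
    k: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 50,
) -> FusedSimilarity:
    """Non-linear (cross-diffusion) fusion of M >= 2 similarity views.

    Each view's state starts from the weight-normalized matrix; per
    iteration, view t is updated to K_t (mean of the other views' previous
    states) K_t^T with K_t the view's fixed local kernel, then re-normalized.
    Iteration stops when the largest relative Frobenius change falls below
    ``tol``.  The fused output is the symmetrized mean of the final states.
    """
    if len(views) < 2:
        raise ValueError("snf_fuse requires at least two views")
    n = views[0].n
    entity = views[0].entity
    for v in views:
        if v.n != n or v.entity != entity:
            raise ValueError("all views must share shape and entity type")
    if k is None:
        k = default_snf_k(n)
    M = len(views)
    kernels = [local_kernel(v.S, k) for v in views]
    states = [normalize_weights(v.S) for v in views]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_states = []
        for t in range(M):
            others = sum(states[s] for s in range(M) if s != t) / (M - 1)
            updated = kernels[t] @ others @ kernels[t].T
            new_states.append(normalize_weights(updated))
        change = max(
            np.linalg.norm(new - old, "fro") / max(np.linalg.norm(old, "fro"), 1e-30)
            for new, old in zip(new_states, states)
        )
        states = new_states
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("snf_fuse: no convergence after %d iterations", max_iter)
    S = sum(states) / M
    S_final = (S + S.T) / 2.0
    return FusedSimilarity(S_final=S_final, n_iterations=it, converged=converged)


def linear_fuse(views: list[SimilarityView]) -> FusedSimilarity:
    """Element-wise mean of the views, symmetrized (the ablation baseline)."""
    if not views:
        raise ValueError("linear_fuse requires at least one view")
    n = views[0].n
    for v in views:
        if v.n != n:
            raise ValueError("all views must share shape")
    S = sum(v.S for v in views) / len(views)
    return FusedSimilarity(S_final=(S + S.T) / 2.0, n_iterations=0, converged=True)
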