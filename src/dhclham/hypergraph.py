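"""Node features and the two hypergraph views (KNN and KO clustering).

Node features concatenate an entity's association profile with its fused
similarity row.  View 1 places one hyperedge per node containing the node
and its k nearest Euclidean neighbors; View 2 partitions the nodes into c
clusters found by a seeded population-based refinement of k-means, one
hyperedge per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .fusion import FusedSimilarity

__all__ = [
    "FeatureMatrix",
    "Hypergraph",
    "build_node_features",
    "knn_hypergraph",
    "ko_hypergraph",
    "degree_matrices",
]


@dataclass(frozen=True)
class FeatureMatrix:
    X: np.ndarray
    entity: str


@dataclass(frozen=True)
class Hypergraph:
    """Incidence matrix H (nodes x hyperedges) with unit hyperedge weights."""

    H: np.ndarray
    view_tag: str
    W: np.ndarray = field(default=None)  # diagonal weights as a vector

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        if not np.isin(H, (0.0, 1.0)).all():
            raise ValueError("incidence matrix entries must be 0/1")
        if (H.sum(axis=0) == 0).any():
            raise ValueError("empty hyperedge (all-zero incidence column)")
        object.__setattr__(self, "H", H)
        W = np.ones(H.shape[1]) if self.W is None else np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)

    @property
    def n_nodes(self) -> int:
        return self.H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.H.shape[1]


def build_node_features(A: np.ndarray, fused: FusedSimilarity, entity: str) -> FeatureMatrix:
    """Concatenate association profiles with fused-similarity rows."""
    A = np.asarray(A, dtype=float)
    S = fused.S_final
    if entity == "microbe":
        if S.shape[0] != A.shape[0]:
            raise ValueError(f"microbe similarity {S.shape} does not match A {A.shape}")
        X = np.concatenate([A, S], axis=1)
    elif entity == "drug":
        if S.shape[0] != A.shape[1]:
            raise ValueError(f"drug similarity {S.shape} does not match A {A.shape}")
        X = np.concatenate([A.T, S], axis=1)
    else:
        raise ValueError(f"entity must be 'microbe' or 'drug', got {entity!r}")
    return FeatureMatrix(X=X, entity=entity)


def knn_hypergraph(X: FeatureMatrix | np.ndarray, k: int, include_centroid: bool = True) -> Hypergraph:
    """View-1 hypergraph: hyperedge i = node i plus its k nearest neighbors.

    Distances are Euclidean on the raw feature rows; ties at the k-th
    neighbor are broken by lowest index.  With ``include_centroid`` every
    hyperedge has exactly k+1 members and H(i, i) = 1.
    """
    X = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    nbrs = order[:, :k]
    H = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    H[nbrs.ravel(), rows] = 1.0  # column i = hyperedge of node i
    if include_centroid:
        H[np.arange(n), np.arange(n)] = 1.0
    return Hypergraph(H=H, view_tag="View1")


def _kmeanspp_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding of c centers."""
    n = X.shape[0]
    centers = np.empty((c, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, c):
        total = d2.sum()
        if total == 0.0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    return labels, float(d2[np.arange(X.shape[0]), labels].sum())


def _lloyd_step(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    labels, _ = _assign(X, centers)
    new = centers.copy()
    for j in range(centers.shape[0]):
        members = X[labels == j]
        if len(members):
            new[j] = members.mean(axis=0)
    return new


def ko_hypergraph(
    X: FeatureMatrix | np.ndarray,
    c: int,
    pop_size: int = 10,
    max_iter: int = 100,
    seed: int = 0,
    step: float = 0.5,
) -> Hypergraph:
    """View-2 hypergraph: one hyperedge per cluster of a k-means optimizer.

    A seeded population of ``pop_size`` candidate center sets (k-means++
    initialized) is refined: each candidate takes one Lloyd step per
    iteration, then drifts by ``step`` toward the centroid of the
    top-quartile candidates (by within-cluster sum of squares).  The
    best-fitness candidate wins; empty clusters are repaired by moving the
    center to the point of the largest cluster farthest from its center.
    Deterministic for a fixed seed.
    """
    X = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (2 <= c <= n):
        raise ValueError(f"cluster count must lie in [2, {n}], got {c}")
    rng = np.random.default_rng(seed)
    pop = [_kmeanspp_init(X, c, rng) for _ in range(pop_size)]
    best_centers = None
    best_fit = np.inf
    for _ in range(max_iter):
        pop = [_lloyd_step(X, cand) for cand in pop]
        fits = np.array([_assign(X, cand)[1] for cand in pop])
        order = np.argsort(fits, kind="stable")
        q = max(1, pop_size // 4)
        elite = sum(pop[i] for i in order[:q]) / q
        if fits[order[0]] < best_fit - 1e-12:
            best_fit = fits[order[0]]
            best_centers = pop[order[0]].copy()
        elif np.allclose(pop[order[0]], best_centers):
            break  # best candidate no longer moving
        pop = [cand + step * (elite - cand) if i != order[0] else cand for i, cand in enumerate(pop)]

    labels, _ = _assign(X, best_centers)
    # repair empty clusters: give them the farthest point of the largest cluster
    for j in range(c):
        if (labels == j).sum() == 0:
            sizes = np.bincount(labels, minlength=c)
            big = sizes.argmax()
            members = np.flatnonzero(labels == big)
            d = ((X[members] - best_centers[big]) ** 2).sum(axis=1)
            labels[members[d.argmax()]] = j
    H = np.zeros((n, c))
    H[np.arange(n), labels] = 1.0
    return Hypergraph(H=H, view_tag="View2")


def degree_matrices(hg: Hypergraph) -> tuple[np.ndarray, np.ndarray]:
    """Node degrees d(v) = sum_e w(e) H(v,e) and hyperedge degrees d(e)."""
    d_e = hg.H.sum(axis=0)
    d_v = hg.H @ hg.W
    if (d_v <= 0).any():
        bad = int(np.flatnonzero(d_v <= 0)[0])
        raise ValueError(f"isolated node {bad}: zero hypergraph degree")
    return d_v, d_e
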