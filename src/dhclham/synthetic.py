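"""Seeded synthetic microbe-drug datasets with planted low-rank structure.

The generator emulates the statistical regime the model assumes: a sparse
binary bipartite association matrix (real curated datasets sit around 1-6%
density) driven by block-structured latent factors — entities cluster into
groups with shared association preferences — plus similarity matrices that
are noisy, partially missing views of the same latent factors.  Clustered
latent structure makes both the KNN and the clustering hypergraph views
meaningful, and the similarity views carry signal about the association
pattern, which is exactly what the fusion and contrastive stages exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import AssociationDataset, SimilarityView

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "permute_labels"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults are the desk-scale study conditions: 60 microbes x 120 drugs,
    rank-4 factors in 3 blocks per entity, 5% association density, mild
    similarity noise, and half of the off-diagonal similarity entries
    removed (curated similarity inputs are typically very incomplete).
    """

    n_microbes: int = 60
    n_drugs: int = 120
    latent_rank: int = 4
    n_blocks: int = 3
    target_density: float = 0.05
    similarity_noise_sd: float = 0.05
    ms1_missing_frac: float = 0.5
    activity_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_microbes < 2 or self.n_drugs < 2:
            raise ValueError("need at least 2 microbes and 2 drugs")
        if not (0.0 < self.target_density < 1.0):
            raise ValueError("target_density must lie in (0,1)")
        if self.target_density < 1.0 / (self.n_microbes * self.n_drugs):
            raise ValueError("target_density below one expected association")
        if not (0.0 <= self.ms1_missing_frac < 1.0):
            raise ValueError("ms1_missing_frac must lie in [0,1)")
        if self.similarity_noise_sd < 0:
            raise ValueError("similarity_noise_sd must be non-negative")
        if self.n_blocks < 1 or self.latent_rank < 1:
            raise ValueError("n_blocks and latent_rank must be >= 1")
        if self.activity_sd < 0:
            raise ValueError("activity_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticDataset:
    ds: AssociationDataset
    ms1: SimilarityView
    ds1: SimilarityView
    U: np.ndarray  # microbe latent factors (Nm, r)
    Vt: np.ndarray  # drug latent factors (Nd, r)
    microbe_blocks: np.ndarray
    drug_blocks: np.ndarray


def _block_directions(rng: np.random.Generator, n_blocks: int, rank: int) -> np.ndarray:
    """Block-mean directions with controlled separation (norm 2 each).

    Orthonormal when n_blocks <= rank (QR of a Gaussian matrix), random unit
    directions otherwise; shared between microbes and drugs so that same-block
    microbe-drug pairs carry positive latent affinity (assortative planted
    block structure).
    """
    G = rng.normal(size=(rank, max(n_blocks, rank)))
    if n_blocks <= rank:
        Q, _ = np.linalg.qr(G)
        dirs = Q[:, :n_blocks].T
    else:
        G = rng.normal(size=(n_blocks, rank))
        dirs = G / np.linalg.norm(G, axis=1, keepdims=True)
    return 2.0 * dirs


def _block_factors(
    rng: np.random.Generator, n: int, rank: int, n_blocks: int, means: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Latent factors = block mean + within-block scatter."""
    labels = rng.integers(n_blocks, size=n)
    # guarantee each block is populated
    labels[:n_blocks] = np.arange(n_blocks)
    X = means[labels] + rng.normal(0.0, 0.35, size=(n, rank))
    return X, labels


def _solve_bias(logits: np.ndarray, target: float) -> float:
    """Bisection on the intercept so mean sigmoid(logits + b) = target."""
    lo, hi = -40.0, 40.0
    f = lambda b: float(np.mean(1.0 / (1.0 + np.exp(-(logits + b))))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target density unreachable within bias bounds")
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _similarity_from_factors(
    X: np.ndarray, noise_sd: float, missing_frac: float, rng: np.random.Generator, entity: str
) -> SimilarityView:
    """Cosine similarity of the factors mapped to [0,1], noised, sparsified."""
    norms = np.linalg.norm(X, axis=1, keepdims=True) + 1e-12
    C = (X / norms) @ (X / norms).T
    S = (C + 1.0) / 2.0
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=S.shape)
        noise = (noise + noise.T) / 2.0
        S = np.clip(S + noise, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    n = S.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    n_missing = int(np.floor(missing_frac * len(iu)))
    if n_missing:
        drop = rng.choice(len(iu), size=n_missing, replace=False)
        S[iu[drop], ju[drop]] = 0.0
        S[ju[drop], iu[drop]] = 0.0
    return SimilarityView(S=S, entity=entity, source_tag="synthetic")


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Sample a full synthetic dataset from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    means = _block_directions(rng, spec.n_blocks, spec.latent_rank)
    U, mb = _block_factors(rng, spec.n_microbes, spec.latent_rank, spec.n_blocks, means)
    V, db = _block_factors(rng, spec.n_drugs, spec.latent_rank, spec.n_blocks, means)
    # per-entity activity: real association data is strongly degree-heterogeneous
    # (broad-spectrum drugs, widely-studied microbes), which is what makes
    # interaction-profile kernels informative
    act_m = rng.normal(0.0, spec.activity_sd, size=(spec.n_microbes, 1))
    act_d = rng.normal(0.0, spec.activity_sd, size=(1, spec.n_drugs))
    logits = U @ V.T + act_m + act_d
    bias = _solve_bias(logits, spec.target_density)
    probs = 1.0 / (1.0 + np.exp(-(logits + bias)))
    A = (rng.random(size=probs.shape) < probs).astype(float)
    ds = AssociationDataset(
        microbe_ids=tuple(f"m{i}" for i in range(spec.n_microbes)),
        drug_ids=tuple(f"d{j}" for j in range(spec.n_drugs)),
        A=A,
    )
    ms1 = _similarity_from_factors(U, spec.similarity_noise_sd, spec.ms1_missing_frac, rng, "microbe")
    ds1 = _similarity_from_factors(V, spec.similarity_noise_sd, spec.ms1_missing_frac, rng, "drug")
    return SyntheticDataset(ds=ds, ms1=ms1, ds1=ds1, U=U, Vt=V, microbe_blocks=mb, drug_blocks=db)


def permute_labels(sd: SyntheticDataset, seed: int = 0) -> SyntheticDataset:
    """Null control: permute A's entries, keeping density and similarities.

    Destroys the linkage between the association pattern and the latent
    factors, so any real model should fall to chance-level discrimination.
    """
    rng = np.random.default_rng(seed)
    flat = sd.ds.A.ravel().copy()
    rng.shuffle(flat)
    ds = AssociationDataset(sd.ds.microbe_ids, sd.ds.drug_ids, flat.reshape(sd.ds.A.shape))
    return replace(sd, ds=ds)
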