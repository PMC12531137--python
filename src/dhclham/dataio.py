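"""Reading/writing association and similarity matrices, run configuration.

On-disk conventions
-------------------
Dense TSV: first cell empty, remaining header cells are drug identifiers;
each following row starts with a microbe identifier followed by the 0/1
entries.  Edge-list TSV: three columns ``microbe_id<TAB>drug_id<TAB>value``;
pairs absent from the file are 0.  Similarity matrices are dense TSVs with
matching row and column labels; missing entries read as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dhclham")

__all__ = [
    "AssociationDataset",
    "RunConfig",
    "SimilarityView",
    "read_association_table",
    "write_association_table",
    "dataset_summary",
    "read_similarity_matrix",
    "write_similarity_matrix",
]


@dataclass(frozen=True)
class AssociationDataset:
    """Binary microbe x drug association matrix with identifier lists.

    Rows are microbes, columns drugs; entry 1 marks a confirmed association.
    """

    microbe_ids: tuple
    drug_ids: tuple
    A: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape != (len(self.microbe_ids), len(self.drug_ids)):
            raise ValueError(
                f"association matrix shape {A.shape} does not match "
                f"{len(self.microbe_ids)} microbes x {len(self.drug_ids)} drugs"
            )
        if len(set(self.microbe_ids)) != len(self.microbe_ids):
            raise ValueError("duplicate microbe identifiers")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug identifiers")
        if A.size == 0:
            raise ValueError("empty association matrix")
        if not np.isin(A, (0.0, 1.0)).all():
            bad = A[~np.isin(A, (0.0, 1.0))][0]
            raise ValueError(f"association entries must be 0/1, found {bad!r}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "microbe_ids", tuple(self.microbe_ids))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)


@dataclass(frozen=True)
class SimilarityView:
    """Square symmetric similarity matrix for one entity type.

    ``source_tag`` records provenance, e.g. "functional" (curated input) or
    "gip" (Gaussian interaction profile kernel).
    """

    S: np.ndarray
    entity: str
    source_tag: str = ""

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {S.shape}")
        if self.entity not in ("microbe", "drug"):
            raise ValueError(f"entity must be 'microbe' or 'drug', got {self.entity!r}")
        object.__setattr__(self, "S", S)

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class RunConfig:
    """Hyperparameters of the model and the training/evaluation protocol.

    Defaults follow the reported training setup: Adam at learning rate 1e-4,
    embedding dimension 256, 400 epochs, reconstruction trade-off alpha=0.11,
    contrastive weights lambda_m = gamma_d = 1, 5 attention heads, 2 HGCN
    layers, KNN neighbor count 13 and 9 cluster centers for the two hypergraph
    views, 5-fold cross-validation.  ``tau`` (InfoNCE temperature) defaults to
    0.5.  ``attention_norm`` selects softmax (default) or the literal
    ratio-of-scores normalization in the hierarchical attention.
    """

    embed_dim: int = 256
    epochs: int = 400
    learning_rate: float = 1e-4
    alpha: float = 0.11
    lambda_m: float = 1.0
    gamma_d: float = 1.0
    tau: float = 0.5
    n_heads: int = 5
    hgcn_layers: int = 2
    knn_k: int = 13
    ko_c: int = 9
    cv_folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    attention_norm: str = "softmax"
    include_centroid: bool = True
    snf_k: int | None = None  # SNF local-kernel neighbors; None -> floor(N/10)
    variant: str = "full"  # full | NoDHA | NoCL | MS1DS1 | MS2DS2 | Linear

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0,1], got {self.alpha}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("embed_dim", "epochs", "n_heads", "hgcn_layers", "knn_k", "ko_c", "cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.attention_norm not in ("softmax", "ratio"):
            raise ValueError("attention_norm must be 'softmax' or 'ratio'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a flat YAML config; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# association matrices


def read_association_table(path, format: str = "dense") -> AssociationDataset:
    """Read an association matrix from a dense TSV or 3-column edge list."""
    path = Path(path)
    if format == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return AssociationDataset(
            microbe_ids=tuple(str(i) for i in df.index),
            drug_ids=tuple(str(c) for c in df.columns),
            A=df.to_numpy(dtype=float),
        )
    if format == "edgelist":
        return _read_edgelist(path)
    raise ValueError(f"unknown format {format!r}")


def _read_edgelist(path: Path) -> AssociationDataset:
    microbe_ids: list[str] = []
    drug_ids: list[str] = []
    entries: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            m, d, raw = parts
            try:
                v = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {raw!r}") from None
            if v not in (0.0, 1.0):
                raise ValueError(f"{path}:{lineno}: association values must be 0/1, got {raw}")
            key = (m, d)
            if key in entries and entries[key] != v:
                raise ValueError(f"{path}:{lineno}: duplicate edge {key} with conflicting value")
            entries[key] = v
            if m not in microbe_ids:
                microbe_ids.append(m)
            if d not in drug_ids:
                drug_ids.append(d)
    A = np.zeros((len(microbe_ids), len(drug_ids)))
    mi = {m: i for i, m in enumerate(microbe_ids)}
    di = {d: j for j, d in enumerate(drug_ids)}
    for (m, d), v in entries.items():
        A[mi[m], di[d]] = v
    return AssociationDataset(tuple(microbe_ids), tuple(drug_ids), A)


def write_association_table(ds: AssociationDataset, path, format: str = "dense") -> None:
    path = Path(path)
    if format == "dense":
        pd.DataFrame(ds.A.astype(int), index=list(ds.microbe_ids), columns=list(ds.drug_ids)).to_csv(
            path, sep="\t"
        )
    elif format == "edgelist":
        with open(path, "w") as fh:
            for i, m in enumerate(ds.microbe_ids):
                for j, d in enumerate(ds.drug_ids):
                    if ds.A[i, j]:
                        fh.write(f"{m}\t{d}\t1\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def dataset_summary(ds: AssociationDataset) -> dict:
    """Counts and matrix density (percent, two decimals) of a dataset."""
    n_assoc = int(np.count_nonzero(ds.A))
    density = round(100.0 * n_assoc / (ds.n_microbes * ds.n_drugs), 2)
    return {
        "n_microbes": ds.n_microbes,
        "n_drugs": ds.n_drugs,
        "n_associations": n_assoc,
        "density_percent": density,
    }


# ----------------------------------------------------------------------
# similarity matrices


def read_similarity_matrix(path, entity_ids, entity: str = "microbe", source_tag: str = "") -> SimilarityView:
    """Read a labelled square similarity TSV, reindexed to ``entity_ids``.

    Values must lie in [0, 1]; missing labels raise; asymmetry beyond 1e-8
    is repaired by (S + S^T)/2 with a warning.
    """
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    entity_ids = [str(e) for e in entity_ids]
    missing = [e for e in entity_ids if e not in df.index or e not in df.columns]
    if missing:
        raise ValueError(f"similarity matrix missing labels: {missing}")
    S = df.reindex(index=entity_ids, columns=entity_ids).fillna(0.0).to_numpy(dtype=float)
    if S.min() < 0.0 or S.max() > 1.0:
        raise ValueError(
            f"similarity values must lie in [0,1]; range found [{S.min():.4g}, {S.max():.4g}]"
        )
    if np.abs(S - S.T).max() > 1e-8:
        logger.warning("asymmetric similarity matrix %s symmetrized as (S+S^T)/2", path)
        S = (S + S.T) / 2.0
    return SimilarityView(S=S, entity=entity, source_tag=source_tag)


def write_similarity_matrix(view: SimilarityView, path, entity_ids) -> None:
    pd.DataFrame(view.S, index=list(entity_ids), columns=list(entity_ids)).to_csv(path, sep="\t")
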