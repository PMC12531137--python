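"""Cross-validation protocol, training loop, prediction and metrics.

Evaluation follows a balanced 5-fold protocol: all confirmed pairs are
positives, an equal-count seeded sample of unconfirmed pairs are negatives,
and the balanced pair set is partitioned into folds stratified by label.
For each fold the model is trained with the fold's positive labels removed
from the association matrix (GIP kernels and reconstruction masks are
recomputed from the masked matrix, and held-out pairs are excluded from
both reconstruction masks) and scored on the held-out pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, average_precision_score, f1_score, roc_auc_score

from .contrastive import ProjectionHead, dual_view_contrastive_loss
from .dataio import AssociationDataset, RunConfig, SimilarityView, dataset_summary
from .encoder import EncoderParams, encode
from .fusion import FusedSimilarity, gip_kernel, linear_fuse, snf_fuse
from .hypergraph import build_node_features, knn_hypergraph, ko_hypergraph
from .integration import IntegrationParams, decode_scores, interview_attention, reconstruction_loss, total_loss, view_gate
from .nn import Adam, Tensor

logger = logging.getLogger("dhclham")

__all__ = [
    "FoldPlan",
    "TrainedModel",
    "EvalReport",
    "make_cv_folds",
    "train_model",
    "predict",
    "evaluate",
    "run_cv",
    "ablate",
]

VARIANTS = ("full", "NoDHA", "NoCL", "MS1DS1", "MS2DS2", "Linear")


@dataclass(frozen=True)
class FoldPlan:
    """Balanced positive/negative pair set with a stratified fold assignment."""

    pairs: np.ndarray  # (n, 2) microbe/drug indices
    labels: np.ndarray  # (n,) 0/1
    fold_assignment: np.ndarray  # (n,) fold index
    seed: int
    n_folds: int

    def fold_pairs(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.fold_assignment == fold
        return self.pairs[m], self.labels[m]


@dataclass
class TrainedModel:
    """All learnable parameters plus the cached score matrix after training."""

    encoders: dict  # (entity, view_tag) -> EncoderParams
    heads: dict  # entity -> ProjectionHead
    integration: dict  # entity -> IntegrationParams
    config: RunConfig
    loss_trace: list
    scores: np.ndarray  # final (Nm, Nd) association scores

    def parameters(self) -> list:
        ps: list = []
        for enc in self.encoders.values():
            ps += enc.parameters()
        for h in self.heads.values():
            ps += h.parameters()
        for ip in self.integration.values():
            ps += ip.parameters()
        return ps


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and averaged AUC / AUPR / F1 / ACC."""

    per_fold: dict  # metric -> list of per-fold values
    mean: dict
    sd: dict
    threshold: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_fold": {k: list(map(float, v)) for k, v in self.per_fold.items()},
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
            "threshold": self.threshold,
            "seed": self.seed,
        }


def make_cv_folds(ds: AssociationDataset, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Balanced, stratified, seeded fold plan over pairs."""
    rng = np.random.default_rng(seed)
    pos = np.argwhere(ds.A == 1)
    n_pos = len(pos)
    if n_pos < n_folds:
        raise ValueError(f"need at least {n_folds} positive pairs, found {n_pos}")
    neg_all = np.argwhere(ds.A == 0)
    if n_pos > len(neg_all):
        raise ValueError("not enough unconfirmed pairs for balanced sampling")
    neg = neg_all[rng.choice(len(neg_all), size=n_pos, replace=False)]
    # stratified round-robin assignment after a seeded shuffle of each class
    folds_pos = np.arange(n_pos) % n_folds
    folds_neg = np.arange(n_pos) % n_folds
    rng.shuffle(pos)
    rng.shuffle(neg)
    pairs = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])
    assignment = np.concatenate([folds_pos, folds_neg])
    return FoldPlan(pairs=pairs, labels=labels, fold_assignment=assignment, seed=seed, n_folds=n_folds)


def _fuse_views(views: list[SimilarityView], config: RunConfig, n: int) -> FusedSimilarity:
    if len(views) == 1:
        S = views[0].S
        return FusedSimilarity(S_final=(S + S.T) / 2.0, n_iterations=0, converged=True)
    if config.variant == "Linear":
        return linear_fuse(views)
    k = config.snf_k if config.snf_k is not None else max(1, n // 10)
    return snf_fuse(views, k=k)


def _forward(ds_shape, A_train, encoders, heads, integration, hgs, feats, config):
    """One full forward pass; returns (As, L_cl_m, L_cl_d)."""
    use_attn = config.variant != "NoDHA"
    Z = {}
    for entity in ("microbe", "drug"):
        for hg in hgs[entity]:
            Z[(entity, hg.view_tag)] = encode(
                hg,
                feats[entity],
                encoders[(entity, hg.view_tag)],
                norm=config.attention_norm,
                entity=entity,
                use_attention=use_attn,
            )
    if config.variant == "NoCL" or (config.lambda_m == 0.0 and config.gamma_d == 0.0):
        L_cl_m = Tensor(0.0)
        L_cl_d = Tensor(0.0)
    else:
        L_cl_m, L_cl_d = dual_view_contrastive_loss(
            Z[("microbe", "View1")],
            Z[("microbe", "View2")],
            Z[("drug", "View1")],
            Z[("drug", "View2")],
            heads["microbe"],
            heads["drug"],
            tau=config.tau,
        )
    fused = {}
    for entity in ("microbe", "drug"):
        ip = integration[entity]
        g1 = view_gate(Z[(entity, "View1")], ip, view=0)
        g2 = view_gate(Z[(entity, "View2")], ip, view=1)
        fused[entity] = interview_attention(g1, g2, ip)
    As = decode_scores(fused["microbe"], fused["drug"], integration["microbe"], integration["drug"])
    return As, L_cl_m, L_cl_d


def train_model(
    ds: AssociationDataset,
    ms1: SimilarityView | None,
    ds1: SimilarityView | None,
    plan: FoldPlan | None,
    fold: int | None,
    config: RunConfig,
) -> TrainedModel:
    """Train on all pairs except the held-out fold (if any); fully seeded."""
    if config.variant not in VARIANTS:
        raise ValueError(f"unknown variant {config.variant!r}")
    A = ds.A.copy()
    test_mask = np.zeros_like(A, dtype=bool)
    if plan is not None and fold is not None:
        test_pairs, _ = plan.fold_pairs(fold)
        test_mask[test_pairs[:, 0], test_pairs[:, 1]] = True
        A[test_mask] = 0.0  # hide test positives from training signal

    # similarity views per entity; GIP recomputed from the fold-masked matrix
    gip_m = gip_kernel(A, axis="rows")
    gip_d = gip_kernel(A, axis="columns")
    if config.variant == "MS1DS1":
        if ms1 is None or ds1 is None:
            raise ValueError("MS1DS1 variant requires ms1 and ds1 inputs")
        views_m, views_d = [ms1], [ds1]
    elif config.variant == "MS2DS2":
        views_m, views_d = [gip_m], [gip_d]
    else:
        views_m = ([ms1] if ms1 is not None else []) + [gip_m]
        views_d = ([ds1] if ds1 is not None else []) + [gip_d]
    fused_m = _fuse_views(views_m, config, ds.n_microbes)
    fused_d = _fuse_views(views_d, config, ds.n_drugs)

    feats = {
        "microbe": build_node_features(A, fused_m, "microbe"),
        "drug": build_node_features(A, fused_d, "drug"),
    }
    rng = np.random.default_rng(config.seed * 100003 + (fold or 0))
    hgs = {}
    for entity, n in (("microbe", ds.n_microbes), ("drug", ds.n_drugs)):
        k = min(config.knn_k, n - 1)
        c = min(config.ko_c, n)
        ko_seed = int(rng.integers(2**31 - 1))
        hgs[entity] = [
            knn_hypergraph(feats[entity], k, include_centroid=config.include_centroid),
            ko_hypergraph(feats[entity], c, seed=ko_seed),
        ]

    d = config.embed_dim
    encoders = {
        (entity, hg.view_tag): EncoderParams.init(rng, feats[entity].X.shape[1], d, config.hgcn_layers)
        for entity in ("microbe", "drug")
        for hg in hgs[entity]
    }
    heads = {entity: ProjectionHead.init(rng, d) for entity in ("microbe", "drug")}
    integration = {entity: IntegrationParams.init(rng, d, n_heads=config.n_heads) for entity in ("microbe", "drug")}

    observed = (A == 1.0) & ~test_mask
    unobserved = (A == 0.0) & ~test_mask
    lam = 0.0 if config.variant == "NoCL" else config.lambda_m
    gam = 0.0 if config.variant == "NoCL" else config.gamma_d

    model = TrainedModel(encoders=encoders, heads=heads, integration=integration, config=config, loss_trace=[], scores=None)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    As = None
    for epoch in range(config.epochs):
        As, L_cl_m, L_cl_d = _forward(ds.A.shape, A, encoders, heads, integration, hgs, feats, config)
        L_RE = reconstruction_loss(A, As, observed, unobserved, config.alpha)
        loss = total_loss(L_RE, L_cl_m, L_cl_d, lam, gam)
        if not np.isfinite(loss.data):
            for name, t in (("reconstruction", L_RE), ("contrastive_m", L_cl_m), ("contrastive_d", L_cl_d)):
                if not np.isfinite(t.data):
                    raise FloatingPointError(f"non-finite {name} loss at epoch {epoch}")
            raise FloatingPointError(f"non-finite total loss at epoch {epoch}")
        model.loss_trace.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    # final forward with trained parameters
    As, _, _ = _forward(ds.A.shape, A, encoders, heads, integration, hgs, feats, config)
    model.scores = As.data.copy()
    return model


def predict(model: TrainedModel, pairs) -> np.ndarray:
    """Scores As[i, j] for each (microbe, drug) index pair."""
    pairs = np.asarray(pairs, dtype=int)
    nm, nd = model.scores.shape
    if pairs.size and ((pairs[:, 0] < 0) | (pairs[:, 0] >= nm) | (pairs[:, 1] < 0) | (pairs[:, 1] >= nd)).any():
        raise IndexError("pair index out of range")
    return model.scores[pairs[:, 0], pairs[:, 1]]


def evaluate(scores, labels, threshold: float = 0.5) -> dict:
    """AUC, AUPR on raw scores; F1/ACC after binarizing at `threshold`.

    The decoder regresses scores toward the 0/1 association targets, so the
    default threshold is the target midpoint 0.5 applied to the raw scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    preds = (scores >= threshold).astype(int)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
        "acc": float(accuracy_score(labels, preds)),
    }


def run_cv(
    ds: AssociationDataset,
    ms1: SimilarityView | None = None,
    ds1: SimilarityView | None = None,
    config: RunConfig | None = None,
) -> EvalReport:
    """Full cross-validated evaluation: one model per fold."""
    config = config or RunConfig()
    logger.info("run_cv: %s | config=%s", dataset_summary(ds), config)
    plan = make_cv_folds(ds, n_folds=config.cv_folds, seed=config.seed)
    per_fold: dict[str, list] = {"auc": [], "aupr": [], "f1": [], "acc": []}
    for fold in range(config.cv_folds):
        model = train_model(ds, ms1, ds1, plan, fold, config)
        test_pairs, test_labels = plan.fold_pairs(fold)
        metrics = evaluate(predict(model, test_pairs), test_labels, threshold=config.threshold)
        logger.info("fold %d: %s", fold, metrics)
        for k, v in metrics.items():
            per_fold[k].append(v)
    mean = {k: float(np.mean(v)) for k, v in per_fold.items()}
    sd = {k: float(np.std(v)) for k, v in per_fold.items()}  # population SD
    return EvalReport(per_fold=per_fold, mean=mean, sd=sd, threshold=config.threshold, seed=config.seed)


def ablate(config: RunConfig, variant: str) -> RunConfig:
    """Configuration for an ablation variant of the model."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant == "NoCL":
        return config.replace(variant="NoCL", lambda_m=0.0, gamma_d=0.0)
    return config.replace(variant=variant)
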