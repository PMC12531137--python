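# dhclham

Microbe–drug association prediction with dual-hypergraph contrastive
learning and hierarchical attention.

Many drugs alter the composition of host-associated microbial communities,
and many microbes modulate drug efficacy; experimentally mapping which
microbe interacts with which drug is slow and expensive. `dhclham`
implements a link-prediction model for this setting: given a sparse binary
association matrix **A** (microbes × drugs, typically 1–6% dense) and
optional curated similarity matrices (microbial functional similarity,
drug structural similarity), it scores every unobserved microbe–drug pair.

## The model

1. **Similarity fusion.** For each entity type, a Gaussian interaction
   profile (GIP) kernel `S(i,j) = exp(−η‖p_i − p_j‖²)` is computed from the
   association profiles (bandwidth `η` normalized by the mean squared
   profile norm). Curated and GIP similarities are integrated by non-linear
   cross-diffusion (similarity network fusion): each view's row-normalized
   state is repeatedly smoothed through the other views via its k-nearest-
   neighbor local kernel, `S_t ← K_t (mean of other states) K_tᵀ`, until the
   relative change falls below 1e-5, then averaged and symmetrized.
2. **Dual hypergraph views.** Node features concatenate the association
   profile with the fused similarity row. View 1 has one hyperedge per node
   (the node plus its k nearest Euclidean neighbors); View 2 partitions the
   nodes into C clusters found by a seeded population-based k-means
   optimizer, one hyperedge per cluster.
3. **Hierarchical attention + HGCN.** Hyperedge-level attention pools
   member nodes into hyperedge representations; node-level attention pools
   incident hyperedges back into node embeddings (scores `qᵀk / D`,
   softmax-normalized), followed by two layers of spectral hypergraph
   convolution `X ← σ(D_v^{−1/2} H W D_e^{−1} Hᵀ D_v^{−1/2} X θ)`.
4. **Dual-view contrastive learning.** An InfoNCE objective pulls the same
   node's two view embeddings together and pushes different nodes apart
   (cosine similarity on projected embeddings, temperature τ).
5. **Gating, inter-view attention, decoding.** Each view is gated by a
   squeeze-and-excitation-style per-feature gate, the two views are fused
   per node by multi-head 2×2 inter-view attention, and association scores
   are the inner products `A_s = Y_m Y_dᵀ` of the decoded embeddings.
6. **Loss.** A weighted Frobenius reconstruction loss
   `(1−α)/2‖P_Ω(A−A_s)‖² + α/2‖P_Ω̄(A−A_s)‖²` (α balances observed vs
   unobserved entries) plus the two contrastive terms, optimized with Adam.

Evaluation follows a balanced 5-fold cross-validation: all confirmed pairs
are positives, an equal number of seeded unconfirmed pairs are negatives,
and each fold's positives are hidden from the training matrix (GIP kernels
and loss masks are recomputed per fold, held-out pairs excluded from both
reconstruction masks).

All differentiable components run on a small reverse-mode autodiff core
over numpy (`dhclham.nn`); no GPU or deep-learning framework is required.

## Worked example

A seeded synthetic benchmark with planted block-structured low-rank
associations (60 microbes × 120 drugs at 5% density, plus noisy,
half-missing similarity views) ships with the package:

```python
import json
from dhclham import RunConfig, SyntheticSpec, generate_dataset, run_cv

spec = SyntheticSpec(seed=0)           # 60 microbes x 120 drugs, 5% density
data = generate_dataset(spec)
config = RunConfig(embed_dim=64, epochs=400, n_heads=4, knn_k=6, ko_c=4, seed=0)
report = run_cv(data.ds, data.ms1, data.ds1, config)
print(json.dumps(report.mean, indent=2))
```

prints (about two minutes on one CPU):

```json
{
  "auc": 0.8481475110141308,
  "aupr": 0.8524995266208718,
  "f1": 0.5882192839665381,
  "acc": 0.6963346908552388
}
```

i.e. held-out microbe–drug pairs are ranked with mean AUC ≈ 0.85 across the
five folds (per-fold values and standard deviations are in
`report.per_fold` / `report.sd`), recovering most of the planted signal;
the same pipeline on label-permuted data scores at chance (AUC ≈ 0.5).

The same workflow is available from the shell:

```bash
dhclham simulate --seed 0 --out data/
dhclham evaluate --assoc data/associations.tsv --ms1 data/ms1.tsv \
    --ds1 data/ds1.tsv --report report.json
dhclham train --assoc data/associations.tsv --out model/
dhclham predict --model model/ --pairs pairs.tsv
```

## Layout

- `src/dhclham/dataio.py` — TSV readers/writers, dataset summaries, config
- `src/dhclham/fusion.py` — GIP kernel, non-linear (SNF) and linear fusion
- `src/dhclham/hypergraph.py` — node features, KNN and clustering views
- `src/dhclham/encoder.py` — hierarchical attention, hypergraph convolution
- `src/dhclham/contrastive.py` — dual-view InfoNCE
- `src/dhclham/integration.py` — gating, inter-view attention, decoder, losses
- `src/dhclham/train.py` — cross-validation, training loop, metrics, ablations
- `src/dhclham/synthetic.py` — seeded planted-structure data generator
- `src/dhclham/nn.py` — minimal reverse-mode autodiff + Adam
- `docs/methods.md` — modelling choices, parameters, and limitations
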