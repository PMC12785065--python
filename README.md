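# lazynet

One-step **log–linear–exp neural-ODE** modeling of two-snapshot CRISPR
perturbation screens, with elasticity-based gene-network inference and the
matched-null statistics needed to validate the inferred edges against
external evidence.

## Who this is for

Perturb-seq experiments (pooled CRISPR activation/interference with a
single-cell RNA readout) usually provide exactly two snapshots per
perturbation: a baseline state and one post-perturbation state. Labs
running such screens on their own data — without GPUs, pathway priors or
large pretraining corpora — need a model that (i) trains from scratch on a
CPU, (ii) yields mechanistically interpretable parameters, and (iii) comes
with honest null models for judging the resulting network. `lazynet`
provides that pipeline end to end, plus synthetic-data generators so every
stage can be exercised against a known ground truth.

## The model

A gene-regulatory ODE dx/dt = F(x) is discretized with one explicit Euler
step, matching the two-snapshot design:

    x_post = x_0 + F(x_0) · Δt

The rate law is a signed sum of monomials realized by a single
log → linear → exp (LLE) block:

    F(x) = C · exp(W₂ · log(max(W₁x + b₁, ε)) + b₂)

Because log converts products into sums, **one hidden row encodes an entire
monomial c·x₁^α₁…x_d^α_d exactly** — its exponent vector lives in a row of
W₂ and log c in b₂ — so a K-term rate law needs only K(d+1) trainable
scalars plus signs. The signed combination matrix C lets the same block
express production and decay. Multiplicative (synergistic) gene–gene
effects are first-class parameters, not emergent composites.

With only two snapshots the absolute time step is not identifiable (only
the product of Δt and the rates is learnable), so Δt is fixed to 1 during
training and folded into the coefficients.

**Elasticities.** The Jacobian of the one-step prediction at a common
baseline state, averaged over an ensemble of independently seeded replicas,
gives a signed, directed sensitivity matrix S with S[g, i] = ∂(predicted
x_i)/∂x_g — row g lists genes downstream of g. |S| scores candidate
regulatory edges; breadth-first seed expansion (per-hop top-N neighbors
passing an absolute floor and a percentile cut) turns it into compact
subgraphs; recall/enrichment against curated benchmark genes, matched-null
co-expression enrichment, hypergeometric reference-graph overlap,
degree-preserving rewiring, and degree-matched protein co-variation tests
quantify how much of the network is supported by independent evidence.

## Worked example

Simulate a screen with a known 20-gene, 30-term rate law, run the full
pipeline, and check how well the learned elasticities recover the planted
interactions:

```python
import numpy as np
from sklearn.metrics import roc_auc_score
from lazynet.synthetic_data import ScreenSimConfig, simulate_guide_screen
from lazynet.perturb_data import (qc_filter, normalize_counts, guide_split,
                                  build_snapshot_pairs, control_baseline)
from lazynet.training import TrainConfig, fit_ensemble
from lazynet.elasticity_network import (compute_elasticity_matrix, expand_seed,
                                        ExpansionConfig, benchmark_recall)

config = ScreenSimConfig(seed=0)                      # 20-gene panel, 2000 singlets
matrix, guides, truth = simulate_guide_screen(config)
raw = qc_filter(matrix, min_cells_per_gene=3, min_genes_per_cell=5)
norm = normalize_counts(raw)
_, singlets, _ = guide_split(raw, guides)
pairs = build_snapshot_pairs(norm, guides, cells=singlets)
ensemble = fit_ensemble(pairs, TrainConfig(seed=7, n_replicas=3,
                                           max_epochs=400, batch_size=256))
baseline = control_baseline(norm, guides)
S = compute_elasticity_matrix(ensemble, baseline)

dyn = [g for g in truth["gene_ids"] if g in S.gene_ids]
idx = [S.gene_ids.index(g) for g in dyn]
off = ~np.eye(len(dyn), dtype=bool)
auc = roc_auc_score(truth["support"][off], S.abs[np.ix_(idx, idx)][off])
print(f"support-recovery ROC-AUC: {auc:.3f}")

graph = expand_seed(S, dyn[0], ExpansionConfig(top=8, depth=2, pct=95.0))
print(f"seed {dyn[0]}: {graph.n_nodes} genes, {graph.n_edges} edges")
report = benchmark_recall(graph.nodes, set(dyn[:8]),
                          background_size=len(S.gene_ids))
print(f"benchmark recall {report.recall:.2f}, enrichment {report.enrichment:.2f}x")
```

Output (about 15 s on one CPU core):

```
support-recovery ROC-AUC: 0.932
seed G00: 29 genes, 62 edges
benchmark recall 1.00, enrichment 3.45x
```

The ROC-AUC says the ensemble's |elasticity| ranking separates true
planted interactions from non-interactions; the expansion then grows a
small subgraph from one anchor gene, and the recall report shows it
recovers the benchmark set 3.45× more often than size-matched chance.

The same workflow is available from the shell:

```bash
lazynet simulate --seed 0 --out screen/
lazynet prepare  --counts screen/ --guides screen/guides.tsv \
                 --min-genes-per-cell 5 --hvg 1.0 --out pairs.h5
lazynet train    --pairs pairs.h5 --seed 7 --out model.h5
lazynet infer-network --model model.h5 --pairs pairs.h5 --seeds seeds.txt \
                 --top 32 --depth 4 --pct 99 --out graph.tsv
lazynet validate-network  --graph graph.tsv --reference ref.tsv --mode overlap --out overlap.json
lazynet validate-proteomics --graph graph.tsv --proteins proteins.tsv --out protein.json
```

Real 10x-style inputs (Matrix Market triplet + guide-call TSV) are read by
`lazynet prepare`; the synthetic generator exists so the full pipeline can
be tested against a known answer.

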